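# tillingkit

Computational support for TILLING (Targeting Induced Local Lesions In
Genomes) platforms built on EMS-mutagenized populations, modelled on the
*Brassica rapa* R-o-18 resource: genetic-code enumeration of EMS-reachable
changes, mutation-density estimation with GC normalization, screen-design
probability calculations, and a forward simulator of a pooled M2 screen
that validates the estimators by parameter recovery.

## The science in brief

EMS (ethyl methane sulfonate) alkylates guanine and induces, almost
exclusively, G:C→A:T transitions. Within the standard genetic code this
restricts the reachable changes to the 96 G/C positions of the 64 codons
(8 codons contain neither base and are untouchable). Exhaustive
enumeration partitions those 96 changes into 33 silent, 58 mis-sense
(26 distinct amino-acid substitutions) and 5 nonsense — there are only
five routes to a stop codon: CAA, CAG, the C of CGA, and either G of TGG.

A TILLING assay screens an amplicon of length *L* bp across *n* pooled
plants and detects *m* mutations; the density is

    bp per mutation = L·n / m          (rendered "1/X kb", X = bp/1000)

Because EMS hits only G/C sites, a density measured at GC fraction *g₁*
rescales to reference GC *g₂* as `bp · g₁/g₂`. Dividing the genome size by
the density gives the per-plant mutation load; multiplying the summed
population load by 1/(genome G/C sites) gives the saturation — the
fraction of mutable sites segregating somewhere in the population. The
chance that a screen yielding *E* expected mutations contains at least one
truncation allele is

    P = 1 − (1 − f)^E,   f = 5/96 under uniform codon usage.

The simulator draws per-plant mutations as independent Bernoulli events on
the G/C sites of a synthetic reference, assigns heterozygosity at a target
het:hom ratio, pools plants eight-fold, and attenuates detection near the
amplicon ends (where TILLING assays are known to miss mutations), so that
the whole estimation chain can be checked against known truth.

## Worked example

```python
>>> from tillingkit import code_spectrum, ScreenAssay, density_estimate
>>> s = code_spectrum()
>>> (s.unaffected_codons, s.mutable_positions, s.silent, s.mis_sense, s.nonsense)
(8, 96, 33, 58, 5)

>>> assay = ScreenAssay("BraA.RPL.a", 0.3, 1007, 47, 21, 768, 6912)
>>> est = density_estimate(assay)
>>> round(est.bp_per_mutation_raw), est.mutations_per_plant_raw, est.mutations_per_plant_norm
(36827, 13577, 10111)
```

One mutation per ~36.8 kb screened at 47% GC (1/49 kb at the 35% genome
GC level) extrapolates to ~13,600 raw, ~10,100 GC-normalized mutations per
plant over a 500 Mbp genome. Running
`python examples/screen_design.py` prints the design numbers:

```
P(>=1 stop codon | 68.2 mutations):      0.974  (~97%)
per-plant budget of a 10,000-mutation load:
  exonic 1100, amino-acid-changing 722, nonsense 57
population saturation of genome G/C sites: 0.484 naive, 0.384 collision-corrected
after 10 generations: 9.8 remain
```

i.e. a standard 3,072-plant screen of a 1 kb exonic amplicon is ~97%
likely to return a truncation allele, a 10,000-mutation plant carries
~1,100 exonic hits of which ~57 could be stops, the population covers
about half of the genome's G/C sites, and ten backcross generations
reduce a 10,000-mutation background to ~10.

The other scripts in `examples/` each demonstrate one capability:
`spectrum_census.py` (code enumeration), `profile_cds.py` (per-window
stop-codon potential of a CDS), `screen_table.py` (re-deriving the full
density table from the packaged raw assay rows), and
`simulate_recovery.py` (parameter recovery on simulated screens). A thin
CLI mirrors these: `tillingkit spectrum | profile | density | design |
saturation | backcross | simulate | recover`.

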