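# Methods

## Genetic-code enumeration

EMS mutagenesis is modelled as producing only G→A and C→T transitions on
the reported (sense) strand; the complementary lesions are the same event
seen from the other strand and are not double-counted. Every G/C
occurrence across the 64 codons of the standard nuclear code (translation
table 1, via Biopython's codon table) is one mutable position — 96 in
total, with 8 codons (those over {A,T} only) unreachable. Each change is
classified by translating before and after:

* **silent** — identical product. Stop→stop changes (TAG→TAA, TGA→TAA)
  are classed silent: the product, chain termination, is unchanged. This
  convention is what yields the 33/58/5 partition; counting stop→stop as
  its own class would give 31/58/5/2.
* **nonsense** — a sense codon becomes a stop codon.
* **mis-sense** — any other amino-acid substitution.

"Conservative" mis-sense changes are flagged under a pluggable
partition of the 20 amino acids; the default groups
{ILVM},{FYW},{KRH},{DE},{ST},{NQ},{AG},{C},{P}. Chemical-similarity
classifications are not canonical, so the conservative count is reported
but never asserted against any external figure.

`profile_cds` applies the same enumeration codon-by-codon along a coding
sequence (1-based sense-strand coordinates, configurable frame offset;
trailing partial codons ignored). Windows for the nonsense-site density
track tile the frame-covered region so that window counts always sum to
the total nonsense-site count. Ambiguity codes are rejected by default; a
permissive mode skips the affected codons with a warning, which biases
`mutable_sites` low and is intended only for quick looks at draft
sequence.

## Density estimation and the derived screen table

For an assay with amplicon length L, plants screened n and mutations
detected m, the density is L·n/m bp per mutation, undefined (an error,
not infinity) at m = 0. GC normalization multiplies by
gc_assay/gc_reference, valid because the per-bp EMS rate is proportional
to local GC content. The per-plant load divides genome size by the
density. Defaults (500 Mbp genome, 35% genome GC, 11% coding fraction,
41% exon GC) describe the *B. rapa* platform and are all overridable
through `PopulationConstants`.

Display conventions, chosen to reproduce published TILLING density
tables exactly and applied only at display time (full precision is kept
internally):

* rounding is round-half-up ("spreadsheet" rounding), not banker's;
* "1/X kb" takes X = bp/1000 rounded half-up;
* the displayed normalized per-plant load is computed from the *rounded*
  raw load (round(load)·gc_ref/gc, then round again);
* per-dose average rows average the rounded per-assay display values,
  again rounding half-up.

With these conventions every derived cell of the packaged eight-assay
table matches its published counterpart, with three caveats documented
here: one density cell was misprinted as "1/358" where the raw columns
give 57,658 bp = 1/58; and two expected-yield cells print 209 and 191
where the raw columns give 208.49 and 191.58 (no consistent rounding
produces both — their ±1 errors cancel, so the printed average row is
reproduced exactly). The fixture stores only raw columns, so these
discrepancies live in the comparison, not in the data.

The expected-yield column is defined for exactly 1000 bp (not the
amplicon length) screened across the full population, at the amplicon's
own GC for the first value and rescaled to exon GC (41%) for the
parenthesized value.

## Screen-design formulas

* **Stop-codon probability.** P(≥1 nonsense) = 1 − (1 − f)^E for E
  expected mutations and nonsense fraction f (default 5/96, the
  uniform-codon prior; a CDS-specific fraction from `profile_cds` may be
  substituted). This closed form treats mutation occurrences as
  independent; for integer E it equals 1 − Binomial(E, f){0}, which the
  test suite checks against scipy's binomial. The formula is this
  package's reconstruction of the standard design calculation; it
  reproduces the benchmark 97% at E = 68.2. The value 68.2 is treated as
  a given screen-average input, not a quantity this package derives.
* **Saturation.** Σ(load_i · n_plants_i) / (genome_size · GC fraction),
  i.e. total population mutations over mutable sites — also a
  reconstruction, reproducing the benchmark 0.484 ("about half") from
  the two dose-group average loads. The naive ratio ignores two plants
  hitting the same site; the optional collision-corrected mode returns
  1 − exp(−λ) under a Poisson-occupancy model and is always smaller.
  Loads should be GC-normalized to match the genome GC used in the
  denominator.
* **Exon budget.** load · exon_fraction exonic hits, of which
  (58+5)/96 change the protein and 5/96 truncate it.
* **Backcrossing.** load · 0.5^generations.

## Population simulator

What it emulates: an EMS M2 population screened by pooled
heteroduplex-cleavage assays.

* Reference: i.i.d. bases, P(G) = P(C) = gc/2. Default 5 Mb at 35% GC — a
  1/100-scale stand-in for a ~500 Mbp genome, small enough for replicate
  experiments in seconds.
* Mutation model: each G/C site mutates independently per plant with
  probability `per_gc_site_rate` (default 5.5e-5, set once so the
  genome-equivalent load is ~9,600, matching a ~10,000-mutation plant);
  A/T sites never mutate. Implemented exactly as Binomial count +
  uniform site subset.
* Zygosity: each mutation is heterozygous with probability r/(r+1)
  (default r = 12.1, a typical observed M2 het:hom ratio). Zygosity is
  an input, not an emergent property: M1→M2 selfing, chimeric raceme
  structure and fertility selection are deliberately not modelled.
* Pooling: one-dimensional, plant i → pool ⌊i/8⌋; a short remainder pool
  holds any leftover plants. Both het and hom mutations are detectable
  in a pool (a hom line still mismatches the seven wild-type lines); an
  off-by-default `allele_dilution` flag halves het sensitivity (1 vs 2
  mutant alleles of 16) for sensitivity analyses.
* Detection: a step model — sensitivity `edge_sensitivity` within
  `edge_window` bp (default 100) of either amplicon end,
  `interior_sensitivity` (default 1.0) elsewhere; a linear-ramp variant
  is available but the observed positional pattern does not constrain a
  ramp shape, so the step is default. The default edge sensitivity
  0.0327 solves 2w·s/(2w·s + (L−2w)) = 5/617 for a 1 kb amplicon — the
  observed share of detections falling within 100 bp of the ends.
  Detection draws one uniform per true mutation against the positional
  sensitivity, so under a fixed seed the detected count is monotone
  non-increasing in the edge window (common random numbers).

All stochastic operations take a numpy `Generator` or seed and are
exactly reproducible; the CLI writes the resolved config (including
seed) next to every simulation output.

What the simulator does **not** capture: chimeric M1 sectors and
linkage between mutations, selection against deleterious loads,
sequence-context rate variation, Taq/Cel1 biochemistry, and
false positives (assumed zero, as in sequencing-confirmed platforms).
Passing recovery tests therefore show the estimation chain is unbiased
under the stated sampling model, not that real screens are free of
context-dependent detection failure — indeed the motivating data contain
two amplicons with fewer nonsense hits than the code's odds predict.

## Validation by parameter recovery

`recovery_experiment` simulates replicate screens at a known rate and
pushes each through the same `ScreenAssay` → density → load chain used on
real tables, using the simulated reference as "genome" and its realized
GC for normalization. The per-plant load estimate is linear in the
detected count and hence unbiased; the bp-per-mutation estimate (∝ 1/m)
carries a small Jensen bias of order 1/m, which is why the acceptance
check uses 3,072-plant screens (~60 detections each, bias ≲2%) over 20
replicates and a 3-standard-error criterion. Problem sizes throughout
the test suite (200 kb–5 Mb references, 64–6,912 plants) were chosen as
the smallest scales at which the binomial error bars are still
informative.

## Known limitations

* The uniform-codon 5/96 nonsense prior ignores codon-usage bias; use a
  CDS-specific fraction for gene-level design.
* GC normalization assumes the per-G/C-site rate is uniform; real EMS
  spectra show context effects the model omits.
* The derived-table display conventions are exactly those of the
  motivating platform's published table; other groups may round
  differently, and machine-readable outputs therefore always carry full
  precision.
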