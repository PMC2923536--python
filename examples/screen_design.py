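"""Screen-design arithmetic: yields, stop-codon odds, saturation, backcrossing.

Given a mutation density, how many mutations will a screen return, what
is the chance of a truncation allele, how much of the genome's mutable
space does the whole population cover, and how long would backcrossing
take to clean a background?
"""

from tillingkit import (
    backcross_load,
    exon_budget,
    expected_mutations,
    normalize_bp_per_mutation,
    p_at_least_one_nonsense,
    saturation_fraction,
)

# A standard screen: 3,072 plants, 1 kb exonic amplicon (41% GC), with the
# population's normalized density of 1/56 kb at 35% GC.
bp_at_exon_gc = normalize_bp_per_mutation(56_000, 35, 41)
e = expected_mutations(3072, 1000, bp_at_exon_gc)
print(f"expected mutations in a standard screen: {e:.1f}")
p = p_at_least_one_nonsense(68.2)  # observed average yield of such screens
print(f"P(>=1 stop codon | 68.2 mutations):      {p:.3f}  (~{100 * p:.0f}%)")

exonic, aa, stops = exon_budget(10_000)
print(f"\nper-plant budget of a 10,000-mutation load:")
print(f"  exonic {exonic:.0f}, amino-acid-changing {aa:.0f}, nonsense {stops:.0f}")

frac = saturation_fraction([(9693, 6912), (7717, 2304)])
corrected = saturation_fraction([(9693, 6912), (7717, 2304)],
                                collision_corrected=True)
print(f"\npopulation saturation of genome G/C sites: {frac:.3f} naive, "
      f"{corrected:.3f} collision-corrected")

print(f"\nbackcrossing 10,000 background mutations, halving per generation:")
print(f"  after 10 generations: {backcross_load(10_000, 10):.1f} remain")
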