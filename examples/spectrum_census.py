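"""Census of EMS-accessible changes in the standard genetic code.

EMS induces G:C->A:T transitions almost exclusively, so its reach within
the genetic code can be enumerated exactly: every G or C in every codon
is one mutable position.  This prints the full census and the class
fractions used elsewhere as screen-design priors.
"""

from tillingkit import code_spectrum, expected_class_fractions

s = code_spectrum()
print(f"codons without G/C (EMS-proof): {s.unaffected_codons} of 64 "
      f"({100 * s.unaffected_codons / 64:.1f}%)")
print(f"mutable G/C positions:          {s.mutable_positions}")
print(f"  silent                        {s.silent}")
print(f"  mis-sense                     {s.mis_sense} "
      f"({s.distinct_substitutions} distinct substitutions)")
print(f"  nonsense (new stop codon)     {s.nonsense}")
print()
for cls, frac in expected_class_fractions().items():
    print(f"fraction of coding hits that are {cls:>9}: {frac:.4f}")
print()
print("Only 5 of 96 coding hits can truncate the protein, which is why")
print("screen design centres on the probability of at least one nonsense hit.")
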