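"""Profile a coding sequence for EMS effect potential.

Before designing a TILLING amplicon it pays to know where stop codons can
be created: here we profile a toy CDS and print the per-window count of
potential nonsense sites, the quantity used to pick the amplicon window.
"""

from tillingkit import profile_cds

# toy 90 bp CDS: a start codon, repeated Trp/Gln/Arg-rich motif, stop
cds = "ATG" + "TGGCAACGAGCTAAA" * 5 + "TGGCAATAA"
prof = profile_cds(cds, frame_offset=0, window_bp=30, sequence_id="toy_cds")

print(f"{prof.sequence_id}: {prof.length_bp} bp, "
      f"{prof.mutable_sites} mutable G/C sites")
print(f"class counts: {prof.class_counts}")
print()
print("window (bp)   potential stop-codon sites")
for start, end, n in prof.window_nonsense_density:
    print(f"{start:>4}-{end:<8} {n}")
print()
print("TGG (Trp), CAA/CAG (Gln) and CGA (Arg) codons are the only stop")
print("routes, so windows rich in them are the best screening targets.")
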