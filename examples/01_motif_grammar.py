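"""Parse, scan, and classify phosphorylation motif patterns.

Motifs are written in the positional shorthand used in the kinase
literature: dash-separated positions, "/" for alternatives, X for a
wildcard.  One position, the phospho-acceptor, is an S/T/Y residue.
"""

from phosmoca import classify_pattern, parse_motif_pattern, scan_sequence

stp = parse_motif_pattern("S/T-P", "proline_directed")
rxxst = parse_motif_pattern("R-X-X-S/T", "basophilic")

print("S/T-P positions:", [sorted(p) if p else "X" for p in stp.positions],
      "acceptor offset:", stp.acceptor_offset)
print("R-X-X-S/T positions:", [sorted(p) if p else "X" for p in rxxst.positions],
      "acceptor offset:", rxxst.acceptor_offset)

seq = "MSPARRAASQPSPDD"
print("\nsequence:", seq)
print("S/T-P acceptors at:", scan_sequence(stp, seq))
print("R-X-X-S/T acceptors at:", scan_sequence(rxxst, seq))

for pat in (stp, rxxst):
    flags = classify_pattern(pat)
    print(f"{pat.raw}: proline_directed={flags.proline_directed} "
          f"basic={flags.basic}")

# The scan positions are 1-based acceptor residues; the structural flags
# drive the CI-rank binning (proline-directed vs basophilic motifs).
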