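"""Fold candidate regions, build their consensus, and locate it vs AREs.

Aligns short candidate binding regions by center-star alignment, derives the
majority consensus, folds it with the Nussinov maximum-pairing program, and
measures the primary-sequence distance from a motif span to the nearest
AUUUA pentamer in a UTR.
"""

import ripscan as rs

# three near-identical candidate regions (one internal deletion each)
base = "UAAUUUUUAUGUGUAAUUU"
regions = [("r1", base), ("r2", base[:7] + base[8:]), ("r3", base[:14] + base[15:])]

ids, rows = rs.align_regions(regions)
motif = rs.consensus_from_alignment(ids, rows)
print("alignment:")
for rid, row in zip(ids, rows):
    print(f"  {rid}  {row}")
print(f"consensus: {motif.consensus}")
print(f"structure: {motif.structure}   ({rs.nussinov_fold(motif.consensus).n_pairs} pairs)")
print(f"consensus GC: {motif.gc * 100:.0f}%  (an AU-rich hairpin)")

# distance from a motif span to the nearest ARE on the primary sequence
utr = "G" * 120 + "AUUUA" + "G" * 40 + motif.consensus + "G" * 30
start = utr.find(motif.consensus)
d = rs.motif_are_distance("demo_utr", utr, (start, start + len(motif.consensus)))
print(f"motif span {d.motif_span} is {d.distance} nt from the nearest pentamer "
      f"(within 165 nt: {d.within_165})")
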