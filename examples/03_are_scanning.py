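"""Profile 3'UTRs for AU-rich elements and compare bound vs control groups.

Simulates an AU-rich bound group (33% GC, planted pentamers) and a
GC-typical control group, profiles each UTR (pentamer count, consecutive
pentamers, U-stretches, GC, ARE class), and tests the prevalence contrasts
with the two-sided proportion test. A discriminative k-mer search then
recovers the AUUUA signal directly from the sequences.
"""

import ripscan as rs

bound_recs, _ = rs.simulate_utrs(rs.UtrSimConfig(
    n_sequences=120, gc_target=0.33, pentamer_rate=2.0, u_stretch_prob=0.07,
    id_prefix="bound", seed=10))
ctrl_recs, _ = rs.simulate_utrs(rs.UtrSimConfig(
    n_sequences=120, gc_target=0.46, pentamer_rate=0.0, u_stretch_prob=0.02,
    id_prefix="ctrl", seed=11))

bound = [rs.canonicalize(s, i) for i, s in bound_recs]
ctrl = [rs.canonicalize(s, i) for i, s in ctrl_recs]

one = rs.profile(bound[0])
print(f"example UTR {one.id}: {one.pentamer_count} pentamers, "
      f"max U-run {one.max_u_run}, GC {one.gc:.2f}, ARE class {one.are_class}")

summary = rs.group_are_summary(bound, ctrl)
for feat, (fb, fc) in summary.fractions.items():
    p = summary.tests[feat].p
    print(f"{feat:22s} bound {fb:.2f} vs control {fc:.2f}  (p = {p:.2g})")
print(f"mean GC: bound {summary.mean_gc['bound']:.2f}, "
      f"control {summary.mean_gc['control']:.2f}")

kmers = rs.discriminative_kmers([u.sequence for u in bound],
                                [u.sequence for u in ctrl], e_threshold=1e-5)
print("top discriminative k-mers:",
      ", ".join(r.motif for r in kmers[:5]) or "(none)")
# pentamer prevalence separates the groups at vanishing p, and AU-rich words
# dominate the discriminative ranking, as expected for an ARE-binding protein
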