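"""Loop detection, aggregate peak analysis and functional classes.

Plants 30 focal loops on a 5 Mb segment at 10 kb, calls them with the
donut-filter detector, measures the aggregate center enrichment, and
classifies anchors by enhancer/promoter content.
"""

import hicscape as hs

spec = hs.make_loop_spec(n_loops=30, intensity=4.0, seed=0)
bal = hs.kr_balance(hs.simulate_contact_map(spec, seed=1))
calls = hs.call_loops(bal, fdr=0.1)

truth = {(a, b) for _c, a, b, _i in spec.loops}
hits = sum(1 for r in calls.loops.itertuples()
           if any(abs(r.bin1 - a) <= 1 and abs(r.bin2 - b) <= 1
                  for a, b in truth))
_mat, apa_score = hs.apa(bal, calls)
print(f"planted 30 loops -> called {len(calls)}, {hits} within one bin of truth")
print(f"APA score (center / lower-left corner): {apa_score:.2f}  (1 = no enrichment)")

ann = hs.simulate_annotations(spec, hs.EffectModel(loop_gene_ratio=3.0), seed=2)
enhancers = hs.define_enhancers(ann.h3k27ac_peaks, ann.h3k4me3_peaks)
promoters = hs.promoter_regions(ann.tss, spec.bins.chrom_sizes)
classes = hs.classify_anchors(calls, enhancers, promoters)
print("loop classes:", classes["loop_class"].value_counts().to_dict())

res = hs.loop_gene_expression(calls, promoters, ann.expression["adult"])
print(f"median FPKM in loops {res['median_in']:.2f} vs outside "
      f"{res['median_out']:.2f} (rank-sum p = {res['p_value']:.3g})")
print("Loops wire promoters to enhancers; genes at called anchors carry the")
print("planted occupancy-dependent expression boost.")
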