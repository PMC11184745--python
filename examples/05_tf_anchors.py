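"""TF occupancy on loop anchors and its expression consequences.

Plants 300 promoter-connected loops whose anchors carry TF peaks at 60 %
probability, with expression multipliers (4, 2, 1) for genes whose best
loop has both / one / neither anchor bound, then recovers the enrichment
and the ordering.
"""

import hicscape as hs
from hicscape.simulate import loopset_from_spec

spec = hs.make_loop_spec(n_bins=5000, n_loops=300, min_sep=20, max_sep=200,
                         seed=8)
loops = loopset_from_spec(spec)
ann = hs.simulate_annotations(spec, hs.EffectModel(occupancy=(4, 2, 1)),
                              seed=8, n_genes=300)

enr = hs.anchor_peak_enrichment(ann.tf_peaks, loops.anchors_bed(),
                                spec.bins.chrom_sizes, n_rand=500, seed=1)
print(f"TF peaks on anchors: observed fraction {enr['observed']:.2f} vs "
      f"random background {enr['background'].mean():.2f} "
      f"(empirical p = {enr['p_value']:.3g})")

promoters = hs.promoter_regions(ann.tss, spec.bins.chrom_sizes)
classes = hs.classify_gene_occupancy(loops, promoters, ann.tf_peaks)
summary = hs.occupancy_expression_summary(classes, ann.expression["adult"],
                                          fpkm_expressed=2.0)
for cls in ("both", "one", "none"):
    info = summary["classes"][cls]
    print(f"  {cls:>4} anchors bound: n={info['n']:3d}  "
          f"expressed fraction {info['expressed_fraction']:.2f}  "
          f"median FPKM {info['median_expressed']:.2f}")
for name, t in summary["tests"].items():
    print(f"  {name}: BH-adjusted q = {t['q']:.3g}")
print("Genes looped to doubly-bound anchors are expressed more often and")
print("more highly - the planted occupancy effect, read back from the data.")
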