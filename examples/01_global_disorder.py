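"""Contact decay, Jensen-Shannon divergence and Von Neumann entropy.

Simulates a full-strength and a relaxed (30 % contrast) version of the
same 20 Mb chromosome, then quantifies how similar their distance-decay
curves are and how disordered each map is.
"""

import numpy as np

import hicscape as hs

base = hs.make_checkerboard_spec(n_bins=400, bin_size=50_000, contrast=0.6,
                                 depth=1_000_000, noise_sigma=0.2)
specs, (relaxed, full) = hs.simulate_stage_series(
    base, [hs.StageEdit(contrast_scale=0.3), hs.StageEdit()], seeds=[1, 2])

kw = dict(dmin=100_000, dmax=20_000_000, nbins=200)
curve_relaxed = hs.contact_decay_curve(relaxed, **kw)
curve_full = hs.contact_decay_curve(full, **kw)
jsd = hs.jensen_shannon_divergence(curve_relaxed, curve_full)

vne_relaxed = hs.von_neumann_entropy(hs.coarsen_map(relaxed, 2), "chr1")
vne_full = hs.von_neumann_entropy(hs.coarsen_map(full, 2), "chr1")

print(f"JSD between decay curves : {jsd:.5f}   (0 = identical, ln2 = disjoint)")
print(f"VNE relaxed stage        : {vne_relaxed:.3f}")
print(f"VNE full-strength stage  : {vne_full:.3f}   (bound: ln 200 = {np.log(200):.3f})")
print("The two stages share the same decay law, so the JSD is small; the")
print("entropies sit well below the ln(n) bound because both maps carry")
print("long-range structure the correlation spectrum concentrates into few modes.")
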