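"""Synthetic Hi-C generator with planted structure.

A :class:`StructureSpec` describes a ground-truth chromatin architecture:
a power-law contact-decay background, an A/B compartment checkerboard with
a contrast parameter, TAD blocks with an intra-TAD enrichment factor,
focal loops with per-loop intensities, sequencing depth, multiplicative
log-normal noise and a trans-contact fraction. Maps are drawn by Poisson
sampling pixel rates; with ``noise_sigma=0`` the expected-rate map can be
used directly as an infinite-depth limit.

The paired annotation generator produces TSS/gene tables, histone/ATAC/TF
peak sets and per-stage expression with occupancy-dependent effects, so
that every downstream statistic has recoverable planted parameters.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contact import ContactMap
from .genome import GenomeBins

__all__ = [
    "StructureSpec",
    "StageEdit",
    "EffectModel",
    "AnnotationBundle",
    "expected_rate_map",
    "simulate_contact_map",
    "simulate_stage_series",
    "simulate_annotations",
    "make_checkerboard_spec",
    "make_tad_spec",
    "make_loop_spec",
    "save_spec",
    "load_spec",
]


@dataclass
class StructureSpec:
    """Ground-truth description of a planted contact-map architecture."""

    bins: GenomeBins
    decay_exponent: float = 1.0
    compartment_labels: dict[str, np.ndarray] = field(default_factory=dict)
    contrast: float = 0.0
    tad_boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    tad_factor: float = 1.0
    loops: list[tuple[str, int, int, float]] = field(default_factory=list)
    depth: float = 1e6
    noise_sigma: float = 0.0
    trans_fraction: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.contrast < 1.0:
            raise ValueError("contrast must lie in [0, 1) to keep rates positive")
        if self.tad_factor < 1.0:
            raise ValueError("tad_factor must be >= 1")
        if not 0.0 <= self.trans_fraction < 1.0:
            raise ValueError("trans_fraction must lie in [0, 1)")
        if self.depth < 0:
            raise ValueError("depth must be nonnegative")
        for chrom, lab in self.compartment_labels.items():
            if len(lab) != self.bins.n_bins(chrom):
                raise ValueError(f"label track length mismatch on {chrom}")
            if not set(np.unique(lab)) <= {"A", "B"}:
                raise ValueError("labels must be 'A' or 'B'")
        for chrom, bd in self.tad_boundaries.items():
            bd = np.asarray(bd)
            if bd.size and (np.any(np.diff(bd) <= 0)
                            or bd[0] < 0 or bd[-1] >= self.bins.n_bins(chrom)):
                raise ValueError(f"boundaries on {chrom} must be strictly "
                                 "increasing and inside the chromosome")
        for chrom, a, b, inten in self.loops:
            n = self.bins.n_bins(chrom)
            if not (0 <= a < b < n):
                raise ValueError(f"loop anchors ({a}, {b}) invalid on {chrom}")
            if inten < 1.0:
                raise ValueError("loop intensity must be >= 1")

    def tad_ids(self, chrom: str) -> np.ndarray:
        """Per-bin TAD index; a boundary bin belongs to the TAD on its left."""
        n = self.bins.n_bins(chrom)
        bd = np.asarray(self.tad_boundaries.get(chrom, []), dtype=int)
        return np.searchsorted(bd, np.arange(n), side="left")


@dataclass
class StageEdit:
    """Structured perturbation applied to a base spec for one stage.

    Scale factors act on the *excess* structure: ``contrast_scale`` scales
    the compartment contrast, ``tad_scale`` scales (tad_factor - 1) and
    ``loop_scale`` scales (intensity - 1), so 0 removes the feature and 1
    leaves it at base strength.
    """

    contrast_scale: float = 1.0
    tad_scale: float = 1.0
    loop_scale: float = 1.0
    label_flips: dict[str, list[int]] = field(default_factory=dict)
    add_boundaries: dict[str, list[int]] = field(default_factory=dict)
    drop_boundaries: dict[str, list[int]] = field(default_factory=dict)
    depth: float | None = None
    trans_fraction: float | None = None

    def apply(self, base: StructureSpec) -> StructureSpec:
        labels = {c: lab.copy() for c, lab in base.compartment_labels.items()}
        for chrom, idxs in self.label_flips.items():
            lab = labels[chrom]
            for i in idxs:
                lab[i] = "A" if lab[i] == "B" else "B"
        bounds = {c: np.asarray(b, dtype=int).copy()
                  for c, b in base.tad_boundaries.items()}
        for chrom, idxs in self.drop_boundaries.items():
            bounds[chrom] = np.setdiff1d(bounds.get(chrom, np.array([], int)), idxs)
        for chrom, idxs in self.add_boundaries.items():
            bounds[chrom] = np.unique(np.concatenate(
                [bounds.get(chrom, np.array([], int)), np.asarray(idxs, int)]))
        loops = [(c, a, b, 1.0 + self.loop_scale * (inten - 1.0))
                 for c, a, b, inten in base.loops]
        return replace(
            base,
            compartment_labels=labels,
            contrast=base.contrast * self.contrast_scale,
            tad_boundaries=bounds,
            tad_factor=1.0 + self.tad_scale * (base.tad_factor - 1.0),
            loops=loops,
            depth=self.depth if self.depth is not None else base.depth,
            trans_fraction=(self.trans_fraction if self.trans_fraction is not None
                            else base.trans_fraction),
        )


# -- rate construction --------------------------------------------------------

def _rate_matrix(spec: StructureSpec, chrom: str) -> np.ndarray:
    n = spec.bins.n_bins(chrom)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    rate = (1.0 + d).astype(float) ** (-spec.decay_exponent)
    lab = spec.compartment_labels.get(chrom)
    if lab is not None and spec.contrast > 0:
        same = np.equal.outer(lab, lab)
        rate *= np.where(same, 1.0 + spec.contrast, 1.0 - spec.contrast)
    if spec.tad_factor > 1.0 and chrom in spec.tad_boundaries:
        tid = spec.tad_ids(chrom)
        rate *= np.where(np.equal.outer(tid, tid), spec.tad_factor, 1.0)
    for lc, a, b, inten in spec.loops:
        if lc == chrom and inten != 1.0:
            rate[a, b] *= inten
            rate[b, a] *= inten
    return rate


def expected_rate_map(spec: StructureSpec) -> ContactMap:
    """Noise-free expected contact map (infinite-depth limit), scaled so
    the total expected cis count equals ``depth * (1 - trans_fraction)``."""
    raw = {c: _rate_matrix(spec, c) for c in spec.bins.chroms}
    total = sum((m.sum() + np.trace(m)) / 2.0 for m in raw.values())
    cis_depth = spec.depth * (1.0 - spec.trans_fraction)
    scale = cis_depth / total if total > 0 else 0.0
    cmap = ContactMap(bins=spec.bins, counts={c: m * scale for c, m in raw.items()})
    _fill_trans_totals(cmap, spec, rng=None)
    return cmap


def _fill_trans_totals(cmap: ContactMap, spec: StructureSpec, rng) -> None:
    chroms = spec.bins.chroms
    if spec.trans_fraction <= 0 or len(chroms) < 2:
        return
    sizes = np.array([spec.bins.chrom_sizes[c] for c in chroms], dtype=float)
    pairs = [(i, j) for i in range(len(chroms)) for j in range(i + 1, len(chroms))]
    wts = np.array([sizes[i] * sizes[j] for i, j in pairs])
    wts /= wts.sum()
    total = spec.depth * spec.trans_fraction
    for (i, j), w in zip(pairs, wts):
        mu = total * w
        val = float(rng.poisson(mu)) if rng is not None else mu
        if val > 0:
            cmap.trans_totals[(chroms[i], chroms[j])] = val


def simulate_contact_map(spec: StructureSpec, seed: int) -> ContactMap:
    """Poisson-sample a symmetric contact map from the spec's pixel rates.

    Pixel rates are the expected-rate map multiplied by i.i.d. log-normal
    noise exp(sigma*Z - sigma^2/2) (mean one) before sampling; only the
    upper triangle is drawn and mirrored.
    """
    rng = np.random.default_rng(seed)
    expected = expected_rate_map(spec)
    out = ContactMap.empty(spec.bins)
    for chrom, rate in expected.counts.items():
        n = rate.shape[0]
        iu, ju = np.triu_indices(n)
        lam = rate[iu, ju]
        if spec.noise_sigma > 0:
            z = rng.standard_normal(lam.size)
            lam = lam * np.exp(spec.noise_sigma * z - spec.noise_sigma ** 2 / 2.0)
        draws = rng.poisson(lam).astype(float)
        m = out.counts[chrom]
        m[iu, ju] = draws
        m[ju, iu] = draws
    _fill_trans_totals(out, spec, rng=rng)
    return out


def simulate_stage_series(base: StructureSpec, perturbations: list[StageEdit],
                          seeds: list[int]) -> tuple[list[StructureSpec], list[ContactMap]]:
    """One map per stage; stage i uses ``perturbations[i]`` applied to the
    base spec and ``seeds[i]``. Returns the per-stage ground-truth specs
    alongside the sampled maps."""
    if len(perturbations) != len(seeds):
        raise ValueError("need one seed per stage")
    specs = [edit.apply(base) for edit in perturbations]
    maps = [simulate_contact_map(s, seed) for s, seed in zip(specs, seeds)]
    return specs, maps


# -- annotations --------------------------------------------------------------

@dataclass
class EffectModel:
    """Multiplicative expression effects.

    ``occupancy``: FPKM multipliers for genes whose best promoter-connecting
    loop has TF peaks on both / one / neither anchor. ``ab_ratio``: mean
    FPKM ratio of genes in A- vs B-labeled bins. ``loop_gene_ratio``: extra
    multiplier for genes wired into a loop at all.
    """

    occupancy: tuple[float, float, float] = (4.0, 2.0, 1.0)
    ab_ratio: float = 3.0
    loop_gene_ratio: float = 1.0

    def __post_init__(self):
        both, one, none = self.occupancy
        if not both >= one >= none > 0:
            raise ValueError("occupancy multipliers must satisfy both >= one >= none > 0")


@dataclass
class AnnotationBundle:
    """Synthetic annotation set paired with a StructureSpec."""

    tss: pd.DataFrame
    h3k27ac_peaks: pd.DataFrame
    h3k4me3_peaks: pd.DataFrame
    atac_peaks: pd.DataFrame
    tf_peaks: pd.DataFrame
    expression: pd.DataFrame
    true_loops: list[tuple[str, int, int, float]]
    truth: dict = field(default_factory=dict)


def simulate_annotations(spec: StructureSpec, effect_model: EffectModel,
                         seed: int, n_genes: int = 300,
                         stages: tuple[str, ...] = ("nascent", "fetal", "adult"),
                         tf_anchor_fraction: float = 0.6,
                         n_background_tf_peaks: int = 50,
                         peak_width: int = 1500,
                         atac_a_bias: float = 4.0,
                         n_atac_peaks: int = 400,
                         base_fpkm_mean: float = 1.0,
                         fpkm_sigma: float = 1.0) -> AnnotationBundle:
    """Generate TSS, peaks and per-stage expression with planted effects.

    One gene TSS is planted inside the first anchor of each loop (so loop-
    connected genes exist by construction); remaining genes are uniform.
    Each loop is independently assigned a TF occupancy state (both / one /
    none anchors bound, probability ``tf_anchor_fraction`` per anchor) and
    the corresponding expression multiplier is applied to its gene.
    """
    rng = np.random.default_rng(seed)
    bs = spec.bins.bin_size
    chroms = spec.bins.chroms
    sizes = spec.bins.chrom_sizes

    # --- genes: one per loop anchor1, rest uniform
    gene_rows = []
    loop_of_gene: dict[str, int] = {}
    for k, (chrom, a, _b, _i) in enumerate(spec.loops):
        pos = a * bs + bs // 2
        gid = f"g{k:04d}"
        gene_rows.append((chrom, pos, gid))
        loop_of_gene[gid] = k
    n_extra = max(0, n_genes - len(gene_rows))
    probs = np.array([sizes[c] for c in chroms], float)
    probs /= probs.sum()
    extra_chroms = rng.choice(len(chroms), size=n_extra, p=probs)
    for k, ci in enumerate(extra_chroms):
        chrom = chroms[ci]
        pos = int(rng.integers(0, sizes[chrom]))
        gene_rows.append((chrom, pos, f"g{len(spec.loops) + k:04d}"))
    tss = pd.DataFrame(gene_rows, columns=["chrom", "start", "name"])
    tss["end"] = tss["start"] + 1
    tss = tss[["chrom", "start", "end", "name"]]

    # --- TF occupancy per loop
    bound = rng.random((len(spec.loops), 2)) < tf_anchor_fraction
    tf_rows = []
    for k, (chrom, a, b, _i) in enumerate(spec.loops):
        for anchor_bin, is_bound in zip((a, b), bound[k]):
            if is_bound:
                center = anchor_bin * bs + bs // 2
                tf_rows.append((chrom, max(0, center - peak_width // 2),
                                min(sizes[chrom], center + peak_width // 2)))
    for _ in range(n_background_tf_peaks):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        s = int(rng.integers(0, sizes[chrom] - peak_width))
        tf_rows.append((chrom, s, s + peak_width))
    tf_peaks = pd.DataFrame(tf_rows, columns=["chrom", "start", "end"])

    # --- histone peaks: K4me3 at every TSS; K27ac at loop anchor2 (distal
    # enhancers) plus background, some of it TSS-proximal
    k4_rows = [(r.chrom, max(0, r.start - 500), r.start + 500)
               for r in tss.itertuples()]
    h3k4me3 = pd.DataFrame(k4_rows, columns=["chrom", "start", "end"])
    k27_rows = []
    for chrom, _a, b, _i in spec.loops:
        center = b * bs + bs // 2
        k27_rows.append((chrom, max(0, center - peak_width // 2),
                         min(sizes[chrom], center + peak_width // 2)))
    for _ in range(n_background_tf_peaks):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        s = int(rng.integers(0, sizes[chrom] - peak_width))
        k27_rows.append((chrom, s, s + peak_width))
    h3k27ac = pd.DataFrame(k27_rows, columns=["chrom", "start", "end"])

    # --- ATAC peaks biased toward A bins
    atac_rows = []
    for _ in range(n_atac_peaks):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        lab = spec.compartment_labels.get(chrom)
        for _try in range(200):
            s = int(rng.integers(0, sizes[chrom] - peak_width))
            if lab is None:
                break
            in_a = lab[min(s // bs, len(lab) - 1)] == "A"
            accept = 1.0 if in_a else 1.0 / atac_a_bias
            if rng.random() < accept:
                break
        atac_rows.append((chrom, s, s + peak_width))
    atac = pd.DataFrame(atac_rows, columns=["chrom", "start", "end"])

    # --- expression
    mult_both, mult_one, mult_none = effect_model.occupancy
    gene_class = {}
    base_mu = np.log(base_fpkm_mean)
    expr = {}
    for gid, chrom, pos in zip(tss["name"], tss["chrom"], tss["start"]):
        mu = base_mu
        lab = spec.compartment_labels.get(chrom)
        if lab is not None and lab[min(pos // bs, len(lab) - 1)] == "A":
            mu += np.log(effect_model.ab_ratio)
        if gid in loop_of_gene:
            k = loop_of_gene[gid]
            nb = int(bound[k].sum())
            cls = ("none", "one", "both")[nb]
            mu += np.log((mult_none, mult_one, mult_both)[nb])
            mu += np.log(effect_model.loop_gene_ratio)
        else:
            cls = "no_loop"
        gene_class[gid] = cls
        vals = np.exp(mu + fpkm_sigma * rng.standard_normal(len(stages)))
        expr[gid] = vals
    expression = pd.DataFrame.from_dict(expr, orient="index", columns=list(stages))
    expression.index.name = "gene"

    return AnnotationBundle(
        tss=tss, h3k27ac_peaks=h3k27ac, h3k4me3_peaks=h3k4me3,
        atac_peaks=atac, tf_peaks=tf_peaks, expression=expression,
        true_loops=list(spec.loops),
        truth={"gene_class": gene_class,
               "loop_bound_anchors": bound.sum(axis=1).tolist(),
               "loop_of_gene": loop_of_gene},
    )


def loopset_from_spec(spec: StructureSpec):
    """The planted loop list as a LoopSet (ground-truth calls), for
    analyses that consume loops without detecting them."""
    from .loops import LoopSet
    df = pd.DataFrame(
        [(c, a, b, i, np.nan, 0.0) for c, a, b, i in spec.loops],
        columns=["chrom", "bin1", "bin2", "observed", "expected", "qvalue"])
    return LoopSet(loops=df, resolution=spec.bins.bin_size)


# -- convenience builders -----------------------------------------------------

def make_checkerboard_spec(n_bins: int = 400, block: int = 20,
                           bin_size: int = 100_000, contrast: float = 0.6,
                           depth: float = 1e6, noise_sigma: float = 0.0,
                           decay_exponent: float = 1.0,
                           chrom: str = "chr1") -> StructureSpec:
    """Single chromosome with alternating A/B blocks."""
    labels = np.where((np.arange(n_bins) // block) % 2 == 0, "A", "B")
    return StructureSpec(
        bins=GenomeBins({chrom: n_bins * bin_size}, bin_size),
        decay_exponent=decay_exponent,
        compartment_labels={chrom: labels},
        contrast=contrast, depth=depth, noise_sigma=noise_sigma,
    )


def make_tad_spec(n_bins: int = 400, n_boundaries: int = 9,
                  bin_size: int = 50_000, tad_factor: float = 3.0,
                  depth: float = 1e6, noise_sigma: float = 0.0,
                  chrom: str = "chr1") -> StructureSpec:
    """Single chromosome with evenly spaced TAD boundaries."""
    bd = np.linspace(0, n_bins, n_boundaries + 2, dtype=int)[1:-1]
    return StructureSpec(
        bins=GenomeBins({chrom: n_bins * bin_size}, bin_size),
        tad_boundaries={chrom: bd}, tad_factor=tad_factor,
        depth=depth, noise_sigma=noise_sigma,
    )


def make_loop_spec(n_bins: int = 500, n_loops: int = 30, bin_size: int = 10_000,
                   intensity: float = 4.0, depth: float = 5e6,
                   noise_sigma: float = 0.0, min_sep: int = 20,
                   max_sep: int = 150, seed: int = 0,
                   chrom: str = "chr1") -> StructureSpec:
    """Single 10 kb-resolution segment with randomly placed focal loops."""
    rng = np.random.default_rng(seed)
    loops: list[tuple[str, int, int, float]] = []
    taken: set[tuple[int, int]] = set()
    while len(loops) < n_loops:
        sep = int(rng.integers(min_sep, max_sep + 1))
        a = int(rng.integers(0, n_bins - sep))
        b = a + sep
        # keep anchors >= 5 bins apart from existing loops so calls are unambiguous
        if any(abs(a - x) < 5 and abs(b - y) < 5 for x, y in taken):
            continue
        taken.add((a, b))
        loops.append((chrom, a, b, intensity))
    return StructureSpec(
        bins=GenomeBins({chrom: n_bins * bin_size}, bin_size),
        loops=loops, depth=depth, noise_sigma=noise_sigma,
    )


# -- flat-config (de)serialization --------------------------------------------

def save_spec(spec: StructureSpec, path) -> None:
    cp = configparser.ConfigParser()
    cp["genome"] = {
        "bin_size": str(spec.bins.bin_size),
        "chrom_sizes": ",".join(f"{c}:{l}" for c, l in spec.bins.chrom_sizes.items()),
    }
    cp["structure"] = {
        "decay_exponent": str(spec.decay_exponent),
        "contrast": str(spec.contrast),
        "tad_factor": str(spec.tad_factor),
        "depth": str(spec.depth),
        "noise_sigma": str(spec.noise_sigma),
        "trans_fraction": str(spec.trans_fraction),
    }
    cp["labels"] = {c: "".join(lab) for c, lab in spec.compartment_labels.items()}
    cp["boundaries"] = {c: ",".join(map(str, bd))
                        for c, bd in spec.tad_boundaries.items()}
    cp["loops"] = {f"loop{k}": f"{c},{a},{b},{i}"
                   for k, (c, a, b, i) in enumerate(spec.loops)}
    with open(path, "w") as fh:
        cp.write(fh)


def load_spec(path) -> StructureSpec:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    sizes = dict(item.split(":") for item in cp["genome"]["chrom_sizes"].split(","))
    bins = GenomeBins({c: int(l) for c, l in sizes.items()},
                      int(cp["genome"]["bin_size"]))
    st = cp["structure"]
    labels = {c: np.array(list(v)) for c, v in cp["labels"].items()} if "labels" in cp else {}
    bounds = {c: np.array([int(x) for x in v.split(",") if x], dtype=int)
              for c, v in cp["boundaries"].items()} if "boundaries" in cp else {}
    loops = []
    if "loops" in cp:
        for _k, v in sorted(cp["loops"].items()):
            c, a, b, i = v.split(",")
            loops.append((c, int(a), int(b), float(i)))
    return StructureSpec(
        bins=bins,
        decay_exponent=float(st["decay_exponent"]),
        compartment_labels=labels,
        contrast=float(st["contrast"]),
        tad_boundaries=bounds,
        tad_factor=float(st["tad_factor"]),
        loops=loops,
        depth=float(st["depth"]),
        noise_sigma=float(st["noise_sigma"]),
        trans_fraction=float(st["trans_fraction"]),
    )
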