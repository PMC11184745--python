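"""Transcription-factor occupancy statistics on loop anchors.

Covers enrichment of TF ChIP peaks at loop anchors versus length-matched
random regions, classification of promoter-connected genes by TF occupancy
of their best loop (both / one / no bound anchor), the expression
consequences of that occupancy, and loop-score stratification by
bound-anchor count. 'Bound' always means >= 1 bp overlap between an
anchor interval and any TF peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import overlap_pairs, overlaps_any
from .loops import LoopSet

__all__ = [
    "anchor_peak_enrichment",
    "classify_gene_occupancy",
    "occupancy_expression_summary",
    "loop_score_by_occupancy",
]


def anchor_peak_enrichment(tf_peaks: pd.DataFrame, anchors: pd.DataFrame,
                           chrom_sizes: dict[str, int], n_rand: int = 1000,
                           seed: int = 0) -> dict:
    """Observed fraction of TF peaks overlapping any anchor, against a
    background of ``n_rand`` draws of length-matched random regions.

    Each random region is drawn uniformly on the same chromosome as the
    anchor it is matched to (regions may overlap each other); the
    empirical p-value is the fraction of draws reaching the observed
    fraction, floored at 1/(n_rand+1).
    """
    if len(tf_peaks) == 0:
        return {"observed": 0.0, "background": np.array([]),
                "p_value": float("nan"), "flag": "empty peak set"}
    for _c, r in anchors.iterrows():
        if r["end"] - r["start"] > chrom_sizes[r["chrom"]]:
            raise ValueError("anchor longer than its chromosome")
    rng = np.random.default_rng(seed)
    observed = float(overlaps_any(tf_peaks, anchors).mean())
    lengths = (anchors["end"] - anchors["start"]).to_numpy()
    chroms = anchors["chrom"].to_numpy()
    maxstart = np.array([chrom_sizes[c] for c in chroms]) - lengths
    background = np.empty(n_rand)
    for t in range(n_rand):
        starts = rng.integers(0, maxstart + 1)
        rand = pd.DataFrame({"chrom": chroms, "start": starts,
                             "end": starts + lengths})
        background[t] = overlaps_any(tf_peaks, rand).mean()
    p = (np.sum(background >= observed) + 1) / (n_rand + 1)
    return {"observed": observed, "background": background, "p_value": float(p)}


def _bound_anchor_counts(loops: LoopSet, tf_peaks: pd.DataFrame) -> np.ndarray:
    """Per loop: how many of its two anchors carry a TF peak (0/1/2)."""
    anchors = loops.anchors_bed()
    if len(anchors) == 0:
        return np.zeros(0, dtype=int)
    bound = overlaps_any(anchors, tf_peaks) if len(tf_peaks) else np.zeros(len(anchors), bool)
    return bound[0::2].astype(int) + bound[1::2].astype(int)


def classify_gene_occupancy(loops: LoopSet, promoter_regions: pd.DataFrame,
                            tf_peaks: pd.DataFrame) -> pd.DataFrame:
    """Gene-level TF occupancy classes over promoter-connecting loops.

    A loop connects a gene when either anchor overlaps the gene's promoter
    region. The gene's class is taken from its best such loop: 'both' if
    any connecting loop has both anchors bound, else 'one' if any has
    exactly one, else 'none'; genes without a connecting loop are
    'no_loop'. Returns gene, class, and supporting loop ids.
    """
    promoter_regions = promoter_regions.reset_index(drop=True)
    n_bound = _bound_anchor_counts(loops, tf_peaks)
    genes = promoter_regions["name"].to_numpy()
    best = {g: -1 for g in genes}
    support: dict[str, list[int]] = {g: [] for g in genes}
    if len(loops):
        anchors = loops.anchors_bed()
        hits = overlap_pairs(promoter_regions, anchors)
        for qi, si in zip(hits["query_index"], hits["subject_index"]):
            gene = promoter_regions.loc[qi, "name"]
            loop_id = int(anchors.loc[si, "loop_id"])
            support[gene].append(loop_id)
            best[gene] = max(best[gene], int(n_bound[loop_id]))
    cls = {-1: "no_loop", 0: "none", 1: "one", 2: "both"}
    return pd.DataFrame({
        "gene": genes,
        "occupancy": [cls[best[g]] for g in genes],
        "loops": [sorted(set(support[g])) for g in genes],
    })


def occupancy_expression_summary(classes: pd.DataFrame, expression: pd.Series,
                                 fpkm_expressed: float = 2.0) -> dict:
    """Per-occupancy-class expressed fraction (FPKM >= threshold),
    expression distributions among expressed genes, and BH-corrected
    two-sided rank-sum comparisons both-vs-one and one-vs-none."""
    out: dict = {"classes": {}, "tests": {}}
    groups = {}
    for cls in ("both", "one", "none", "no_loop"):
        genes = classes.loc[classes["occupancy"] == cls, "gene"]
        vals = expression[expression.index.isin(genes)].to_numpy(float)
        expressed = vals[vals >= fpkm_expressed]
        groups[cls] = vals
        out["classes"][cls] = {
            "n": int(vals.size),
            "expressed_fraction": float((vals >= fpkm_expressed).mean())
            if vals.size else np.nan,
            "expressed_values": expressed,
            "median_expressed": float(np.median(expressed)) if expressed.size else np.nan,
        }
    pvals, names = [], []
    for a, b in (("both", "one"), ("one", "none")):
        va, vb = groups[a], groups[b]
        if va.size and vb.size:
            _s, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            pvals.append(p)
            names.append(f"{a}_vs_{b}")
    if pvals:
        order = np.argsort(pvals, kind="stable")
        m = len(pvals)
        adj = np.minimum.accumulate(
            (np.asarray(pvals)[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        for k, i in enumerate(order):
            out["tests"][names[i]] = {"p": float(pvals[i]),
                                      "q": float(min(adj[k], 1.0))}
    return out


def loop_score_by_occupancy(loop_scores: np.ndarray, loops: LoopSet,
                            tf_peaks: pd.DataFrame) -> dict:
    """Loop-score distributions stratified by bound-anchor count (2/1/0)
    with pairwise two-sided rank-sum comparisons."""
    n_bound = _bound_anchor_counts(loops, tf_peaks)
    scores = np.asarray(loop_scores, dtype=float)
    if scores.size != len(loops):
        raise ValueError("one score per loop required")
    strata = {k: scores[n_bound == k] for k in (2, 1, 0)}
    tests = {}
    for a, b in ((2, 1), (1, 0)):
        if strata[a].size and strata[b].size:
            _s, p = stats.mannwhitneyu(strata[a], strata[b], alternative="two-sided")
            tests[f"{a}_vs_{b}"] = float(p)
    return {
        "strata": strata,
        "medians": {k: (float(np.median(v)) if v.size else np.nan)
                    for k, v in strata.items()},
        "tests": tests,
    }
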