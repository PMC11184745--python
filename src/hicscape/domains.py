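"""Insulation scores, TAD boundary calling, aggregation, sharing and
variability ranking.

The insulation score of bin i is the log2 ratio of the summed balanced
contacts in a square window spanning the bin (upstream x downstream) to
the chromosome mean of those sums; boundaries are strength-filtered local
minima found by a delta-vector zero-crossing rule, and TADs are the
inter-boundary intervals of at least three bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .contact import ContactMap, OEMatrix
from .genome import GenomeBins

__all__ = [
    "InsulationTrack",
    "insulation_score",
    "call_boundaries",
    "aggregate_boundary_profile",
    "aggregate_boundary_matrix",
    "tads_to_frame",
    "shared_tads",
    "boundary_variability",
]

MIN_TAD_BINS = 3


@dataclass
class InsulationTrack:
    bins: GenomeBins
    score: dict[str, np.ndarray]      # NaN where undefined
    window: int                        # bp
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    boundary_strength: dict[str, np.ndarray] = field(default_factory=dict)
    tads: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def insulation_score(cmap: ContactMap, window: int = 500_000) -> InsulationTrack:
    """Per-bin insulation score from a balanced map.

    The window sum of bin i covers pairs (a, b) with a in [i-w, i-1] and
    b in [i+1, i+w] (w = window / bin_size). Scores are missing where the
    window crosses a chromosome end or >= 50 % of the window bins are
    masked, and are log2 of the sum over the chromosome mean of defined
    sums.
    """
    if window % cmap.bins.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // cmap.bins.bin_size
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    scores = {}
    for chrom in cmap.bins.chroms:
        b = cmap.balanced(chrom)
        mask = np.isnan(cmap.weights[chrom])
        n = b.shape[0]
        sums = np.full(n, np.nan)
        for i in range(w, n - w):
            up = slice(i - w, i)
            dn = slice(i + 1, i + 1 + w)
            n_masked = mask[up].sum() + mask[dn].sum()
            if n_masked >= w:  # >= 50 % of the 2w window bins
                continue
            sums[i] = b[up, dn].sum()
        defined = np.isfinite(sums) & (sums > 0)
        score = np.full(n, np.nan)
        if defined.any():
            mean = sums[defined].mean()
            score[defined] = np.log2(sums[defined] / mean)
        scores[chrom] = score
    return InsulationTrack(bins=cmap.bins, score=scores, window=window)


def _delta_vector(score: np.ndarray, d: int) -> np.ndarray:
    """Mean score over the d bins right of i minus the d bins left of i."""
    n = score.size
    delta = np.full(n, np.nan)
    for i in range(d, n - d):
        left = score[i - d:i]
        right = score[i + 1:i + 1 + d]
        if np.isnan(left).all() or np.isnan(right).all():
            continue
        delta[i] = np.nanmean(right) - np.nanmean(left)
    return delta


def call_boundaries(track: InsulationTrack, delta_window: int = 2,
                    strength_min: float = 0.1) -> InsulationTrack:
    """Boundary and TAD calls from an insulation track.

    A boundary sits at a negative-to-positive zero crossing of the delta
    vector (an insulation minimum) whose strength — the local delta swing
    (max after minus min before, within ``delta_window``) — reaches
    ``strength_min``. TADs are the strictly-inter-boundary intervals of
    at least three bins; boundary bins belong to no TAD, and gaps shorter
    than three bins are left unassigned (suppression tie-break).
    """
    d = delta_window
    boundaries, strengths, tads = {}, {}, {}
    for chrom, score in track.score.items():
        delta = _delta_vector(score, d)
        n = score.size
        cand, stren = [], []
        for i in range(n - 1):
            if not (np.isfinite(delta[i]) and np.isfinite(delta[i + 1])):
                continue
            if delta[i] < 0 <= delta[i + 1]:
                at = i if _safe(score[i]) <= _safe(score[i + 1]) else i + 1
                lo = np.nanmin(delta[max(0, i - d + 1):i + 1])
                hi = np.nanmax(delta[i + 1:i + 1 + d])
                s = hi - lo
                if s >= strength_min:
                    cand.append(at)
                    stren.append(s)
        bd = np.asarray(cand, dtype=int)
        boundaries[chrom] = bd
        strengths[chrom] = np.asarray(stren)
        edges = np.concatenate([[-1], bd, [n]])
        iv = []
        for a, b in zip(edges[:-1], edges[1:]):
            start, end = a + 1, b  # bins strictly between boundaries
            if end - start >= MIN_TAD_BINS:
                iv.append((int(start), int(end)))
        tads[chrom] = iv
    return InsulationTrack(bins=track.bins, score=track.score,
                           window=track.window, boundaries=boundaries,
                           boundary_strength=strengths, tads=tads)


def _safe(x: float) -> float:
    return x if np.isfinite(x) else np.inf


def aggregate_boundary_profile(track: InsulationTrack,
                               boundaries: dict[str, np.ndarray],
                               flank: int = 10) -> np.ndarray:
    """Mean insulation score per offset in [-flank, +flank] around
    boundaries; boundaries whose window leaves the chromosome are skipped."""
    prof = np.zeros(2 * flank + 1)
    count = np.zeros(2 * flank + 1)
    for chrom, bd in boundaries.items():
        score = track.score[chrom]
        n = score.size
        for b in bd:
            if b - flank < 0 or b + flank >= n:
                continue
            seg = score[b - flank:b + flank + 1]
            ok = np.isfinite(seg)
            prof[ok] += seg[ok]
            count[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, prof / np.maximum(count, 1), np.nan)


def aggregate_boundary_matrix(oe: OEMatrix, boundaries: dict[str, np.ndarray],
                              flank: int = 10) -> tuple[np.ndarray, dict[str, float]]:
    """Mean O/E submatrix centered on boundaries, with corner summaries:
    intra-TAD = mean of the upper-left + lower-right corner blocks,
    inter-TAD = upper-right + lower-left blocks (block size flank // 2)."""
    size = 2 * flank + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    skipped = 0
    for chrom, bd in boundaries.items():
        vals = oe.values[chrom]
        n = vals.shape[0]
        for b in bd:
            if b - flank < 0 or b + flank >= n:
                skipped += 1
                continue
            sub = vals[b - flank:b + flank + 1, b - flank:b + flank + 1]
            ok = np.isfinite(sub)
            acc[ok] += sub[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    k = max(1, flank // 2)
    corners = {
        "intra_tad": float(np.nanmean(np.concatenate(
            [mean[:k, :k].ravel(), mean[-k:, -k:].ravel()]))),
        "inter_tad": float(np.nanmean(np.concatenate(
            [mean[:k, -k:].ravel(), mean[-k:, :k].ravel()]))),
        "skipped_boundaries": float(skipped),
    }
    return mean, corners


def tads_to_frame(track: InsulationTrack) -> pd.DataFrame:
    """TAD intervals in bp as a chrom/start/end frame."""
    bs = track.bins.bin_size
    rows = [(chrom, a * bs, min(b * bs, track.bins.chrom_sizes[chrom]))
            for chrom, iv in track.tads.items() for a, b in iv]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def shared_tads(tads_a: pd.DataFrame, tads_b: pd.DataFrame,
                min_frac: float = 0.75) -> dict:
    """Reciprocal-overlap TAD matching.

    A pair is shared when overlap / length >= ``min_frac`` for BOTH
    intervals; matching is one-to-one by best reciprocal overlap
    (greedy on the smaller of the two fractions). Returns shared index
    pairs plus each side's specific indices.
    """
    cand = []
    for ia, ra in tads_a.iterrows():
        sel = tads_b[(tads_b["chrom"] == ra["chrom"])
                     & (tads_b["start"] < ra["end"])
                     & (tads_b["end"] > ra["start"])]
        for ib, rb in sel.iterrows():
            ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            fa = ov / (ra["end"] - ra["start"])
            fb = ov / (rb["end"] - rb["start"])
            if fa >= min_frac and fb >= min_frac:
                cand.append((min(fa, fb), ia, ib))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, pairs = set(), set(), []
    for _score, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib))
    return {
        "shared_pairs": pairs,
        "n_shared": len(pairs),
        "a_specific": sorted(set(tads_a.index) - used_a),
        "b_specific": sorted(set(tads_b.index) - used_b),
    }


def boundary_variability(tracks: list[InsulationTrack], top_k: int = 1000,
                         n_clusters: int = 4) -> pd.DataFrame:
    """Rank boundary bins by cross-stage insulation variability.

    The universe is every bin called as a boundary in ANY stage; bins
    missing a score in any stage are excluded (count in attrs). Rows are
    the per-stage scores; the SD across stages ranks them (descending,
    ties broken by genome order), the top ``top_k`` are kept, rows are
    standardized and clustered (hierarchical, complete linkage,
    Euclidean) into ``n_clusters`` groups.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two stages")
    bins = tracks[0].bins
    universe: set[tuple[str, int]] = set()
    for tr in tracks:
        if tr.bins != bins:
            raise ValueError("tracks must share binning")
        for chrom, bd in tr.boundaries.items():
            universe.update((chrom, int(b)) for b in bd)
    rows, excluded = [], 0
    for chrom, b in sorted(universe):
        vals = np.array([tr.score[chrom][b] for tr in tracks])
        if np.isnan(vals).any():
            excluded += 1
            continue
        rows.append((chrom, b, vals))
    if not rows:
        raise ValueError("no boundary bin scored in every stage")
    sd = np.array([v.std(ddof=0) for _c, _b, v in rows])
    order = np.argsort(-sd, kind="stable")[:top_k]
    chosen = [rows[i] for i in order]
    mat = np.stack([v for _c, _b, v in chosen])
    mu = mat.mean(axis=1, keepdims=True)
    sig = mat.std(axis=1, keepdims=True)
    z = np.where(sig > 0, (mat - mu) / np.where(sig == 0, 1, sig), 0.0)
    if len(chosen) > n_clusters:
        labels = fcluster(linkage(z, method="complete", metric="euclidean"),
                          t=n_clusters, criterion="maxclust")
    else:
        labels = np.arange(1, len(chosen) + 1)
    df = pd.DataFrame({
        "chrom": [c for c, _b, _v in chosen],
        "bin": [b for _c, b, _v in chosen],
        "sd": sd[order],
        "cluster": labels,
    })
    for k, tr in enumerate(tracks):
        df[f"is_stage{k}"] = mat[:, k]
    df.attrs["excluded_bins"] = excluded
    return df
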