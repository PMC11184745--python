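"""Binned Hi-C contact maps: I/O, balancing, O/E normalization, depth
manipulation, and reproducibility scoring.

The in-memory model keeps one dense symmetric cis matrix per chromosome
(desk-scale genomes; hundreds to a few thousand bins per chromosome) plus
per-chromosome-pair trans totals used only for the cis/trans ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins

__all__ = [
    "ContactMap",
    "OEMatrix",
    "read_triplets",
    "read_dense",
    "write_triplets",
    "kr_balance",
    "observed_over_expected",
    "downsample",
    "reproducibility_score",
    "coarsen_map",
]


@dataclass
class ContactMap:
    """Symmetric binned contact matrices with balancing weights.

    Attributes
    ----------
    bins
        The genome binning shared by all chromosomes.
    counts
        chrom -> dense symmetric (n, n) float array of raw counts.
    weights
        chrom -> per-bin balancing weight (NaN on masked bins), or None
        if the map has not been balanced.
    trans_totals
        (chromA, chromB) sorted pair -> total inter-chromosomal count.
    """

    bins: GenomeBins
    counts: dict[str, np.ndarray]
    weights: dict[str, np.ndarray] | None = None
    trans_totals: dict[tuple[str, str], float] = field(default_factory=dict)
    balanced_flag: bool = False

    # -- construction helpers -------------------------------------------------

    @classmethod
    def empty(cls, bins: GenomeBins) -> "ContactMap":
        counts = {c: np.zeros((bins.n_bins(c), bins.n_bins(c))) for c in bins.chroms}
        return cls(bins=bins, counts=counts)

    def copy(self) -> "ContactMap":
        return ContactMap(
            bins=self.bins,
            counts={c: m.copy() for c, m in self.counts.items()},
            weights=None if self.weights is None
            else {c: w.copy() for c, w in self.weights.items()},
            trans_totals=dict(self.trans_totals),
            balanced_flag=self.balanced_flag,
        )

    # -- basic properties -----------------------------------------------------

    def masked_bins(self, chrom: str) -> np.ndarray:
        """Boolean mask of zero-marginal (excluded) bins."""
        return self.counts[chrom].sum(axis=0) == 0

    def cis_total(self) -> float:
        # diagonal counted once: matrices are symmetric with each pair mirrored
        tot = 0.0
        for m in self.counts.values():
            tot += (m.sum() + np.trace(m)) / 2.0
        return tot

    def trans_total(self) -> float:
        return float(sum(self.trans_totals.values()))

    def total(self) -> float:
        return self.cis_total() + self.trans_total()

    def balanced(self, chrom: str) -> np.ndarray:
        """W M W view of a chromosome; requires prior balancing."""
        if self.weights is None:
            raise ValueError("map is not balanced; run kr_balance first")
        w = np.nan_to_num(self.weights[chrom], nan=0.0)
        return self.counts[chrom] * np.outer(w, w)


@dataclass
class OEMatrix:
    """Observed/expected view: balanced counts divided by the per-diagonal
    mean at the same genomic separation, per chromosome."""

    bins: GenomeBins
    values: dict[str, np.ndarray]
    source: ContactMap | None = None

    def masked_bins(self, chrom: str) -> np.ndarray:
        return np.all(np.isnan(self.values[chrom]), axis=0)


# -- I/O ----------------------------------------------------------------------

def read_triplets(path, bins: GenomeBins) -> ContactMap:
    """Read sparse triplet text into a symmetric ContactMap.

    Two dialects are accepted per record: ``binA binB count`` (global bin
    indices) or ``chrom1 start1 chrom2 start2 count``. Duplicate (i, j) /
    (j, i) records are summed. Trans records accumulate into pair totals.
    """
    cmap = ContactMap.empty(bins)
    offsets = bins._offsets
    order = bins.chroms

    def locate(gidx: int) -> tuple[str, int]:
        for chrom in reversed(order):
            if gidx >= offsets[chrom]:
                local = gidx - offsets[chrom]
                if local >= bins.n_bins(chrom):
                    raise ValueError(f"bin index {gidx} out of range")
                return chrom, local
        raise ValueError(f"bin index {gidx} out of range")

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                if len(parts) == 3:
                    i, j = int(parts[0]), int(parts[1])
                    count = _parse_count(parts[2], lineno)
                    c1, a = locate(i)
                    c2, b = locate(j)
                elif len(parts) == 5:
                    c1, c2 = parts[0], parts[2]
                    for c in (c1, c2):
                        if c not in bins.chrom_sizes:
                            raise ValueError(f"unknown chromosome {c!r}")
                    a = bins.bin_index(c1, int(parts[1]))
                    b = bins.bin_index(c2, int(parts[3]))
                    count = _parse_count(parts[4], lineno)
                else:
                    raise ValueError("expected 3 or 5 fields")
            except ValueError as exc:
                raise ValueError(f"record {lineno}: {exc}") from None
            if c1 == c2:
                m = cmap.counts[c1]
                m[a, b] += count
                if a != b:
                    m[b, a] += count
            else:
                key = tuple(sorted((c1, c2)))
                cmap.trans_totals[key] = cmap.trans_totals.get(key, 0.0) + count
    return cmap


def _parse_count(tok: str, lineno: int) -> int:
    try:
        count = int(tok)
    except ValueError:
        raise ValueError(f"non-integer count {tok!r}")
    if count < 0:
        raise ValueError(f"negative count {count}")
    return count


def read_dense(path, bins: GenomeBins, chrom: str) -> ContactMap:
    """Read one chromosome's dense whitespace-separated matrix (tests)."""
    m = np.loadtxt(path)
    n = bins.n_bins(chrom)
    if m.shape != (n, n):
        raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
    cmap = ContactMap.empty(bins)
    cmap.counts[chrom] = (m + m.T) / 2.0 if not np.allclose(m, m.T) else m
    return cmap


def write_triplets(cmap: ContactMap, path) -> None:
    """Write the upper triangle (incl. diagonal) as 5-column triplet text."""
    bs = cmap.bins.bin_size
    with open(path, "w") as fh:
        for chrom, m in cmap.counts.items():
            iu, ju = np.nonzero(np.triu(m))
            for a, b in zip(iu, ju):
                fh.write(f"{chrom}\t{a * bs}\t{chrom}\t{b * bs}\t{m[a, b]:g}\n")


# -- balancing ----------------------------------------------------------------

def kr_balance(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 1000) -> ContactMap:
    """Matrix balancing by symmetric Sinkhorn iteration.

    Finds per-bin weights w such that W M W has equal row sums (= 1) over
    unmasked bins of each chromosome. Zero-marginal bins are masked (weight
    NaN), not balanced. On non-convergence the map is returned unbalanced
    for that chromosome with a warning carrying the residual.
    """
    out = cmap.copy()
    out.weights = {}
    for chrom, m in out.counts.items():
        n = m.shape[0]
        mask = m.sum(axis=0) == 0
        w = np.ones(n)
        w[mask] = 0.0
        converged = n - mask.sum() == 0  # fully masked: nothing to do
        for _ in range(max_iter):
            if converged:
                break
            r = (m * np.outer(w, w)).sum(axis=1)
            r[mask] = 1.0
            resid = np.max(np.abs(r[~mask] - 1.0))
            if resid < tol:
                converged = True
                break
            w = w / np.sqrt(r)
            w[mask] = 0.0
        if not converged:
            r = (m * np.outer(w, w)).sum(axis=1)
            resid = float(np.max(np.abs(r[~mask] - 1.0))) if (~mask).any() else 0.0
            warnings.warn(
                f"balancing did not converge on {chrom} "
                f"(residual {resid:.3g} after {max_iter} iterations)")
        w = w.astype(float)
        w[mask] = np.nan
        out.weights[chrom] = w
    out.balanced_flag = True
    return out


# -- O/E ----------------------------------------------------------------------

def expected_by_distance(mat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-diagonal empirical mean over unmasked entries; NaN where the
    diagonal has no unmasked pairs or a zero mean."""
    n = mat.shape[0]
    valid = ~mask
    exp = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        keep = valid[i] & valid[j]
        if keep.any():
            mu = mat[i[keep], j[keep]].mean()
            exp[d] = mu if mu > 0 else np.nan
    return exp


def observed_over_expected(cmap: ContactMap) -> OEMatrix:
    """Balanced counts divided by the mean balanced contact at the same
    separation on the same chromosome. Masked bins become NaN rows/cols."""
    if not cmap.balanced_flag or cmap.weights is None:
        raise ValueError("observed_over_expected requires a balanced map")
    values = {}
    for chrom in cmap.bins.chroms:
        b = cmap.balanced(chrom)
        mask = np.isnan(cmap.weights[chrom])
        n = b.shape[0]
        if mask.all():
            warnings.warn(f"chromosome {chrom} fully masked; empty O/E")
            values[chrom] = np.full((n, n), np.nan)
            continue
        exp = expected_by_distance(b, mask)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = b / exp[d]
        oe[mask, :] = np.nan
        oe[:, mask] = np.nan
        values[chrom] = oe
    return OEMatrix(bins=cmap.bins, values=values, source=cmap)


# -- depth manipulation -------------------------------------------------------

def downsample(cmap: ContactMap, target_total: int, seed: int) -> ContactMap:
    """Draw ``target_total`` contacts without replacement across all pixels
    (multivariate hypergeometric over cis upper-triangle pixels and trans
    pair totals). Symmetry and integer counts are preserved."""
    total = cmap.total()
    if not float(total).is_integer():
        raise ValueError("downsample requires integer counts")
    total = int(total)
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total {total}")
    rng = np.random.default_rng(seed)

    pools: list[np.ndarray] = []
    keys: list[tuple] = []
    for chrom, m in cmap.counts.items():
        iu, ju = np.triu_indices(m.shape[0])
        vals = m[iu, ju]
        nz = vals > 0
        pools.append(vals[nz].astype(np.int64))
        keys.append(("cis", chrom, iu[nz], ju[nz]))
    tkeys = list(cmap.trans_totals)
    if tkeys:
        pools.append(np.array([int(cmap.trans_totals[k]) for k in tkeys], dtype=np.int64))
        keys.append(("trans", tkeys))

    colors = np.concatenate(pools) if pools else np.array([], dtype=np.int64)
    if colors.size == 0 or target_total == 0:
        out = ContactMap.empty(cmap.bins)
        return out
    draw = rng.multivariate_hypergeometric(colors, target_total, method="marginals")

    out = ContactMap.empty(cmap.bins)
    pos = 0
    for key, pool in zip(keys, pools):
        k = pool.size
        sub = draw[pos:pos + k]
        pos += k
        if key[0] == "cis":
            _, chrom, iu, ju = key
            m = out.counts[key[1]]
            m[iu, ju] = sub
            m[ju, iu] = sub
        else:
            for pair, v in zip(key[1], sub):
                if v > 0:
                    out.trans_totals[pair] = float(v)
    return out


# -- reproducibility ----------------------------------------------------------

def _smoothed_transition(mat: np.ndarray, mask: np.ndarray, t: int) -> np.ndarray:
    keep = ~mask
    sub = mat[np.ix_(keep, keep)]
    rowsum = sub.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    p = sub / rowsum
    return np.linalg.matrix_power(p, t)


def reproducibility_score(map_a: ContactMap, map_b: ContactMap,
                          smoothing_steps: int = 3) -> float:
    """GenomeDISCO-style concordance between two contact maps.

    Per chromosome the cis matrix is row-normalized to a random-walk
    transition matrix, smoothed by ``smoothing_steps`` walk steps, and the
    pair is scored as 1 minus the L1 difference of the smoothed matrices
    divided by the number of mutually unmasked bins; the chromosome scores
    are averaged. 1 means identical; scores can go negative for very
    discordant maps.
    """
    if map_a.bins != map_b.bins:
        raise ValueError("maps must share binning")
    scores = []
    for chrom in map_a.bins.chroms:
        a, b = map_a.counts[chrom], map_b.counts[chrom]
        mask = (a.sum(axis=0) == 0) | (b.sum(axis=0) == 0)
        n_valid = int((~mask).sum())
        if n_valid == 0:
            continue
        pa = _smoothed_transition(a, mask, smoothing_steps)
        pb = _smoothed_transition(b, mask, smoothing_steps)
        scores.append(1.0 - np.abs(pa - pb).sum() / n_valid)
    if not scores:
        raise ValueError("no chromosome with shared coverage")
    return float(np.mean(scores))


# -- resolution change --------------------------------------------------------

def coarsen_map(cmap: ContactMap, factor: int) -> ContactMap:
    """Aggregate counts into bins ``factor`` times larger (e.g. 50 kb -> 100 kb)."""
    new_bins = cmap.bins.coarsen(factor)
    out = ContactMap.empty(new_bins)
    for chrom, m in cmap.counts.items():
        n_new = new_bins.n_bins(chrom)
        n_old = m.shape[0]
        idx = np.arange(n_old) // factor
        agg = np.zeros((n_new, n_new))
        np.add.at(agg, (idx[:, None].repeat(n_old, 1), idx[None, :].repeat(n_old, 0)), m)
        # mirrored fine off-diagonal pairs landing on the coarse diagonal
        # would double-count; restore the pair-counted-once convention
        diag_fine = np.zeros(n_new)
        np.add.at(diag_fine, idx, np.diag(m))
        di = np.arange(n_new)
        agg[di, di] = (agg[di, di] + diag_fine) / 2.0
        out.counts[chrom] = agg
    out.trans_totals = dict(cmap.trans_totals)
    return out
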