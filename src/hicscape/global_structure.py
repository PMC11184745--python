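"""Whole-chromosome disorder and similarity metrics.

Contact-decay curves P(s) over 500 logarithmic distance bins (20 kb-50 Mb
by default), Jensen-Shannon divergence between curves (natural-log
convention, bounded by ln 2), Von Neumann entropy of the contact
correlation spectrum, and the trans-contact fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact import ContactMap

__all__ = [
    "DecayCurve",
    "contact_decay_curve",
    "jensen_shannon_divergence",
    "von_neumann_entropy",
    "vne_from_correlation",
    "cis_trans_ratio",
]


@dataclass
class DecayCurve:
    """Mean contact frequency per logarithmic genomic-distance bin.

    ``values`` is NaN where a distance bin contains no pixel pairs
    (missing, not zero)."""

    bin_edges: np.ndarray  # length nbins + 1, bp
    values: np.ndarray     # length nbins

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def as_distribution(self) -> np.ndarray:
        """Values renormalized to sum 1 over non-missing bins."""
        v = np.where(np.isnan(self.values), 0.0, self.values)
        s = v.sum()
        if s <= 0:
            raise ValueError("curve has no mass")
        return v / s


def contact_decay_curve(cmap: ContactMap, dmin: int = 20_000,
                        dmax: int = 50_000_000, nbins: int = 500) -> DecayCurve:
    """P(s): per log-distance bin, the mean contact frequency over all
    unmasked cis pixel pairs with separation in the bin, pooled across
    chromosomes."""
    edges = np.geomspace(dmin, dmax, nbins + 1)
    sums = np.zeros(nbins)
    npairs = np.zeros(nbins)
    bs = cmap.bins.bin_size
    for chrom, m in cmap.counts.items():
        n = m.shape[0]
        mask = cmap.masked_bins(chrom)
        valid = ~mask
        for d in range(1, n):
            sep = d * bs
            if sep < dmin or sep >= dmax:
                continue
            k = int(np.searchsorted(edges, sep, side="right") - 1)
            i = np.arange(n - d)
            keep = valid[i] & valid[i + d]
            if keep.any():
                sums[k] += m[i[keep], i[keep] + d].sum()
                npairs[k] += keep.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(npairs > 0, sums / np.maximum(npairs, 1), np.nan)
    return DecayCurve(bin_edges=edges, values=values)


def jensen_shannon_divergence(p: DecayCurve, q: DecayCurve) -> float:
    """JSD between two decay curves treated as probability distributions.

    Curves must share binning; both are renormalized over the intersection
    of non-missing bins. Natural-log convention: 0 <= JSD <= ln 2, with 0
    iff the distributions coincide. Disjoint support is finite by the
    0*ln(0) := 0 rule.
    """
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(p.bin_edges, q.bin_edges):
        raise ValueError("curves must share binning")
    joint = ~np.isnan(p.values) & ~np.isnan(q.values)
    if not joint.any():
        raise ValueError("no jointly non-missing bins")
    pv = p.values[joint] / p.values[joint].sum()
    qv = q.values[joint] / q.values[joint].sum()
    m = 0.5 * (pv + qv)

    def _kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log(a[nz] / b[nz])))

    return 0.5 * _kl(pv, m) + 0.5 * _kl(qv, m)


def vne_from_correlation(corr: np.ndarray) -> float:
    """Entropy of the normalized eigenvalue spectrum of a correlation
    matrix: eigenvalues clipped at zero, normalized to sum one, and summed
    as -sum(lambda * ln lambda) with 0*ln(0) := 0."""
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        raise ValueError("degenerate spectrum")
    lam = lam / s
    nz = lam > 0
    return float(-np.sum(lam[nz] * np.log(lam[nz])))


def von_neumann_entropy(cmap: ContactMap, chrom: str,
                        pseudocount: float = 1.0) -> float:
    """Von Neumann entropy of one chromosome's contact matrix.

    The matrix is log2-transformed with a pseudocount, masked bins are
    removed (not imputed), columns are correlated (Pearson), and the
    entropy of the normalized eigenvalue spectrum is returned. Bounded by
    ln(n) for an n-bin chromosome; higher values mean a more disordered,
    less block-structured map.
    """
    m = cmap.counts[chrom]
    mask = cmap.masked_bins(chrom)
    sub = m[np.ix_(~mask, ~mask)]
    if sub.shape[0] < 2:
        raise ValueError(f"chromosome {chrom} has < 2 unmasked bins")
    logm = np.log2(sub + pseudocount)
    sd = logm.std(axis=0)
    if np.any(sd == 0):
        keep = sd > 0
        logm = logm[:, keep]
        if logm.shape[1] < 2:
            raise ValueError("correlation undefined: matrix is constant")
    corr = np.corrcoef(logm, rowvar=False)
    return vne_from_correlation(corr)


def cis_trans_ratio(cmap: ContactMap) -> float:
    """Fraction of all contacts that are inter-chromosomal."""
    cis, trans = cmap.cis_total(), cmap.trans_total()
    if cis + trans == 0:
        raise ValueError("empty map")
    return trans / (cis + trans)
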