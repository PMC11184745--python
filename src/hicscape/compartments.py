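"""A/B compartment calling, strength, saddle aggregation and switch analysis.

The first eigenvector (E1) of the Pearson correlation matrix of the
per-chromosome O/E map splits bins into two classes; the sign is oriented
per chromosome so that positive-E1 bins (class A) have the higher mean
gene density. Compartment strength is the AB/(AA+BB) contact ratio —
lower means stronger segregation. The saddle aggregates O/E between
E1-ranked bin groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contact import OEMatrix
from .genome import GenomeBins
from .intervals import overlaps_any

__all__ = [
    "CompartmentProfile",
    "SaddleMatrix",
    "gene_density_track",
    "call_compartments",
    "compartment_strength",
    "saddle",
    "compartment_switches",
    "switch_fractions",
    "switch_expression_association",
    "peak_compartment_overlap",
]

MASKED = "."


@dataclass
class CompartmentProfile:
    bins: GenomeBins
    e1: dict[str, np.ndarray]
    label: dict[str, np.ndarray]  # 'A' | 'B' | '.' (masked)
    stage: str = ""


@dataclass
class SaddleMatrix:
    values: np.ndarray                 # (ngroups, ngroups), NaN where empty
    group_of_bin: dict[str, np.ndarray]
    corner_summaries: dict[str, float] = field(default_factory=dict)


def gene_density_track(tss: pd.DataFrame, bins: GenomeBins) -> dict[str, np.ndarray]:
    """TSS count per bin (the operational definition of gene density)."""
    out = {c: np.zeros(bins.n_bins(c)) for c in bins.chroms}
    for chrom, pos in zip(tss["chrom"], tss["start"]):
        if chrom in out and 0 <= pos < bins.chrom_sizes[chrom]:
            out[chrom][pos // bins.bin_size] += 1
    return out


def call_compartments(oe: OEMatrix, gene_density: dict[str, np.ndarray],
                      stage: str = "", min_bins: int = 10) -> CompartmentProfile:
    """Per-chromosome E1 of the O/E correlation matrix, oriented by gene
    density (A = positive E1 = higher gene density). Chromosomes with
    fewer than ``min_bins`` unmasked bins are masked entirely."""
    e1_out, lab_out = {}, {}
    for chrom, vals in oe.values.items():
        n = vals.shape[0]
        mask = np.all(np.isnan(vals), axis=0)
        valid = ~mask
        e1 = np.full(n, np.nan)
        labels = np.full(n, MASKED, dtype="<U1")
        if valid.sum() >= min_bins:
            sub = vals[np.ix_(valid, valid)]
            sub = np.nan_to_num(sub, nan=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant cols give nan corr
                corr = np.corrcoef(sub)
            corr = np.nan_to_num(corr, nan=0.0)
            # PC1 of the correlation matrix's columns (centered): the
            # uncentered first eigenvector can collapse to an all-positive
            # Perron mode on structureless maps
            centered = corr - corr.mean(axis=0, keepdims=True)
            _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
            vec = vt[0]
            dens = gene_density[chrom][valid]
            pos, neg = vec > 0, vec <= 0
            mean_pos = dens[pos].mean() if pos.any() else -np.inf
            mean_neg = dens[neg].mean() if neg.any() else -np.inf
            if mean_neg > mean_pos:
                vec = -vec
            e1[valid] = vec
            labels[valid] = np.where(vec > 0, "A", "B")
        e1_out[chrom] = e1
        lab_out[chrom] = labels
    return CompartmentProfile(bins=oe.bins, e1=e1_out, label=lab_out, stage=stage)


def _pair_means(vals: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    out = {}
    idx = {lab: np.flatnonzero(labels == lab) for lab in ("A", "B")}
    for key, (l1, l2) in {"AA": ("A", "A"), "BB": ("B", "B"), "AB": ("A", "B")}.items():
        i, j = idx[l1], idx[l2]
        if i.size == 0 or j.size == 0:
            out[key] = np.nan
            continue
        block = vals[np.ix_(i, j)]
        if l1 == l2:
            iu = np.triu_indices(i.size, k=1)
            block = block[iu]
        out[key] = float(np.nanmean(block)) if block.size else np.nan
    return out


def compartment_strength(oe: OEMatrix, profile: CompartmentProfile,
                         chrom: str) -> float:
    """AB / (AA + BB) over all cis pairs on one chromosome.

    Lower = stronger compartmentalization; 0.5 for a structureless map.
    NaN (with a warning) when a label class is absent.
    """
    means = _pair_means(oe.values[chrom], profile.label[chrom])
    if any(np.isnan(v) for v in means.values()):
        warnings.warn(f"label class absent on {chrom}; strength undefined")
        return float("nan")
    return means["AB"] / (means["AA"] + means["BB"])


def saddle(oe: OEMatrix, profile: CompartmentProfile, ngroups: int = 50,
           corner_frac: float = 0.1) -> SaddleMatrix:
    """O/E aggregated between E1-ranked bin groups.

    Bins are ranked by E1 genome-wide (ascending: group 0 = strongest B)
    and split into ``ngroups`` near-equal quantile groups; entry (g, h) is
    the mean cis O/E over pairs with one bin in each group. Corners
    average the ``corner_frac`` outermost groups: BB = low-E1 corner,
    AA = high-E1 corner, AB = off-diagonal corners.
    """
    chroms = list(oe.values)
    flat_e1, flat_chrom, flat_idx = [], [], []
    for chrom in chroms:
        e1 = profile.e1[chrom]
        ok = ~np.isnan(e1)
        flat_e1.append(e1[ok])
        flat_chrom.extend([chrom] * int(ok.sum()))
        flat_idx.append(np.flatnonzero(ok))
    e1_all = np.concatenate(flat_e1)
    if e1_all.size < ngroups:
        raise ValueError("fewer unmasked bins than groups")
    order = np.argsort(e1_all, kind="stable")
    group = np.empty(e1_all.size, dtype=int)
    for g, chunk in enumerate(np.array_split(order, ngroups)):
        group[chunk] = g

    group_of_bin = {c: np.full(oe.bins.n_bins(c), -1, dtype=int) for c in chroms}
    pos = 0
    for chrom, idxs in zip(chroms, flat_idx):
        group_of_bin[chrom][idxs] = group[pos:pos + idxs.size]
        pos += idxs.size

    sums = np.zeros((ngroups, ngroups))
    counts = np.zeros((ngroups, ngroups))
    for chrom in chroms:
        g = group_of_bin[chrom]
        vals = oe.values[chrom]
        ok = g >= 0
        idx = np.flatnonzero(ok)
        sub = vals[np.ix_(idx, idx)]
        gg = g[idx]
        finite = np.isfinite(sub)
        np.add.at(sums, (gg[:, None].repeat(idx.size, 1)[finite],
                         gg[None, :].repeat(idx.size, 0)[finite]), sub[finite])
        np.add.at(counts, (gg[:, None].repeat(idx.size, 1)[finite],
                           gg[None, :].repeat(idx.size, 0)[finite]), 1)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    k = max(1, int(round(ngroups * corner_frac)))
    corners = {
        "BB": float(np.nanmean(values[:k, :k])),
        "AA": float(np.nanmean(values[-k:, -k:])),
        "AB": float(np.nanmean(np.concatenate(
            [values[:k, -k:].ravel(), values[-k:, :k].ravel()]))),
    }
    return SaddleMatrix(values=values, group_of_bin=group_of_bin,
                        corner_summaries=corners)


def compartment_switches(p1: CompartmentProfile,
                         p2: CompartmentProfile) -> dict[str, np.ndarray]:
    """Per-bin joint category in {A2A, B2B, A2B, B2A, masked}."""
    if p1.bins != p2.bins:
        raise ValueError("profiles must share binning")
    out = {}
    for chrom in p1.label:
        l1, l2 = p1.label[chrom], p2.label[chrom]
        cat = np.full(l1.size, "masked", dtype="<U6")
        ok = (l1 != MASKED) & (l2 != MASKED)
        cat[ok] = np.char.add(np.char.add(l1[ok], "2"), l2[ok])
        out[chrom] = cat
    return out


def switch_fractions(switches: dict[str, np.ndarray]) -> dict[str, float]:
    """Fractions of unmasked bins per category; 'switched' aggregates
    A2B + B2A."""
    cats = np.concatenate(list(switches.values()))
    ok = cats != "masked"
    n = int(ok.sum())
    if n == 0:
        return {"switched": float("nan")}
    out = {key: float((cats == key).sum() / n)
           for key in ("A2A", "B2B", "A2B", "B2A")}
    out["switched"] = out["A2B"] + out["B2A"]
    return out


def switch_expression_association(switches: dict[str, np.ndarray],
                                  expression_delta: pd.Series,
                                  tss: pd.DataFrame,
                                  bins: GenomeBins) -> dict:
    """Per-switch-category distributions of expression change.

    Genes are assigned the category of their TSS bin; returns the
    per-category log fold-change arrays, medians, and a two-sided
    rank-sum comparison of B2A vs A2B. Genes without a usable TSS are
    dropped and counted.
    """
    dist: dict[str, list[float]] = {k: [] for k in ("A2A", "B2B", "A2B", "B2A")}
    dropped = 0
    tss_by_gene = {r.name: (r.chrom, r.start)
                   for r in tss.itertuples(index=False)}
    for gene, delta in expression_delta.items():
        loc = tss_by_gene.get(gene)
        if loc is None or loc[0] not in switches:
            dropped += 1
            continue
        chrom, pos = loc
        if not 0 <= pos < bins.chrom_sizes[chrom]:
            dropped += 1
            continue
        cat = switches[chrom][pos // bins.bin_size]
        if cat in dist:
            dist[cat].append(float(delta))
    arrays = {k: np.asarray(v) for k, v in dist.items()}
    b2a, a2b = arrays["B2A"], arrays["A2B"]
    if b2a.size and a2b.size:
        stat, pval = stats.mannwhitneyu(b2a, a2b, alternative="two-sided")
    else:
        stat, pval = np.nan, np.nan
    return {
        "distributions": arrays,
        "medians": {k: (float(np.median(v)) if v.size else np.nan)
                    for k, v in arrays.items()},
        "b2a_vs_a2b_p": float(pval) if pval == pval else np.nan,
        "dropped_genes": dropped,
    }


def peak_compartment_overlap(peaks: pd.DataFrame,
                             profile: CompartmentProfile) -> dict[str, int]:
    """Count peaks overlapping (>= 1 bp) bins of each label; a peak
    straddling an A/B edge counts toward both. Peaks on chromosomes
    absent from the profile are dropped with a warning."""
    known = peaks["chrom"].isin(profile.bins.chroms)
    if (~known).any():
        warnings.warn(f"dropping {int((~known).sum())} peaks on unknown chromosomes")
        peaks = peaks[known]
    table = profile.bins.bin_table()
    labels = np.concatenate([profile.label[c] for c in profile.bins.chroms])
    out = {}
    for lab in ("A", "B"):
        sub = table[labels == lab]
        out[lab] = int(overlaps_any(peaks, sub).sum()) if len(sub) else 0
    return out
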