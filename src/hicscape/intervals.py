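"""Minimal BED-style interval utilities.

Intervals are pandas frames with at least ``chrom``, ``start``, ``end``
columns, 0-based half-open. Overlap everywhere means >= 1 bp shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_bed", "write_bed", "overlaps_any", "overlap_pairs"]

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = names or BED_COLS[: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it share >= 1 bp with any subject interval?

    Half-open semantics: [a, b) and [c, d) overlap iff a < d and c < b.
    """
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    for chrom, sub in subject.groupby("chrom", sort=False):
        sel = np.flatnonzero(query["chrom"].to_numpy() == chrom)
        if sel.size == 0:
            continue
        # merge subject intervals, then binary-search each query against them
        starts, ends = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        qs = query["start"].to_numpy()[sel]
        qe = query["end"].to_numpy()[sel]
        # interval [qs, qe) overlaps a merged block iff the first block with
        # end > qs starts before qe
        idx = np.searchsorted(ends, qs, side="right")
        hit = (idx < starts.size) & (starts[np.minimum(idx, starts.size - 1)] < qe)
        out[sel] = hit
    return out


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s < cur_e:  # strict: touching intervals share no bp
            cur_e = max(cur_e, e)
        else:
            ms.append(cur_s)
            me.append(cur_e)
            cur_s, cur_e = s, e
    ms.append(cur_s)
    me.append(cur_e)
    return np.asarray(ms), np.asarray(me)


def overlap_pairs(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query_index, subject_index) pairs with >= 1 bp overlap."""
    rows = []
    for chrom, sub in subject.groupby("chrom", sort=False):
        q = query[query["chrom"] == chrom]
        if q.empty:
            continue
        qs, qe = q["start"].to_numpy()[:, None], q["end"].to_numpy()[:, None]
        ss, se = sub["start"].to_numpy()[None, :], sub["end"].to_numpy()[None, :]
        qi, si = np.nonzero((qs < se) & (ss < qe))
        rows.append(pd.DataFrame({"query_index": q.index.to_numpy()[qi],
                                  "subject_index": sub.index.to_numpy()[si]}))
    if not rows:
        return pd.DataFrame(columns=["query_index", "subject_index"], dtype=int)
    return pd.concat(rows, ignore_index=True)
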