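"""Regulatory-element definitions from histone peaks and expression.

Active enhancers are distal H3K27ac peaks, i.e. H3K27ac ChIP-seq peaks
sharing no overlap (>= 1 bp rule) with any H3K4me3 peak. Active promoters
are 6 kb windows centered on the TSS of genes expressed above an FPKM
threshold; plain promoter regions are TSS +/- 3 kb without the expression
filter. Strand is ignored (the window is symmetric); intervals are clipped
to chromosome bounds.
"""

from __future__ import annotations

import pandas as pd

from .intervals import overlaps_any

__all__ = ["define_enhancers", "define_active_promoters", "promoter_regions"]


def define_enhancers(h3k27ac: pd.DataFrame, h3k4me3: pd.DataFrame) -> pd.DataFrame:
    """H3K27ac peaks with zero-bp overlap against every H3K4me3 peak."""
    if len(h3k27ac) == 0:
        return h3k27ac.copy()
    keep = ~overlaps_any(h3k27ac, h3k4me3)
    return h3k27ac[keep].reset_index(drop=True)


def promoter_regions(tss: pd.DataFrame, chrom_sizes: dict[str, int],
                     halfwidth: int = 3000) -> pd.DataFrame:
    """Symmetric window of ``2*halfwidth`` centered on each TSS, clipped.

    ``tss`` needs columns chrom, start (the TSS position) and a gene-id
    column named ``name``.
    """
    out = tss.copy()
    center = out["start"]
    out["start"] = (center - halfwidth).clip(lower=0)
    out["end"] = [min(c + halfwidth, chrom_sizes[ch])
                  for c, ch in zip(center, out["chrom"])]
    return out[["chrom", "start", "end", "name"]].reset_index(drop=True)


def define_active_promoters(tss: pd.DataFrame, expression: pd.DataFrame,
                            chrom_sizes: dict[str, int], stage: str,
                            fpkm_min: float = 1.0,
                            window: int = 6000) -> pd.DataFrame:
    """Promoter windows for genes with FPKM strictly above ``fpkm_min``.

    ``expression`` is indexed by gene id with one FPKM column per stage.
    Genes lacking a TSS are skipped (count available via set difference).
    """
    active = expression.index[expression[stage] > fpkm_min]
    sub = tss[tss["name"].isin(active)]
    return promoter_regions(sub, chrom_sizes, halfwidth=window // 2)
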