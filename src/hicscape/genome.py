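"""Genome binning: fixed-size bins tiling a set of chromosomes.

Coordinates are 0-based half-open throughout; the terminal bin of each
chromosome may be shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "read_chrom_sizes"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    if (df["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return dict(zip(df["chrom"], df["length"].astype(int)))


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-size binning of a genome.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping chromosome name -> length in bp.
    bin_size
        Bin width in bp (working resolutions are typically 10/50/100 kb).
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)
    _nbins: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        offsets, nbins, total = {}, {}, 0
        for chrom, length in self.chrom_sizes.items():
            n = int(np.ceil(length / self.bin_size))
            offsets[chrom] = total
            nbins[chrom] = n
            total += n
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_nbins", nbins)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def n_total(self) -> int:
        return sum(self._nbins.values())

    def n_bins(self, chrom: str) -> int:
        return self._nbins[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Chromosome-local index of the bin containing ``pos``."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def global_index(self, chrom: str, pos: int) -> int:
        return self._offsets[chrom] + self.bin_index(chrom, pos)

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in genome order."""
        rows = []
        for chrom, length in self.chrom_sizes.items():
            starts = np.arange(self._nbins[chrom], dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self._nbins[chrom], dtype=np.int64) * self.bin_size

    def coarsen(self, factor: int) -> "GenomeBins":
        """Same genome at ``factor`` times the bin size."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return GenomeBins(self.chrom_sizes, self.bin_size * factor)

    def __eq__(self, other):
        return (isinstance(other, GenomeBins)
                and self.chrom_sizes == other.chrom_sizes
                and self.bin_size == other.bin_size)
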