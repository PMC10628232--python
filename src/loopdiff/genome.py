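"""Genome layout: chromosome sizes and bin index arithmetic.

All internal coordinates are 0-based half-open. A resolution ``r`` tiles each
chromosome with bins ``[k*r, (k+1)*r)``; the last bin is truncated at the
chromosome end. Bin indices are chromosome-local; global indices offset each
chromosome by the cumulative bin count of its predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths in base pairs."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.chrom_names)}
        )

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self._index[chrom]]

    def n_bins(self, chrom: str, resolution: int) -> int:
        """Number of bins tiling ``chrom`` at ``resolution`` (last truncated)."""
        L = self.length_of(chrom)
        return -(-L // resolution)

    def bin_counts(self, resolution: int) -> dict[str, int]:
        return {c: self.n_bins(c, resolution) for c in self.chrom_names}

    def total_bins(self, resolution: int) -> int:
        return sum(self.n_bins(c, resolution) for c in self.chrom_names)

    def bin_offsets(self, resolution: int) -> dict[str, int]:
        """Global index of each chromosome's first bin."""
        out, acc = {}, 0
        for c in self.chrom_names:
            out[c] = acc
            acc += self.n_bins(c, resolution)
        return out

    def bin_of(self, chrom: str, pos: int, resolution: int) -> int:
        """Chromosome-local bin index of a 0-based position."""
        L = self.length_of(chrom)
        if not 0 <= pos < L:
            raise ValueError(f"position {pos} outside {chrom} (length {L})")
        return pos // resolution

    def bin_table(self, resolution: int):
        """BED-like table of all bins: (chrom, start, end, local bin index)."""
        import pandas as pd

        rows = []
        for c in self.chrom_names:
            n = self.n_bins(c, resolution)
            starts = np.arange(n, dtype=np.int64) * resolution
            ends = np.minimum(starts + resolution, self.length_of(c))
            rows.append(
                pd.DataFrame(
                    {"chrom": c, "start": starts, "end": ends, "bin": np.arange(n)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def genome_size(self) -> int:
        return sum(self.chrom_lengths)
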