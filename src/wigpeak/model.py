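"""Core in-memory data model shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np


class ReadAlignment(NamedTuple):
    """One mapped locus of one read.

    ``pos5`` is the 0-based leftmost coordinate of the aligned segment
    (internal coordinates are 0-based half-open everywhere; 1-based formats
    are converted at the I/O boundary).  ``n_k`` is the number of genomic
    loci this read maps to; each locus carries weight ``1/n_k``.
    """

    read_id: str
    chrom: str
    pos5: int          # 0-based leftmost coordinate of the aligned segment
    strand: str        # "+" or "-"
    alen: int          # aligned length on the reference
    n_k: int = 1
    score: int = 0     # mapping quality / alignment score (best-hit tie-break)

    @property
    def weight(self) -> float:
        return 1.0 / self.n_k

    def five_prime(self) -> int:
        """Strand-aware 5' end: leftmost base for +, rightmost for -."""
        return self.pos5 if self.strand == "+" else self.pos5 + self.alen - 1


@dataclass
class BinnedTrack:
    """Per-chromosome binned coverage vectors (the wig data model).

    ``raw`` holds r_x (weighted fragment counts per bin), ``normalized``
    holds R_x after modified-RPKM scaling, ``smoothed`` the moving average
    of ``normalized``.  Any layer may be absent; :attr:`values` returns the
    most processed layer available.
    """

    chrom: str
    bin_size: int
    raw: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    smoothed: Optional[np.ndarray] = None

    @property
    def nbins(self) -> int:
        for layer in (self.raw, self.normalized, self.smoothed):
            if layer is not None:
                return len(layer)
        return 0

    @property
    def values(self) -> np.ndarray:
        """Display/calling values: smoothed if present, else normalized, else raw."""
        for layer in (self.smoothed, self.normalized, self.raw):
            if layer is not None:
                return layer
        raise ValueError(f"track {self.chrom}: no data layers present")

    def layer(self, name: str) -> np.ndarray:
        if name == "auto":
            return self.values
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"track {self.chrom}: layer {name!r} is empty")
        return arr


@dataclass(frozen=True)
class PeakRecord:
    """One merged enriched region; a row of the peak list / BED output.

    Coordinates are 0-based half-open in bp; ``end - start`` is a multiple
    of the bin size.  ``summit`` is the start coordinate of the bin with the
    maximum ChIP intensity (leftmost on ties).
    """

    chrom: str
    start: int
    end: int
    summit: int
    pvalue: float
    fold_enrichment: float
    max_intensity: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Gene annotation entry for figure panels (exons drawn thick, introns thin)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list = field(default_factory=list)  # list of (start, end), 0-based half-open
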