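"""Convert mapped reads into normalized, smoothed, binned coverage tracks.

The preprocessing chain is: mapping-mode selection -> PCR-duplicate
filtering (strand-specific 5' ends piled over the cap T_b) -> fragment
extension and binning with 1/n_k weights -> per-chromosome modified-RPKM
normalization R_x = 1e6 * (r_x / N_i) * (L_i / 1e8) -> centered moving
average smoothing.  Library-level QC counters mirror the usual mapping /
PCR-bias summary columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .defaults import DEFAULTS
from .genome import GenomeTable
from .io import AlignmentSet
from .model import BinnedTrack, ReadAlignment

log = logging.getLogger(__name__)

MAPPING_MODES = ("unique_only", "multi_up_to_M", "best_hit_only")
_MODE_FLAGS = {"m1": "unique_only", "mM": "multi_up_to_M", "k1": "best_hit_only"}


@dataclass(frozen=True)
class MappingMode:
    """Which mapped loci enter the pipeline.

    ``unique_only`` keeps reads with a single locus (n_k = 1);
    ``multi_up_to_M`` keeps all loci of reads mapping to at most ``M``
    places; ``best_hit_only`` keeps one best-scoring locus per read and
    resets its weight to 1.
    """

    mode: str = "unique_only"
    M: int = DEFAULTS["max_multi"]

    def __post_init__(self):
        if self.mode not in MAPPING_MODES:
            raise ValueError(f"unknown mapping mode {self.mode!r}")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @classmethod
    def from_flag(cls, flag: str, M: int = DEFAULTS["max_multi"]) -> "MappingMode":
        """Build from the short CLI spellings m1 / mM / k1."""
        if flag not in _MODE_FLAGS:
            raise ValueError(f"unknown mapping-mode flag {flag!r} (use m1, mM or k1)")
        return cls(mode=_MODE_FLAGS[flag], M=M)


@dataclass
class ChromStats:
    """Per-chromosome totals feeding the normalization formula."""

    chrom: str
    n_reads: float      # N_i: weighted reads mapped to this chromosome (post-filter)
    length: int         # L_i
    mean_depth: float   # mean of R_x over all bins


@dataclass
class LibraryStats:
    """Library-level counters for the mapping / PCR-bias quality report."""

    total_reads: int = 0
    mapped_unique: int = 0      # reads with n_k == 1
    mapped_multi: int = 0       # reads with n_k > 1
    unmapped: int = 0
    skipped_unknown: int = 0    # loci on chromosomes absent from the genome table
    selected: float = 0.0       # weighted reads surviving mode selection
    filtered_pcr: float = 0.0   # weighted reads removed as PCR bias
    remaining: float = 0.0      # weighted reads binned (selected - filtered)
    n_plus: float = 0.0         # weighted reads on + strand (post selection)
    n_minus: float = 0.0
    genome_length: int = 0
    t_b: int = 1

    @property
    def mapped(self) -> int:
        return self.mapped_unique + self.mapped_multi

    @property
    def mapping_ratio(self) -> float:
        return self.mapped / self.total_reads if self.total_reads else 0.0

    @property
    def pcr_bias_fraction(self) -> float:
        return self.filtered_pcr / self.selected if self.selected else 0.0

    @property
    def expected_per_base(self) -> dict:
        """E(s) = N^s / L per strand."""
        L = self.genome_length
        return {"+": self.n_plus / L if L else 0.0,
                "-": self.n_minus / L if L else 0.0}


# ---------------------------------------------------------------------------
# mapping-mode selection
# ---------------------------------------------------------------------------

def select_alignments(alignments, mode: MappingMode,
                      genome: GenomeTable | None = None) -> list[ReadAlignment]:
    """Apply the mapping mode to a stream of loci.

    ``best_hit_only`` picks the highest-scoring locus per read (ties broken
    by lowest chromosome order then position, so the choice is
    deterministic) and resets its weight to 1.
    """
    alignments = list(alignments)
    if mode.mode == "unique_only":
        return [a for a in alignments if a.n_k == 1]
    if mode.mode == "multi_up_to_M":
        return [a for a in alignments if a.n_k <= mode.M]
    # best_hit_only
    chrom_order = (lambda c: genome.index_of(c)) if genome is not None else (lambda c: c)
    best: dict[str, tuple] = {}
    order: list[str] = []
    for a in alignments:
        key = (-a.score, chrom_order(a.chrom), a.pos5)
        if a.read_id not in best:
            best[a.read_id] = (key, a)
            order.append(a.read_id)
        elif key < best[a.read_id][0]:
            best[a.read_id] = (key, a)
    return [best[rid][1]._replace(n_k=1) for rid in order]


# ---------------------------------------------------------------------------
# PCR-duplicate filtering
# ---------------------------------------------------------------------------

def compute_tb(n_plus: float, n_minus: float, genome_length: int) -> int:
    """Duplicate-count cap T_b = max(1, ceil(10 * max_s E(s))), E(s) = N^s / L.

    A strand-specific 5'-end position carrying more than T_b reads is
    treated as over-amplified; the excess is filtered as PCR bias.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    e_max = max(n_plus, n_minus) / genome_length
    return max(1, math.ceil(e_max * 10))


def filter_pcr_bias(alignments, t_b: int):
    """Keep at most ``t_b`` alignments per (chrom, 5' end, strand) key.

    Returns ``(kept, n_filtered)`` with ``n_filtered`` in locus units.
    First-seen order decides which duplicates survive, so the operation is
    deterministic and idempotent; opposite strands are independent keys.
    """
    if t_b < 1:
        raise ValueError("T_b must be >= 1")
    seen: dict[tuple, int] = {}
    kept: list[ReadAlignment] = []
    n_filtered = 0
    for a in alignments:
        key = (a.chrom, a.five_prime(), a.strand)
        c = seen.get(key, 0)
        if c < t_b:
            kept.append(a)
            seen[key] = c + 1
        else:
            n_filtered += 1
    return kept, n_filtered


# ---------------------------------------------------------------------------
# binning, normalization, smoothing
# ---------------------------------------------------------------------------

def bin_reads(alignments, genome: GenomeTable,
              bin_size: int = DEFAULTS["bin_size"],
              fragment_length: int = DEFAULTS["fragment_length"]) -> dict:
    """Extend each alignment to the fragment length and accumulate r_x.

    Each alignment becomes a fragment of ``max(fragment_length, alen)`` bp
    anchored at its 5' end and extending 3'-ward (leftward for - strand),
    clipped to the chromosome.  The weight 1/n_k is added to every bin the
    fragment overlaps (coverage semantics), implemented as a difference
    array over bin indices.

    Returns ``{chrom: r_x vector}`` covering every chromosome in the table.
    """
    if bin_size < 1 or fragment_length < 1:
        raise ValueError("bin_size and fragment_length must be >= 1")
    by_chrom: dict[str, list] = {c: [] for c, _ in genome}
    for a in alignments:
        by_chrom[a.chrom].append(a)
    out = {}
    for chrom, length in genome:
        nbins = genome.n_bins(chrom, bin_size)
        diff = np.zeros(nbins + 1)
        rows = by_chrom[chrom]
        if rows:
            pos5 = np.fromiter((a.pos5 for a in rows), dtype=np.int64, count=len(rows))
            alen = np.fromiter((a.alen for a in rows), dtype=np.int64, count=len(rows))
            minus = np.fromiter((a.strand == "-" for a in rows), dtype=bool, count=len(rows))
            w = np.fromiter((1.0 / a.n_k for a in rows), dtype=float, count=len(rows))
            flen = np.maximum(alen, fragment_length)
            start = np.where(minus, pos5 + alen - flen, pos5)
            end = start + flen
            np.clip(start, 0, length, out=start)
            np.clip(end, 0, length, out=end)
            ok = end > start
            sb = start[ok] // bin_size
            eb = (end[ok] - 1) // bin_size + 1
            np.add.at(diff, sb, w[ok])
            np.add.at(diff, eb, -w[ok])
        out[chrom] = np.cumsum(diff)[:-1]
        # cumsum can leave tiny negative residue from float cancellation
        np.maximum(out[chrom], 0.0, out=out[chrom])
    return out


def normalize_track(raw: np.ndarray, n_i: float, l_i: int) -> np.ndarray:
    """Modified RPKM: R_x = 1e6 * (r_x / N_i) * (L_i / 1e8).

    Scales bin counts to reads per 1e6 mapped reads per 100 Mb of
    chromosome, using the *per-chromosome* read total N_i and length L_i so
    tracks from differently sequenced samples are comparable.  With N_i = 0
    the raw values are returned unchanged (with a warning).
    """
    raw = np.asarray(raw, dtype=float)
    if n_i <= 0:
        log.warning("normalize_track: N_i = 0; returning raw values unscaled")
        return raw.copy()
    return 1e6 * (raw / n_i) * (l_i / 1e8)


def smooth_track(values: np.ndarray,
                 smoothing_width: int = DEFAULTS["smoothing_width"],
                 bin_size: int = DEFAULTS["bin_size"]) -> np.ndarray:
    """Centered moving average over ``round(smoothing_width / bin_size)`` bins.

    The window is forced odd (+1 when even) so it is symmetric; at the
    chromosome edges the average runs over the truncated window.  When the
    smoothing width equals the bin size this is the identity.
    """
    if smoothing_width < bin_size:
        raise ValueError("smoothing_width must be >= bin_size")
    w = int(round(smoothing_width / bin_size))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return np.asarray(values, dtype=float).copy()
    values = np.asarray(values, dtype=float)
    kernel = np.ones(w)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrackConfig:
    """Preprocessing parameters (defaults from :mod:`wigpeak.defaults`)."""

    bin_size: int = DEFAULTS["bin_size"]
    fragment_length: int = DEFAULTS["fragment_length"]
    smoothing_width: int = DEFAULTS["smoothing_width"]
    smooth: bool = True
    mode: MappingMode = field(default_factory=MappingMode)
    t_b: int | None = None   # None: derive from the data via compute_tb
    filter_duplicates: bool = True


@dataclass
class TrackResult:
    tracks: dict                 # chrom -> BinnedTrack
    chrom_stats: dict            # chrom -> ChromStats
    stats: LibraryStats


def process_alignments(aset, genome: GenomeTable,
                       config: TrackConfig | None = None) -> TrackResult:
    """Full preprocessing chain from parsed alignments to smoothed tracks.

    ``aset`` is an :class:`~wigpeak.io.AlignmentSet` or a plain iterable of
    :class:`~wigpeak.model.ReadAlignment`.  Steps run in the order: mode
    selection, duplicate filtering, binning, normalization, smoothing.
    """
    config = config or TrackConfig()
    if isinstance(aset, AlignmentSet):
        alignments = aset.alignments
        n_unmapped, n_skipped = aset.n_unmapped, aset.n_skipped_unknown
    else:
        alignments = list(aset)
        n_unmapped, n_skipped = 0, 0

    stats = LibraryStats(unmapped=n_unmapped, skipped_unknown=n_skipped,
                         genome_length=genome.total_length)
    read_nk: dict[str, int] = {}
    for a in alignments:
        read_nk[a.read_id] = a.n_k
    stats.mapped_unique = sum(1 for v in read_nk.values() if v == 1)
    stats.mapped_multi = sum(1 for v in read_nk.values() if v > 1)
    stats.total_reads = stats.mapped + n_unmapped

    selected = select_alignments(alignments, config.mode, genome)
    stats.n_plus = sum(a.weight for a in selected if a.strand == "+")
    stats.n_minus = sum(a.weight for a in selected if a.strand == "-")
    stats.selected = stats.n_plus + stats.n_minus

    if config.filter_duplicates:
        t_b = config.t_b if config.t_b is not None else compute_tb(
            stats.n_plus, stats.n_minus, genome.total_length)
        kept, _ = filter_pcr_bias(selected, t_b)
        stats.t_b = t_b
        stats.filtered_pcr = stats.selected - sum(a.weight for a in kept)
    else:
        kept = selected
    stats.remaining = stats.selected - stats.filtered_pcr

    raw = bin_reads(kept, genome, config.bin_size, config.fragment_length)
    n_i = {c: 0.0 for c, _ in genome}
    for a in kept:
        n_i[a.chrom] += a.weight

    tracks: dict[str, BinnedTrack] = {}
    chrom_stats: dict[str, ChromStats] = {}
    for chrom, length in genome:
        normalized = normalize_track(raw[chrom], n_i[chrom], length)
        smoothed = (smooth_track(normalized, config.smoothing_width, config.bin_size)
                    if config.smooth else None)
        tracks[chrom] = BinnedTrack(chrom=chrom, bin_size=config.bin_size,
                                    raw=raw[chrom], normalized=normalized,
                                    smoothed=smoothed)
        chrom_stats[chrom] = ChromStats(chrom=chrom, n_reads=n_i[chrom], length=length,
                                        mean_depth=float(np.mean(normalized)))
    return TrackResult(tracks=tracks, chrom_stats=chrom_stats, stats=stats)


def process_map_file(path, format: str, genome: GenomeTable,
                     config: TrackConfig | None = None, *,
                     on_unknown: str = "skip") -> TrackResult:
    """Read a SAM/Bowtie/BED map file and run :func:`process_alignments`."""
    from .io import read_alignments

    aset = read_alignments(path, format, genome, on_unknown=on_unknown)
    return process_alignments(aset, genome, config)


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

def library_report(stats: LibraryStats) -> str:
    """Human-readable mapping / PCR-bias summary with quality warnings.

    Flags a mapping ratio below 50% and a PCR-bias fraction above 40%
    (over-amplification); a fraction above 20% gets a milder note.
    """
    lines = []
    total = stats.total_reads

    def pct(x, base):
        return f"{100.0 * x / base:.2f}%" if base else "n/a"

    lines.append("library summary")
    lines.append(f"  total reads          {total}")
    lines.append(f"  mapped (unique)      {stats.mapped_unique}\t{pct(stats.mapped_unique, total)}")
    lines.append(f"  mapped (multi)       {stats.mapped_multi}\t{pct(stats.mapped_multi, total)}")
    lines.append(f"  unmapped             {stats.unmapped}\t{pct(stats.unmapped, total)}")
    lines.append(f"  mapping ratio        {pct(stats.mapped, total)}")
    lines.append(f"  mode-selected        {stats.selected:.2f}")
    lines.append(f"  duplicate cap T_b    {stats.t_b}")
    lines.append(f"  filtered as PCR bias {stats.filtered_pcr:.2f}\t{pct(stats.filtered_pcr, stats.selected)}")
    lines.append(f"  remaining            {stats.remaining:.2f}")
    warnings = []
    if total and stats.mapping_ratio < 0.5:
        warnings.append(f"WARNING: mapping ratio {100 * stats.mapping_ratio:.1f}% < 50%")
    frac = stats.pcr_bias_fraction
    if frac > 0.4:
        warnings.append(
            f"WARNING: PCR-bias fraction {100 * frac:.1f}% > 40%; over-amplification likely")
    elif frac > 0.2:
        warnings.append(f"NOTE: PCR-bias fraction {100 * frac:.1f}% > 20%")
    lines.extend(warnings)
    return "\n".join(lines) + "\n"


def library_report_tsv(stats: LibraryStats) -> str:
    """Machine-readable one-row TSV mirroring :func:`library_report`."""
    cols = ["total_reads", "mapped_unique", "mapped_multi", "unmapped",
            "selected", "t_b", "filtered_pcr", "remaining",
            "mapping_ratio", "pcr_bias_fraction"]
    vals = [stats.total_reads, stats.mapped_unique, stats.mapped_multi,
            stats.unmapped, f"{stats.selected:.4f}", stats.t_b,
            f"{stats.filtered_pcr:.4f}", f"{stats.remaining:.4f}",
            f"{stats.mapping_ratio:.4f}", f"{stats.pcr_bias_fraction:.4f}"]
    return "\t".join(cols) + "\n" + "\t".join(str(v) for v in vals) + "\n"
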