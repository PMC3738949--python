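"""Readers and writers for every external format the pipeline touches.

Alignments come in as SAM (header optional; the genome table supplies
chromosome lengths), default Bowtie text output, or 6-column BED.  Binned
tracks go out as fixedStep wiggle, bedGraph, a documented binary dialect,
or gzip-compressed wiggle, one file per chromosome.  Peak lists are TSV
whose first three columns make a valid BED once the ``#``-prefixed header
is ignored.

Internal coordinates are 0-based half-open; conversions to/from 1-based
formats (SAM, fixedStep wiggle) happen only here.
"""

from __future__ import annotations

import gzip
import logging
import re
import struct
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError
from .genome import GenomeTable
from .model import BinnedTrack, GeneModel, PeakRecord, ReadAlignment

log = logging.getLogger(__name__)

ALIGNMENT_FORMATS = ("sam", "bowtie", "bed")
WIG_DIALECTS = ("wiggle", "bedgraph", "binary", "compressed")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")

# Binary wig dialect (self-defined, little-endian):
#   magic  8s   b"WIGBIN1\0"
#   nlen   H    length of chromosome name
#   name   {nlen}s
#   bin    I    bin size in bp
#   count  Q    number of bins
#   data   {count}d  float64 bin values
_BINARY_MAGIC = b"WIGBIN1\0"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSet:
    """Parsed mapped loci plus the record-level counters needed for QC."""

    alignments: list[ReadAlignment] = field(default_factory=list)
    n_unmapped: int = 0          # SAM records with the unmapped flag
    n_skipped_unknown: int = 0   # records on chromosomes absent from the genome table

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self):
        return len(self.alignments)


def _cigar_reference_length(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_CONSUMING)


def read_alignments(path, format: str, genome: GenomeTable, *,
                    on_unknown: str = "skip") -> AlignmentSet:
    """Read a mapped-read file into an :class:`AlignmentSet`.

    Parameters
    ----------
    format
        One of ``"sam"``, ``"bowtie"``, ``"bed"``.
    on_unknown
        ``"skip"`` (default) drops alignments on chromosomes missing from
        the genome table with a warning; ``"error"`` raises.

    Notes
    -----
    Multiplicity ``n_k`` comes from the SAM ``NH`` tag when present;
    otherwise (and always for Bowtie/BED input) it is the number of loci in
    the file sharing the same read name.  The file is materialized in
    memory so the name count can be applied in a second pass.
    """
    if format not in ALIGNMENT_FORMATS:
        raise ValueError(f"unknown alignment format {format!r}; expected one of {ALIGNMENT_FORMATS}")
    if on_unknown not in ("skip", "error"):
        raise ValueError("on_unknown must be 'skip' or 'error'")
    reader = {"sam": _read_sam, "bowtie": _read_bowtie, "bed": _read_bed}[format]
    return reader(path, genome, on_unknown)


def _check_chrom(chrom: str, genome: GenomeTable, on_unknown: str, path, lineno: int) -> bool:
    if chrom in genome:
        return True
    if on_unknown == "error":
        raise FormatError(f"{path}: line {lineno}: chromosome {chrom!r} not in genome table")
    log.warning("%s: line %d: skipping alignment on unknown chromosome %r", path, lineno, chrom)
    return False


def _fill_nk_by_name(records: list, need_count_idx: list[int]) -> None:
    """Set n_k of the flagged records to the number of loci sharing their read_id."""
    if not need_count_idx:
        return
    counts = Counter(records[i].read_id for i in need_count_idx)
    for i in need_count_idx:
        rec = records[i]
        records[i] = rec._replace(n_k=counts[rec.read_id])


def _read_sam(path, genome: GenomeTable, on_unknown: str) -> AlignmentSet:
    out = AlignmentSet()
    records = out.alignments
    need_count: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise FormatError(f"{path}: line {lineno}: SAM record with fewer than 11 fields")
            try:
                flag = int(f[1])
                pos1 = int(f[3])
                mapq = int(f[4])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: malformed SAM numeric field") from None
            if flag & 0x4:
                out.n_unmapped += 1
                continue
            chrom = f[2]
            if not _check_chrom(chrom, genome, on_unknown, path, lineno):
                out.n_skipped_unknown += 1
                continue
            cigar, seq = f[5], f[9]
            alen = _cigar_reference_length(cigar) if cigar != "*" else (
                len(seq) if seq != "*" else 1)
            if alen < 1:
                alen = 1
            nh = None
            for tag in f[11:]:
                if tag.startswith("NH:i:"):
                    nh = int(tag[5:])
                    break
            strand = "-" if flag & 0x10 else "+"
            rec = ReadAlignment(read_id=f[0], chrom=chrom, pos5=pos1 - 1,
                                strand=strand, alen=alen,
                                n_k=nh if nh is not None else 1, score=mapq)
            if nh is None:
                need_count.append(len(records))
            records.append(rec)
    _fill_nk_by_name(records, need_count)
    return out


def _read_bowtie(path, genome: GenomeTable, on_unknown: str) -> AlignmentSet:
    # default Bowtie output: name, strand, chrom, 0-based offset, seq, quals,
    # [other-alignment count, mismatch descriptors]
    out = AlignmentSet()
    records = out.alignments
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}: line {lineno}: Bowtie record with fewer than 5 fields")
            name, strand, chrom, off, seq = f[0], f[1], f[2], f[3], f[4]
            if strand not in "+-":
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            if not _check_chrom(chrom, genome, on_unknown, path, lineno):
                out.n_skipped_unknown += 1
                continue
            try:
                pos5 = int(off)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer offset {off!r}") from None
            records.append(ReadAlignment(read_id=name, chrom=chrom, pos5=pos5,
                                         strand=strand, alen=max(len(seq), 1)))
    _fill_nk_by_name(records, list(range(len(records))))
    return out


def _read_bed(path, genome: GenomeTable, on_unknown: str) -> AlignmentSet:
    out = AlignmentSet()
    records = out.alignments
    anonymous: list[int] = []
    named: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}: line {lineno}: BED6 record needs 6 columns")
            chrom, name, strand = f[0], f[3], f[5]
            if strand not in "+-":
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            if not _check_chrom(chrom, genome, on_unknown, path, lineno):
                out.n_skipped_unknown += 1
                continue
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer BED interval") from None
            if end <= start:
                raise FormatError(f"{path}: line {lineno}: empty BED interval")
            idx = len(records)
            records.append(ReadAlignment(read_id=name, chrom=chrom, pos5=start,
                                         strand=strand, alen=end - start))
            (anonymous if name in (".", "", "*") else named).append(idx)
    _fill_nk_by_name(records, named)
    return out


# ---------------------------------------------------------------------------
# wig-family track files
# ---------------------------------------------------------------------------

def write_wig(track: BinnedTrack, path, dialect: str = "wiggle", *,
              layer: str = "auto") -> None:
    """Write one chromosome's binned values to a wig-family file.

    ``layer`` selects ``raw``/``normalized``/``smoothed`` or ``auto`` (the
    most processed layer present).  Refuses to write NaN.
    """
    if dialect not in WIG_DIALECTS:
        raise ValueError(f"unknown wig dialect {dialect!r}; expected one of {WIG_DIALECTS}")
    values = np.asarray(track.layer(layer), dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"track {track.chrom}: refusing to write NaN values")
    if dialect == "wiggle":
        with open(path, "w") as fh:
            fh.write(_wiggle_text(track.chrom, track.bin_size, values))
    elif dialect == "compressed":
        with gzip.open(path, "wt") as fh:
            fh.write(_wiggle_text(track.chrom, track.bin_size, values))
    elif dialect == "bedgraph":
        with open(path, "w") as fh:
            b = track.bin_size
            for i, v in enumerate(values):
                fh.write(f"{track.chrom}\t{i * b}\t{(i + 1) * b}\t{v:.4f}\n")
    else:  # binary
        name = track.chrom.encode()
        with open(path, "wb") as fh:
            fh.write(struct.pack(f"<8sH{len(name)}sIQ", _BINARY_MAGIC, len(name),
                                 name, track.bin_size, len(values)))
            fh.write(values.astype("<f8").tobytes())


def _wiggle_text(chrom: str, bin_size: int, values: np.ndarray) -> str:
    lines = [f"fixedStep chrom={chrom} start=1 step={bin_size} span={bin_size}"]
    lines.extend(f"{v:.4f}" for v in values)
    return "\n".join(lines) + "\n"


def read_wig(path, dialect: str | None = None) -> BinnedTrack:
    """Read any wig dialect written by :func:`write_wig` back into a track.

    The values land in the ``normalized`` layer (the dialects do not record
    which layer was written).  Dialect is inferred from the file content
    when not given.
    """
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == "binary":
        with open(path, "rb") as fh:
            head = fh.read(10)
            magic, nlen = struct.unpack("<8sH", head)
            if magic != _BINARY_MAGIC:
                raise FormatError(f"{path}: bad binary wig magic {magic!r}")
            name = fh.read(nlen).decode()
            bin_size, count = struct.unpack("<IQ", fh.read(12))
            data = np.frombuffer(fh.read(8 * count), dtype="<f8").copy()
        if len(data) != count:
            raise FormatError(f"{path}: truncated binary wig ({len(data)}/{count} bins)")
        return BinnedTrack(chrom=name, bin_size=bin_size, normalized=data)
    opener = gzip.open if dialect == "compressed" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        if dialect in ("wiggle", "compressed") or first.startswith("fixedStep"):
            m = re.match(r"fixedStep chrom=(\S+) start=(\d+) step=(\d+)", first)
            if not m:
                raise FormatError(f"{path}: missing fixedStep header")
            chrom, bin_size = m.group(1), int(m.group(3))
            data = np.array([float(line) for line in fh if line.strip()])
            return BinnedTrack(chrom=chrom, bin_size=bin_size, normalized=data)
        # bedGraph
        rows = [first.rstrip("\n").split("\t")] + [
            line.rstrip("\n").split("\t") for line in fh if line.strip()]
        chrom = rows[0][0]
        bin_size = int(rows[0][2]) - int(rows[0][1])
        data = np.array([float(r[3]) for r in rows])
        return BinnedTrack(chrom=chrom, bin_size=bin_size, normalized=data)


def _sniff_dialect(path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head == _BINARY_MAGIC:
        return "binary"
    if head[:2] == b"\x1f\x8b":
        return "compressed"
    if head[:5] == b"fixed":
        return "wiggle"
    return "bedgraph"


def write_track_set(tracks: dict, outdir, sample: str, dialect: str = "wiggle", *,
                    layer: str = "auto") -> list:
    """Write one wig file per chromosome, named ``{sample}_{chrom}.{ext}``."""
    import os

    ext = {"wiggle": "wig", "bedgraph": "bedGraph", "binary": "bwig",
           "compressed": "wig.gz"}[dialect]
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for chrom, track in tracks.items():
        p = os.path.join(outdir, f"{sample}_{chrom}.{ext}")
        write_wig(track, p, dialect, layer=layer)
        paths.append(p)
    return paths


def read_track_set(indir, sample: str, genome: GenomeTable) -> dict:
    """Read back a per-chromosome wig set written by :func:`write_track_set`."""
    import glob
    import os

    tracks = {}
    for chrom, _ in genome:
        hits = sorted(glob.glob(os.path.join(indir, f"{sample}_{chrom}.*")))
        if not hits:
            raise FileNotFoundError(f"no wig file for sample {sample!r}, chromosome {chrom!r} in {indir}")
        tracks[chrom] = read_wig(hits[0])
    return tracks


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["chrom", "start", "end", "name", "summit", "pvalue",
                 "fold_enrichment", "max_intensity"]


def write_peaks(peaks: list[PeakRecord], path, genome: GenomeTable | None = None) -> None:
    """Write the peak list as TSV; a valid BED once the ``#`` header is ignored.

    Peaks must arrive sorted by (chromosome order, start) and
    non-overlapping within each chromosome — merging happens upstream.
    """
    order = (lambda c: genome.index_of(c)) if genome is not None else (lambda c: c)
    last: dict[str, tuple] = {}
    prev_key = None
    for pk in peaks:
        key = (order(pk.chrom), pk.start)
        if prev_key is not None and key < prev_key:
            raise ValueError("peaks are not sorted by (chromosome order, start)")
        prev_key = key
        if pk.chrom in last and pk.start < last[pk.chrom][1]:
            raise ValueError(
                f"overlapping peaks on {pk.chrom}: {last[pk.chrom]} and ({pk.start}, {pk.end})")
        last[pk.chrom] = (pk.start, pk.end)
    df = pd.DataFrame(
        [(p.chrom, p.start, p.end, f"peak_{i + 1}", p.summit, p.pvalue,
          p.fold_enrichment, p.max_intensity) for i, p in enumerate(peaks)],
        columns=_PEAK_COLUMNS,
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PEAK_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False,
                  float_format="%.6g")


def read_peaks(path) -> list[PeakRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_PEAK_COLUMNS)
    return [
        PeakRecord(chrom=r.chrom, start=int(r.start), end=int(r.end),
                   summit=int(r.summit), pvalue=float(r.pvalue),
                   fold_enrichment=float(r.fold_enrichment),
                   max_intensity=float(r.max_intensity))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# gene annotation (BED12 / refFlat)
# ---------------------------------------------------------------------------

def read_genes(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or refFlat; format auto-detected by default."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            this = fmt or _sniff_gene_format(f)
            try:
                if this == "bed12":
                    genes.append(_parse_bed12(f))
                else:
                    genes.append(_parse_refflat(f))
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: malformed {this} record") from None
    return genes


def _sniff_gene_format(f: list[str]) -> str:
    # refFlat: strand in column 4 and exon lists in the last two columns
    if len(f) >= 11 and f[3] in "+-":
        return "refflat"
    if len(f) >= 12 and f[5] in "+-":
        return "bed12"
    raise FormatError("cannot identify gene annotation format (need BED12 or refFlat)")


def _parse_bed12(f: list[str]) -> GeneModel:
    start = int(f[1])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    return GeneModel(name=f[3], chrom=f[0], start=start, end=int(f[2]),
                     strand=f[5], exons=exons)


def _parse_refflat(f: list[str]) -> GeneModel:
    starts = [int(x) for x in f[9].rstrip(",").split(",")]
    ends = [int(x) for x in f[10].rstrip(",").split(",")]
    return GeneModel(name=f[0], chrom=f[2], start=int(f[4]), end=int(f[5]),
                     strand=f[3], exons=list(zip(starts, ends)))
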