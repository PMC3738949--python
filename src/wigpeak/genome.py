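"""Genome table: the ordered coordinate frame for every downstream step.

A genome table is a two-column tab-delimited file of chromosome name and
length in bp.  Its row order defines the chromosome order of every output
(wig files, peak lists, figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError


@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosomes with lengths.

    Parameters
    ----------
    entries
        Ordered ``(chrom_name, length)`` pairs.  Lengths must be strictly
        positive and names unique.
    """

    entries: tuple[tuple[str, int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, entries):
        entries = tuple((str(c), int(n)) for c, n in entries)
        seen: dict[str, int] = {}
        for i, (chrom, length) in enumerate(entries):
            if length <= 0:
                raise FormatError(f"chromosome {chrom!r} has non-positive length {length}")
            if chrom in seen:
                raise FormatError(f"duplicate chromosome {chrom!r} in genome table")
            seen[chrom] = i
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "_index", seen)

    # -- container protocol -------------------------------------------------
    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    # -- accessors ----------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def total_length(self) -> int:
        """L: summed length of all chromosomes."""
        return sum(n for _, n in self.entries)

    def length_of(self, chrom: str) -> int:
        """L_i: length of one chromosome."""
        try:
            return self.entries[self._index[chrom]][1]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome table") from None

    def index_of(self, chrom: str) -> int:
        """Position of `chrom` in table order (used for deterministic sorting)."""
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome table") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        """Number of bins covering `chrom` at `bin_size` (last bin may be partial)."""
        length = self.length_of(chrom)
        return -(-length // bin_size)


def read_genome_table(path) -> GenomeTable:
    """Parse a tab-delimited ``chrom<TAB>length`` file into a :class:`GenomeTable`.

    Raises
    ------
    FormatError
        On a non-integer length (reported with its line number) or a
        duplicate chromosome name.
    """
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 tab-delimited columns")
            chrom, raw_len = fields[0], fields[1]
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer length {raw_len!r} for {chrom!r}"
                ) from None
            entries.append((chrom, length))
    return GenomeTable(entries)


def write_genome_table(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")
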