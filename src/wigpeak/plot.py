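"""Read-distribution and enrichment bar-graph figures (pdf/png).

Figures are built in two stages: a backend-independent *figure data model*
(lists of bars with positions, heights and colors per panel) and a
matplotlib renderer that draws it.  Tests assert on the data model, not on
pixels.  Color conventions: ChIP reads green, control reads blue,
ChIP/control ratio orange; bins inside called peaks are drawn red on the
ChIP and ratio panels.  Gene models draw exons as thick lines and introns
as thin lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.backends.backend_pdf import PdfPages  # noqa: E402

from .errors import WigpeakError
from .genome import GenomeTable
from .model import BinnedTrack, GeneModel, PeakRecord

TRACK_KINDS = ("chip_reads", "control_reads", "ratio")
KIND_COLORS = {"chip_reads": "green", "control_reads": "blue", "ratio": "orange"}
PEAK_COLOR = "red"
_HIGHLIGHTED_KINDS = ("chip_reads", "ratio")  # panels where peak bins turn red


@dataclass(frozen=True)
class TrackSpec:
    label: str
    kind: str            # one of TRACK_KINDS
    yscale: float | None = None   # fixed y max; None: per-panel max

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")


@dataclass(frozen=True)
class PlotSpec:
    """What to draw: region or whole genome, panel list, annotation, output."""

    region: tuple | None = None          # (chrom, start, end); None with whole_genome
    whole_genome: bool = False
    tracks: tuple = ()                   # TrackSpec, at least one
    scale_ratio: float = 1.0             # red/black cutoff for macro ratio bars
    output: str = "pdf"                  # "pdf" or "png"
    page_bp: int = 1_000_000             # pdf pagination width

    def __post_init__(self):
        if not self.tracks:
            raise ValueError("at least one track is required")
        if not self.whole_genome:
            if self.region is None:
                raise ValueError("either a region or the whole-genome flag is required")
            _, start, end = self.region
            if start >= end:
                raise ValueError("region start must be < end")
        if self.output not in ("pdf", "png"):
            raise ValueError("output must be 'pdf' or 'png'")


@dataclass
class BarPanel:
    """One panel of the figure data model."""

    label: str
    kind: str
    x: np.ndarray          # bar start coordinates (bp)
    width: int             # bar width (bp)
    heights: np.ndarray
    colors: list           # one color string per bar
    ymax: float | None = None


@dataclass
class RegionFigureModel:
    chrom: str
    start: int
    end: int
    panels: list = field(default_factory=list)
    genes: list = field(default_factory=list)

    def red_intervals(self, kind: str = "chip_reads") -> list:
        """Merged (start, end) spans of red bars in the first panel of `kind`."""
        for panel in self.panels:
            if panel.kind != kind:
                continue
            spans = []
            for xi, color in zip(panel.x, panel.colors):
                if color != PEAK_COLOR:
                    continue
                s, e = int(xi), int(xi) + panel.width
                if spans and s <= spans[-1][1]:
                    spans[-1] = (spans[-1][0], e)
                else:
                    spans.append((s, e))
            return spans
        return []


def _ratio_values(chip: np.ndarray, control: np.ndarray) -> np.ndarray:
    floor = max(float(np.mean(control)) * 0.1, np.finfo(float).tiny)
    return chip / np.maximum(control, floor)


def build_region_model(spec: PlotSpec, chip: BinnedTrack, control: BinnedTrack,
                       peaks=(), genes=()) -> RegionFigureModel:
    """Assemble the figure data model for one genomic region."""
    chrom, start, end = spec.region
    if chip.chrom != chrom:
        raise WigpeakError(f"track {chip.chrom!r} does not cover region chromosome {chrom!r}")
    b = chip.bin_size
    nbins = chip.nbins
    if start < 0 or start // b >= nbins:
        raise WigpeakError(f"region {chrom}:{start}-{end} outside the binned track")
    lo, hi = start // b, min(-(-end // b), nbins)
    x = np.arange(lo, hi) * b
    in_peak = np.zeros(hi - lo, dtype=bool)
    for pk in peaks:
        if pk.chrom != chrom:
            continue
        s, e = max(pk.start // b, lo), min(-(-pk.end // b), hi)
        if e > s:
            in_peak[s - lo:e - lo] = True

    chip_v = np.asarray(chip.values, dtype=float)[lo:hi]
    ctrl_v = np.asarray(control.values, dtype=float)[lo:hi]
    values = {"chip_reads": chip_v, "control_reads": ctrl_v,
              "ratio": _ratio_values(chip_v, ctrl_v)}
    model = RegionFigureModel(chrom=chrom, start=start, end=end,
                              genes=[g for g in genes
                                     if g.chrom == chrom and g.end > start and g.start < end])
    for ts in spec.tracks:
        base = KIND_COLORS[ts.kind]
        if ts.kind in _HIGHLIGHTED_KINDS:
            colors = [PEAK_COLOR if p else base for p in in_peak]
        else:
            colors = [base] * len(in_peak)
        model.panels.append(BarPanel(label=ts.label, kind=ts.kind, x=x, width=b,
                                     heights=values[ts.kind], colors=colors,
                                     ymax=ts.yscale))
    return model


def render_region(spec: PlotSpec, chip: BinnedTrack, control: BinnedTrack,
                  path, peaks=(), genes=()) -> RegionFigureModel:
    """Render a region figure to ``path`` (pdf paginated per Mb, or png).

    Returns the figure data model that was drawn.
    """
    model = build_region_model(spec, chip, control, peaks, genes)
    if spec.output == "png":
        fig = _draw_page(model, model.start, model.end)
        fig.savefig(path, format="png", dpi=120)
        plt.close(fig)
    else:
        npages = max(1, math.ceil((model.end - model.start) / spec.page_bp))
        with PdfPages(path) as pdf:
            for i in range(npages):
                s = model.start + i * spec.page_bp
                e = min(model.end, s + spec.page_bp)
                fig = _draw_page(model, s, e)
                pdf.savefig(fig)
                plt.close(fig)
    return model


def _draw_page(model: RegionFigureModel, start: int, end: int):
    n_panels = len(model.panels) + (1 if model.genes else 0)
    fig, axes = plt.subplots(n_panels, 1, figsize=(10, 1.8 * n_panels),
                             sharex=True, squeeze=False)
    axes = axes.ravel()
    for ax, panel in zip(axes, model.panels):
        mask = (panel.x + panel.width > start) & (panel.x < end)
        ax.bar(panel.x[mask], panel.heights[mask], width=panel.width,
               color=[c for c, m in zip(panel.colors, mask) if m],
               align="edge", linewidth=0)
        ax.set_ylabel(panel.label, fontsize=8)
        if panel.ymax is not None:
            ax.set_ylim(0, panel.ymax)
        ax.set_xlim(start, end)
    if model.genes:
        ax = axes[-1]
        for row, gene in enumerate(g for g in model.genes if g.end > start and g.start < end):
            y = -row
            ax.plot([gene.start, gene.end], [y, y], color="black", linewidth=1)
            for es, ee in gene.exons:
                ax.plot([es, ee], [y, y], color="black", linewidth=6, solid_capstyle="butt")
            ax.text(gene.start, y + 0.3, gene.name, fontsize=7)
        ax.set_xlim(start, end)
        ax.set_yticks([])
        ax.set_ylabel("genes", fontsize=8)
    axes[-1].set_xlabel(f"{model.chrom} position (bp)")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# chromosome-wide macro view
# ---------------------------------------------------------------------------

def rebin_track(track: BinnedTrack, macro_bin: int, chrom_length: int,
                n_reads: float) -> BinnedTrack:
    """Aggregate raw counts into macro bins and renormalize.

    Raw bin values are summed into the macro bin and re-scaled with the
    same per-chromosome normalization used at native resolution.
    """
    if macro_bin < track.bin_size or macro_bin % track.bin_size:
        raise WigpeakError("macro bin must be a multiple of the native bin size")
    if track.raw is None:
        raise WigpeakError("macro rebinning needs the raw layer")
    from .coverage import normalize_track

    factor = macro_bin // track.bin_size
    raw = np.asarray(track.raw, dtype=float)
    n_macro = -(-len(raw) // factor)
    padded = np.zeros(n_macro * factor)
    padded[:len(raw)] = raw
    macro_raw = padded.reshape(n_macro, factor).sum(axis=1)
    return BinnedTrack(chrom=track.chrom, bin_size=macro_bin, raw=macro_raw,
                       normalized=normalize_track(macro_raw, n_reads, chrom_length))


def build_chromosome_model(chip: BinnedTrack, control: BinnedTrack,
                           genome: GenomeTable, chip_reads: float,
                           control_reads: float, macro_bin: int = 100_000,
                           scale_ratio: float = 1.0) -> RegionFigureModel:
    """Whole-chromosome enrichment bars at macro resolution.

    Bars are red where ChIP/control exceeds ``scale_ratio`` (strictly) and
    black otherwise; macro bins with no reads in either sample (assembly
    gaps) are drawn at 0.
    """
    chrom = chip.chrom
    length = genome.length_of(chrom)
    chip_m = rebin_track(chip, macro_bin, length, chip_reads)
    ctrl_m = rebin_track(control, macro_bin, length, control_reads)
    cv = np.asarray(chip_m.normalized, dtype=float)
    uv = np.asarray(ctrl_m.normalized, dtype=float)
    gap = (np.asarray(chip_m.raw) == 0) & (np.asarray(ctrl_m.raw) == 0)
    ratio = np.where(gap, 0.0, _ratio_values(cv, uv))
    colors = ["red" if (not g and r > scale_ratio) else "black"
              for r, g in zip(ratio, gap)]
    model = RegionFigureModel(chrom=chrom, start=0, end=length)
    model.panels.append(BarPanel(label=f"{chrom} ChIP/control", kind="ratio",
                                 x=np.arange(len(ratio)) * macro_bin,
                                 width=macro_bin, heights=ratio, colors=colors))
    return model


def render_chromosome(chip: BinnedTrack, control: BinnedTrack, genome: GenomeTable,
                      chip_reads: float, control_reads: float, path, *,
                      macro_bin: int = 100_000, scale_ratio: float = 1.0,
                      output: str = "pdf") -> RegionFigureModel:
    model = build_chromosome_model(chip, control, genome, chip_reads,
                                   control_reads, macro_bin, scale_ratio)
    fig = _draw_page(model, 0, model.end)
    fig.savefig(path, format=output, dpi=120)
    plt.close(fig)
    return model


# ---------------------------------------------------------------------------
# GC-content track (optional FASTA feature)
# ---------------------------------------------------------------------------

def gc_track(fasta_path, chrom: str, genome: GenomeTable,
             window: int = 500_000) -> BinnedTrack:
    """Fraction of G/C among non-N bases per window; all-N windows are NaN."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    if chrom not in fa:
        raise WigpeakError(f"chromosome {chrom!r} not in FASTA {fasta_path}")
    seq = str(fa[chrom][:]).upper()
    length = genome.length_of(chrom)
    if len(seq) != length:
        raise WigpeakError(
            f"{chrom}: FASTA length {len(seq)} != genome-table length {length}")
    n_win = -(-length // window)
    values = np.full(n_win, np.nan)
    for i in range(n_win):
        chunk = seq[i * window:(i + 1) * window]
        informative = len(chunk) - chunk.count("N")
        if informative:
            values[i] = (chunk.count("G") + chunk.count("C")) / informative
    return BinnedTrack(chrom=chrom, bin_size=window, normalized=values)
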