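"""Sliding-window peak calling against an input control, plus empirical FDR.

A window of ``window_bins`` contiguous bins slides along each chromosome
(step 1 bin by default).  A window is significant iff all five conditions
hold simultaneously:

(i)   one-sided Wilcoxon rank-sum p (ChIP > control) < ``p_thresh``
(ii)  fold enrichment (ChIP window sum / control window sum) > ``fold_thresh``
(iii) max ChIP bin in the window / ChIP chromosome mean depth > ``chip_depth_ratio_thresh``
(iv)  control window mean / control chromosome mean depth < ``control_repeat_thresh``
      (rejects highly repetitive regions)
(v)   max ChIP bin in the window > ``intensity_thresh``

Contiguous or overlapping significant windows merge into peaks.  The
empirical FDR is the peak count with ChIP and control swapped divided by
the ChIP peak count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .defaults import DEFAULTS
from .genome import GenomeTable
from .model import BinnedTrack, PeakRecord
from .stats import wilcoxon_onesided

log = logging.getLogger(__name__)

THRESHOLD_NAMES = ("pvalue", "fold", "chip_depth_ratio", "control_repeat", "intensity")


@dataclass(frozen=True)
class PeakCallParams:
    """The five significance thresholds and the window geometry."""

    window_bins: int = DEFAULTS["window_bins"]
    p_thresh: float = DEFAULTS["p_thresh"]
    fold_thresh: float = DEFAULTS["fold_thresh"]
    chip_depth_ratio_thresh: float = DEFAULTS["chip_depth_ratio_thresh"]
    control_repeat_thresh: float = DEFAULTS["control_repeat_thresh"]
    intensity_thresh: float = DEFAULTS["intensity_thresh"]
    step_bins: int = 1
    control_floor_frac: float = 0.1   # floor on control window sum, as a fraction
                                      # of (control mean depth * window_bins)
    use_smoothed: bool = True         # call on smoothed values (else unsmoothed)

    def __post_init__(self):
        if self.window_bins < 2:
            raise ValueError("window_bins must be >= 2")
        if self.step_bins < 1:
            raise ValueError("step_bins must be >= 1")
        for name in ("p_thresh", "fold_thresh", "chip_depth_ratio_thresh",
                     "control_repeat_thresh", "intensity_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class WindowStat:
    """Per-window summary feeding the five thresholds."""

    chrom: str
    start_bin: int
    chip_values: np.ndarray
    control_values: np.ndarray
    pvalue: float
    fold: float
    chip_max: float
    control_mean: float
    passed: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return all(self.passed.get(k, False) for k in THRESHOLD_NAMES)


def _calling_values(track: BinnedTrack, params: PeakCallParams) -> np.ndarray:
    if params.use_smoothed:
        return np.asarray(track.values, dtype=float)
    arr = track.normalized if track.normalized is not None else track.values
    return np.asarray(arr, dtype=float)


def _control_floor(control_depth: float, params: PeakCallParams) -> float:
    floor = control_depth * params.window_bins * params.control_floor_frac
    return max(floor, np.finfo(float).tiny)


def window_scan(chip: BinnedTrack, control: BinnedTrack, params: PeakCallParams,
                chip_depth: float | None = None,
                control_depth: float | None = None) -> Iterator[WindowStat]:
    """Reference per-window scan: yields a full :class:`WindowStat` per start.

    Evaluates all five thresholds (including the Wilcoxon p) for every
    window.  :func:`call_peaks` uses an equivalent vectorized path that
    defers the rank-sum test to windows passing the cheap thresholds; a
    regression test keeps the two in agreement.
    """
    if chip.bin_size != control.bin_size:
        raise ValueError("ChIP and control tracks have different bin sizes")
    x = _calling_values(chip, params)
    y = _calling_values(control, params)
    if len(x) != len(y):
        raise ValueError("ChIP and control tracks have different lengths")
    w = params.window_bins
    chip_depth = float(np.mean(x)) if chip_depth is None else chip_depth
    control_depth = float(np.mean(y)) if control_depth is None else control_depth
    floor = _control_floor(control_depth, params)
    for start in range(0, len(x) - w + 1, params.step_bins):
        cv = x[start:start + w]
        uv = y[start:start + w]
        p = wilcoxon_onesided(cv, uv)
        fold = cv.sum() / max(uv.sum(), floor)
        chip_max = float(cv.max())
        control_mean = float(uv.mean())
        passed = {
            "pvalue": p < params.p_thresh,
            "fold": fold > params.fold_thresh,
            "chip_depth_ratio": chip_depth > 0 and chip_max / chip_depth > params.chip_depth_ratio_thresh,
            "control_repeat": control_depth <= 0 or control_mean / control_depth < params.control_repeat_thresh,
            "intensity": chip_max > params.intensity_thresh,
        }
        yield WindowStat(chrom=chip.chrom, start_bin=start, chip_values=cv,
                         control_values=uv, pvalue=p, fold=float(fold),
                         chip_max=chip_max, control_mean=control_mean, passed=passed)


def merge_windows(windows, bin_size: int) -> list[PeakRecord]:
    """Merge overlapping-or-abutting significant windows into peaks.

    Windows must be sorted by (chrom, start_bin) and all belong to the same
    chromosome ordering as produced by the scan.  Peak statistics: p-value
    = min over member windows, fold = max, max intensity and summit from
    the maximum ChIP bin over the merged span (leftmost bin on ties).
    """
    peaks: list[PeakRecord] = []
    group: list = []
    w = None
    for win in windows:
        if w is not None and len(win.chip_values) != w:
            raise ValueError("windows of mixed width cannot be merged")
        w = len(win.chip_values)
        if group and (win.chrom != group[-1].chrom or win.start_bin > group[-1].start_bin + w):
            peaks.append(_emit_peak(group, w, bin_size))
            group = []
        group.append(win)
    if group:
        peaks.append(_emit_peak(group, w, bin_size))
    return peaks


def _emit_peak(group, w: int, bin_size: int) -> PeakRecord:
    first, last = group[0], group[-1]
    start_bin = first.start_bin
    end_bin = last.start_bin + w
    best_val = -math.inf
    best_bin = start_bin
    for win in group:
        local = int(np.argmax(win.chip_values))
        val = float(win.chip_values[local])
        pos = win.start_bin + local
        if val > best_val or (val == best_val and pos < best_bin):
            best_val = val
            best_bin = pos
    return PeakRecord(
        chrom=first.chrom,
        start=start_bin * bin_size,
        end=end_bin * bin_size,
        summit=best_bin * bin_size,
        pvalue=min(win.pvalue for win in group),
        fold_enrichment=max(win.fold for win in group),
        max_intensity=best_val,
    )


@dataclass
class PeakCallResult:
    peaks: list
    rejection_counts: dict       # threshold name -> windows it rejected
    n_windows: int
    n_candidates: int = 0        # windows passing the four cheap thresholds


def call_peaks(chip_tracks: Mapping[str, BinnedTrack],
               control_tracks: Mapping[str, BinnedTrack],
               genome: GenomeTable,
               params: PeakCallParams | None = None) -> PeakCallResult:
    """Scan all chromosomes, apply the five thresholds, merge, and report.

    Thresholds (ii)-(v) are evaluated vectorized over every window; the
    rank-sum test (i) is then run on the surviving candidates (the
    conjunction makes its value irrelevant elsewhere).  ``rejection_counts``
    gives, for each of (ii)-(v), the number of windows that threshold alone
    rejected, and for (i) the number of candidates it rejected.
    """
    params = params or PeakCallParams()
    rejections = {name: 0 for name in THRESHOLD_NAMES}
    all_peaks: list[PeakRecord] = []
    n_windows = 0
    n_candidates = 0
    for chrom, _ in genome:
        if chrom not in chip_tracks or chrom not in control_tracks:
            continue
        chip, control = chip_tracks[chrom], control_tracks[chrom]
        if chip.bin_size != control.bin_size:
            raise ValueError(f"{chrom}: ChIP and control bin sizes differ")
        x = _calling_values(chip, params)
        y = _calling_values(control, params)
        if len(x) != len(y):
            raise ValueError(f"{chrom}: ChIP and control track lengths differ")
        w = params.window_bins
        if len(x) < w:
            continue
        step = params.step_bins
        starts = np.arange(0, len(x) - w + 1, step)
        n_windows += len(starts)

        cs_x = np.concatenate([[0.0], np.cumsum(x)])
        cs_y = np.concatenate([[0.0], np.cumsum(y)])
        chip_sum = cs_x[starts + w] - cs_x[starts]
        ctrl_sum = cs_y[starts + w] - cs_y[starts]
        chip_max = np.lib.stride_tricks.sliding_window_view(x, w)[::step].max(axis=1)
        chip_depth = float(np.mean(x))
        ctrl_depth = float(np.mean(y))
        floor = _control_floor(ctrl_depth, params)

        fold = chip_sum / np.maximum(ctrl_sum, floor)
        c_fold = fold > params.fold_thresh
        c_ratio = (chip_max / chip_depth > params.chip_depth_ratio_thresh
                   if chip_depth > 0 else np.zeros(len(starts), dtype=bool))
        c_repeat = ((ctrl_sum / w) / ctrl_depth < params.control_repeat_thresh
                    if ctrl_depth > 0 else np.ones(len(starts), dtype=bool))
        c_intensity = chip_max > params.intensity_thresh
        rejections["fold"] += int((~c_fold).sum())
        rejections["chip_depth_ratio"] += int((~np.asarray(c_ratio)).sum())
        rejections["control_repeat"] += int((~np.asarray(c_repeat)).sum())
        rejections["intensity"] += int((~c_intensity).sum())

        cand = c_fold & c_ratio & c_repeat & c_intensity
        cand_idx = np.nonzero(cand)[0]
        n_candidates += len(cand_idx)
        sig_windows = []
        for i in cand_idx:
            s = int(starts[i])
            p = wilcoxon_onesided(x[s:s + w], y[s:s + w])
            if p < params.p_thresh:
                sig_windows.append(WindowStat(
                    chrom=chrom, start_bin=s, chip_values=x[s:s + w],
                    control_values=y[s:s + w], pvalue=p, fold=float(fold[i]),
                    chip_max=float(chip_max[i]), control_mean=float(ctrl_sum[i] / w),
                    passed={name: True for name in THRESHOLD_NAMES}))
            else:
                rejections["pvalue"] += 1
        all_peaks.extend(merge_windows(sig_windows, chip.bin_size))
    return PeakCallResult(peaks=all_peaks, rejection_counts=rejections,
                          n_windows=n_windows, n_candidates=n_candidates)


# ---------------------------------------------------------------------------
# empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    n_chip_peaks: int
    n_swapped_peaks: int
    fdr: float                  # NaN when no ChIP peaks
    warning: str | None = None


def empirical_fdr(chip_tracks, control_tracks, genome: GenomeTable,
                  params: PeakCallParams | None = None) -> FdrResult:
    """Empirical FDR by sample swap: (# peaks of control vs ChIP) / (# ChIP peaks).

    Both directions run with identical parameters.  With zero ChIP peaks
    the ratio is undefined and reported as NaN; with fewer than 100 ChIP
    peaks the estimate is flagged as unreliable.
    """
    params = params or PeakCallParams()
    fwd = call_peaks(chip_tracks, control_tracks, genome, params)
    rev = call_peaks(control_tracks, chip_tracks, genome, params)
    n_chip, n_swap = len(fwd.peaks), len(rev.peaks)
    if n_chip == 0:
        log.warning("empirical FDR undefined: no ChIP peaks called")
        return FdrResult(0, n_swap, float("nan"), warning="no ChIP peaks; FDR undefined")
    warning = None
    if n_chip < 100:
        warning = f"only {n_chip} ChIP peaks (< 100); empirical FDR may be unreliable"
        log.warning("%s", warning)
    return FdrResult(n_chip, n_swap, n_swap / n_chip, warning=warning)


def fdr_threshold_sweep(chip_tracks, control_tracks, genome: GenomeTable,
                        params: PeakCallParams | None = None,
                        thresholds=()) -> pd.DataFrame:
    """Re-call peaks at a series of intensity thresholds (threshold (v)).

    Returns a DataFrame with one row per threshold: the ChIP peak count,
    the swapped (control) peak count, and the empirical FDR.  Peak counts
    are non-increasing in the threshold.
    """
    params = params or PeakCallParams()
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for t in thresholds:
        res = empirical_fdr(chip_tracks, control_tracks, genome,
                            replace(params, intensity_thresh=float(t)))
        rows.append((float(t), res.n_chip_peaks, res.n_swapped_peaks, res.fdr))
    return pd.DataFrame(rows, columns=["intensity_thresh", "n_chip_peaks",
                                       "n_control_peaks", "fdr"])
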