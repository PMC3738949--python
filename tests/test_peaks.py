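"""Window scan, five-threshold logic, merging, empirical FDR, sweeps."""

import numpy as np
import pytest

from wigpeak import (BinnedTrack, GenomeTable, PeakCallParams, call_peaks,
                     empirical_fdr, fdr_threshold_sweep, merge_windows,
                     window_scan)
from wigpeak.peaks import THRESHOLD_NAMES, WindowStat


def track(values, chrom="chr1", bin_size=10):
    v = np.asarray(values, dtype=float)
    return BinnedTrack(chrom=chrom, bin_size=bin_size, normalized=v)


def flat_background(n, level=1.0, bump=None, rng=None):
    v = np.full(n, level) if rng is None else rng.gamma(4, level / 4, size=n)
    if bump:
        lo, hi, height = bump
        v[lo:hi] = height
    return v


@pytest.fixture
def small_params():
    return PeakCallParams(window_bins=5, use_smoothed=False)


def test_all_zero_chip_window_is_not_significant(small_params):
    chip = track(np.zeros(50))
    ctrl = track(np.ones(50))
    for w in window_scan(chip, ctrl, small_params):
        assert not w.passed["intensity"] and not w.passed["chip_depth_ratio"]
        assert not w.significant


def test_constructed_enriched_window_passes_all_five():
    """ChIP 10x control with max far above depth: every predicate true.

    The window must be wide enough that the rank-sum p can fall below the
    default 1e-4 (a 12-per-side split reaches ~2e-5)."""
    params = PeakCallParams(window_bins=12, use_smoothed=False)
    rng = np.random.default_rng(5)
    chip_v = flat_background(200, 1.0, rng=rng)
    chip_v[100:112] = 70.0
    ctrl_v = flat_background(200, 1.0, rng=rng)
    stats = list(window_scan(track(chip_v), track(ctrl_v), params))
    at_peak = [w for w in stats if w.start_bin == 100]
    assert at_peak[0].significant
    assert all(at_peak[0].passed[name] for name in THRESHOLD_NAMES)


def test_high_control_window_rejected_as_repetitive(small_params):
    """Control 20x its mean depth fails threshold (iv) regardless of ChIP."""
    chip_v = flat_background(400, 1.0)
    ctrl_v = flat_background(400, 1.0)
    chip_v[200:205] = 500.0
    ctrl_v[200:205] = 25.0  # control depth ~1.3; window mean ~19x depth
    stats = {w.start_bin: w for w in window_scan(track(chip_v), track(ctrl_v),
                                                 small_params)}
    assert not stats[200].passed["control_repeat"]
    assert not stats[200].significant


def test_vectorized_call_agrees_with_reference_scan(rng):
    """call_peaks (lazy p on candidates) and window_scan (p everywhere) must
    select the same significant windows and produce identical peaks."""
    genome = GenomeTable([("chr1", 4000)])
    chip_v = rng.gamma(2, 1.0, size=400)
    ctrl_v = rng.gamma(2, 1.0, size=400)
    chip_v[120:140] = rng.gamma(40, 0.5, size=20)   # enriched stretch
    chip_v[300:310] = 25.0
    params = PeakCallParams(window_bins=8, use_smoothed=False)
    chip, ctrl = track(chip_v), track(ctrl_v)
    ref_sig = [w for w in window_scan(chip, ctrl, params) if w.significant]
    ref_peaks = merge_windows(ref_sig, 10)
    res = call_peaks({"chr1": chip}, {"chr1": ctrl}, genome, params)
    assert [(p.chrom, p.start, p.end, p.summit) for p in res.peaks] == \
        [(p.chrom, p.start, p.end, p.summit) for p in ref_peaks]
    assert res.n_windows == len(chip_v) - params.window_bins + 1


def make_window(start_bin, chip_values, pvalue=1e-6, fold=5.0, chrom="chr1"):
    cv = np.asarray(chip_values, dtype=float)
    return WindowStat(chrom=chrom, start_bin=start_bin, chip_values=cv,
                      control_values=np.ones_like(cv), pvalue=pvalue, fold=fold,
                      chip_max=float(cv.max()), control_mean=1.0,
                      passed={n: True for n in THRESHOLD_NAMES})


def test_merge_overlapping_windows_spans_union():
    w = [make_window(0, [1, 2, 9]), make_window(1, [2, 9, 1])]
    (peak,) = merge_windows(w, bin_size=10)
    assert (peak.start, peak.end) == (0, 40)
    assert peak.end - peak.start == 40  # multiple of bin size
    assert peak.summit == 20            # leftmost max bin
    assert peak.max_intensity == 9.0


def test_merge_respects_gaps_and_chromosomes():
    w = [make_window(0, [5, 5, 5]), make_window(10, [5, 5, 5]),
         make_window(0, [5, 5, 5], chrom="chr2")]
    peaks = merge_windows(w, 10)
    assert [(p.chrom, p.start, p.end) for p in peaks] == [
        ("chr1", 0, 30), ("chr1", 100, 130), ("chr2", 0, 30)]


def test_merge_abutting_windows_joins_them():
    w = [make_window(0, [5, 5, 5]), make_window(3, [5, 5, 5])]
    (peak,) = merge_windows(w, 10)
    assert (peak.start, peak.end) == (0, 60)


def test_merge_statistics_min_p_max_fold():
    w = [make_window(0, [1, 2, 3], pvalue=1e-5, fold=4.0),
         make_window(1, [2, 3, 1], pvalue=1e-8, fold=6.0)]
    (peak,) = merge_windows(w, 10)
    assert peak.pvalue == 1e-8 and peak.fold_enrichment == 6.0


def test_chip_equals_control_yields_zero_peaks(rng):
    genome = GenomeTable([("chr1", 10000)])
    v = rng.gamma(3, 3.0, size=1000)
    chip, ctrl = track(v), track(v.copy())
    params = PeakCallParams(use_smoothed=False)
    assert call_peaks({"chr1": chip}, {"chr1": ctrl}, genome, params).peaks == []
    res = empirical_fdr({"chr1": chip}, {"chr1": ctrl}, genome, params)
    assert res.n_chip_peaks == 0 and np.isnan(res.fdr)
    assert "undefined" in res.warning


def _enriched_pair(rng, n=3000, n_sites=8):
    chip_v = rng.gamma(16, 0.1, size=n)
    ctrl_v = rng.gamma(16, 0.1, size=n)
    centers = np.linspace(150, n - 150, n_sites).astype(int)
    for c in centers:
        chip_v[c - 40:c + 40] *= 8.0
    return track(chip_v), track(ctrl_v), centers


def test_empirical_fdr_division_and_warning(rng):
    genome = GenomeTable([("chr1", 30000)])
    chip, ctrl, _ = _enriched_pair(rng)
    params = PeakCallParams(use_smoothed=False)
    res = empirical_fdr({"chr1": chip}, {"chr1": ctrl}, genome, params)
    assert res.n_chip_peaks > 0
    assert res.fdr == res.n_swapped_peaks / res.n_chip_peaks
    assert res.warning and "< 100" in res.warning  # few-peak caveat


def test_rejection_counts_cover_all_windows(rng):
    genome = GenomeTable([("chr1", 30000)])
    chip, ctrl, _ = _enriched_pair(rng)
    res = call_peaks({"chr1": chip}, {"chr1": ctrl}, genome,
                     PeakCallParams(use_smoothed=False))
    assert set(res.rejection_counts) == set(THRESHOLD_NAMES)
    # every non-candidate window failed at least one cheap threshold
    assert res.rejection_counts["fold"] >= res.n_windows - res.n_candidates - \
        res.rejection_counts["intensity"] - res.rejection_counts["chip_depth_ratio"] \
        - res.rejection_counts["control_repeat"]


def test_fdr_sweep_counts_non_increasing(rng):
    genome = GenomeTable([("chr1", 30000)])
    chip, ctrl, _ = _enriched_pair(rng)
    params = PeakCallParams(use_smoothed=False)
    table = fdr_threshold_sweep({"chr1": chip}, {"chr1": ctrl}, genome, params,
                                [6.0, 8.0, 16.0])
    assert list(table.columns) == ["intensity_thresh", "n_chip_peaks",
                                   "n_control_peaks", "fdr"]
    assert (np.diff(table.n_chip_peaks) <= 0).all()
    # single-threshold sweep row equals the direct FDR computation
    single = fdr_threshold_sweep({"chr1": chip}, {"chr1": ctrl}, genome, params,
                                 [6.0]).iloc[0]
    direct = empirical_fdr({"chr1": chip}, {"chr1": ctrl}, genome, params)
    assert single.n_chip_peaks == direct.n_chip_peaks
    assert single.fdr == pytest.approx(direct.fdr)


def test_fdr_sweep_validates_order_and_empty(rng):
    genome = GenomeTable([("chr1", 30000)])
    chip, ctrl, _ = _enriched_pair(rng)
    with pytest.raises(ValueError):
        fdr_threshold_sweep({"chr1": chip}, {"chr1": ctrl}, genome,
                            thresholds=[8.0, 6.0])
    assert fdr_threshold_sweep({"chr1": chip}, {"chr1": ctrl}, genome,
                               thresholds=[]).empty


def test_params_validation():
    with pytest.raises(ValueError):
        PeakCallParams(window_bins=1)
    with pytest.raises(ValueError):
        PeakCallParams(fold_thresh=0.0)
    with pytest.raises(ValueError):
        PeakCallParams(step_bins=0)


def test_bin_size_mismatch_rejected():
    genome = GenomeTable([("chr1", 1000)])
    a = track(np.ones(100), bin_size=10)
    b = track(np.ones(100), bin_size=20)
    with pytest.raises(ValueError, match="bin size"):
        list(window_scan(a, b, PeakCallParams(window_bins=5)))
    with pytest.raises(ValueError, match="bin size"):
        call_peaks({"chr1": a}, {"chr1": b}, genome)
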