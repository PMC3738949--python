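"""Mode selection, PCR filtering, binning, normalization, smoothing, QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wigpeak import (GenomeTable, MappingMode, TrackConfig, bin_reads,
                     compute_tb, filter_pcr_bias, library_report,
                     normalize_track, process_alignments, select_alignments,
                     smooth_track)
from wigpeak.coverage import LibraryStats

from conftest import make_read, naive_bin_counts


# ---------------------------------------------------------------------------
# mapping-mode selection
# ---------------------------------------------------------------------------

def multi_read(n_k, read_id="m", scores=None):
    scores = scores or [42] * n_k
    return [make_read(pos5=100 * i, n_k=n_k, read_id=read_id, score=scores[i])
            for i in range(n_k)]


def test_unique_only_keeps_single_locus_reads():
    alns = [make_read(read_id="u")] + multi_read(3)
    kept = select_alignments(alns, MappingMode("unique_only"))
    assert [a.read_id for a in kept] == ["u"]


def test_multi_up_to_m_drops_all_loci_above_m():
    alns = multi_read(12, "heavy") + multi_read(3, "light")
    kept = select_alignments(alns, MappingMode("multi_up_to_M", M=10))
    assert {a.read_id for a in kept} == {"light"} and len(kept) == 3


def test_best_hit_keeps_one_locus_with_weight_one(toy_genome):
    alns = multi_read(3, scores=[10, 30, 20])
    (kept,) = select_alignments(alns, MappingMode("best_hit_only"), toy_genome)
    assert kept.pos5 == 100 and kept.n_k == 1 and kept.weight == 1.0


def test_best_hit_tie_breaks_to_lowest_coordinate(toy_genome):
    alns = [make_read(chrom="chr2", pos5=5, n_k=2, read_id="t"),
            make_read(chrom="chr1", pos5=50, n_k=2, read_id="t")]
    (kept,) = select_alignments(alns, MappingMode("best_hit_only"), toy_genome)
    assert (kept.chrom, kept.pos5) == ("chr1", 50)


def test_mode_validation():
    with pytest.raises(ValueError):
        MappingMode("multi_up_to_M", M=0)
    with pytest.raises(ValueError):
        MappingMode("whatever")


# ---------------------------------------------------------------------------
# duplicate-cap T_b and PCR filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_plus,n_minus,L,expected", [
    (1e6, 1e6, int(1e9), 1),     # E(s)=1e-3 -> 10*E = 0.01 -> cap stays 1
    (3e8, 3e8, int(1e7), 300),   # E(s)=30 -> 300
    (0, 0, int(1e6), 1),         # no reads: floor of the rule
    (1.2e6, 1e6, int(1e7), 2),   # max strand decides; ceil(1.2) = 2
])
def test_compute_tb(n_plus, n_minus, L, expected):
    assert compute_tb(n_plus, n_minus, L) == expected


def test_compute_tb_requires_positive_genome_length():
    with pytest.raises(ValueError):
        compute_tb(10, 10, 0)


def pileup(c, pos5=100, strand="+", chrom="chr1"):
    return [make_read(chrom=chrom, pos5=pos5, strand=strand, read_id=f"d{i}")
            for i in range(c)]


@pytest.mark.parametrize("c,t_b", [(1, 1), (5, 1), (3, 3), (7, 3), (2, 4)])
def test_pcr_filter_keeps_min_c_tb(c, t_b):
    kept, n_filtered = filter_pcr_bias(pileup(c), t_b)
    assert len(kept) == min(c, t_b)
    assert n_filtered == c - min(c, t_b)
    # first-seen order survives
    assert [a.read_id for a in kept] == [f"d{i}" for i in range(min(c, t_b))]


def test_pcr_filter_strands_independent():
    reads = pileup(1, strand="+") + [make_read(pos5=65, strand="-", alen=36,
                                               read_id="rev")]
    # the reverse read's 5' end (65+36-1=100) coincides with the forward 5' end
    assert reads[0].five_prime() == reads[1].five_prime() == 100
    kept, n_filtered = filter_pcr_bias(reads, 1)
    assert len(kept) == 2 and n_filtered == 0


def test_pcr_filter_idempotent():
    kept1, n1 = filter_pcr_bias(pileup(9) + pileup(4, pos5=300), 2)
    kept2, n2 = filter_pcr_bias(kept1, 2)
    assert kept2 == kept1 and n2 == 0 and n1 == 7 + 2


def test_pcr_filter_rejects_bad_cap():
    with pytest.raises(ValueError):
        filter_pcr_bias([], 0)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_single_forward_read_covers_fragment_bins(toy_genome):
    raw = bin_reads([make_read(pos5=0)], toy_genome, bin_size=10, fragment_length=150)
    assert np.array_equal(raw["chr1"][:15], np.ones(15))
    assert raw["chr1"][15:].sum() == 0 and raw["chr2"].sum() == 0


def test_multi_read_contributes_fractional_weight(toy_genome):
    raw = bin_reads([make_read(pos5=0, n_k=4)], toy_genome, 10, 150)
    assert np.allclose(raw["chr1"][:15], 0.25)


def test_reverse_read_extends_leftward_with_clipping(toy_genome):
    # 5' end at 20 (pos5=0, alen=21); fragment [20-149, 21) clipped to [0, 21)
    raw = bin_reads([make_read(pos5=0, strand="-", alen=21)], toy_genome, 10, 150)
    assert np.array_equal(raw["chr1"][:3], [1.0, 1.0, 1.0])
    assert raw["chr1"][3:].sum() == 0


def test_short_fragment_not_shrunk_below_aligned_length(toy_genome):
    raw = bin_reads([make_read(pos5=0, alen=60)], toy_genome, 10, 30)
    assert np.array_equal(raw["chr1"][:6], np.ones(6))


def test_bin_reads_validates_sizes(toy_genome):
    with pytest.raises(ValueError):
        bin_reads([], toy_genome, 0, 150)
    with pytest.raises(ValueError):
        bin_reads([], toy_genome, 10, 0)


@given(data=st.data())
@settings(max_examples=60, deadline=None)
def test_binning_matches_per_base_oracle(data):
    """Property: vectorized binning equals the per-base overlap oracle exactly,
    including multi-read weights, strands and edge clipping."""
    L = data.draw(st.integers(200, 3000))
    genome = GenomeTable([("c", L)])
    bin_size = data.draw(st.sampled_from([1, 7, 10, 50]))
    flen = data.draw(st.integers(1, 300))
    n = data.draw(st.integers(0, 25))
    alns = []
    for i in range(n):
        alen = data.draw(st.integers(1, 80))
        pos5 = data.draw(st.integers(0, max(0, L - alen)))
        alns.append(make_read(chrom="c", pos5=pos5,
                              strand=data.draw(st.sampled_from("+-")),
                              alen=alen, n_k=data.draw(st.integers(1, 6)),
                              read_id=f"r{i}"))
    got = bin_reads(alns, genome, bin_size, flen)
    want = naive_bin_counts(alns, genome, bin_size, flen)
    np.testing.assert_allclose(got["c"], want["c"], rtol=0, atol=1e-9)


def test_weight_conservation(toy_genome, rng):
    """Sum over bins of r_x equals sum over fragments of (bins overlapped / n_k)."""
    alns = [make_read(pos5=int(rng.integers(0, 900)), n_k=int(rng.integers(1, 4)),
                      strand="+-"[int(rng.integers(2))], read_id=f"r{i}")
            for i in range(50)]
    raw = bin_reads(alns, toy_genome, 10, 100)
    want = naive_bin_counts(alns, toy_genome, 10, 100)
    assert np.isclose(sum(v.sum() for v in raw.values()),
                      sum(v.sum() for v in want.values()))


# ---------------------------------------------------------------------------
# normalization and smoothing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("r,n_i,l_i,expected", [
    (5.0, 1e6, int(1e8), 5.0),
    (5.0, 2e6, int(1e8), 2.5),
    (0.0, 1e6, int(1e8), 0.0),
])
def test_modified_rpkm_formula(r, n_i, l_i, expected):
    assert normalize_track(np.array([r]), n_i, l_i)[0] == pytest.approx(expected)


def test_normalize_zero_reads_returns_raw_with_warning(caplog):
    raw = np.array([1.0, 2.0])
    out = normalize_track(raw, 0, 1000)
    assert np.array_equal(out, raw)


def test_scale_invariance_of_normalized_track(toy_genome):
    """Doubling every read (pre-filter) doubles r_x and N_i alike, leaving R_x
    unchanged."""
    alns = [make_read(pos5=p, read_id=f"r{p}") for p in range(0, 900, 37)]
    doubled = alns + [a._replace(read_id=a.read_id + "b") for a in alns]
    for chrom in ("chr1", "chr2"):
        l_i = toy_genome.length_of(chrom)
        r1 = bin_reads(alns, toy_genome, 10, 100)[chrom]
        r2 = bin_reads(doubled, toy_genome, 10, 100)[chrom]
        n1 = sum(a.weight for a in alns if a.chrom == chrom)
        np.testing.assert_allclose(normalize_track(r1, n1, l_i),
                                   normalize_track(r2, 2 * n1, l_i), atol=1e-9)


def test_smoothing_constant_track_unchanged():
    x = np.full(200, 3.7)
    np.testing.assert_allclose(smooth_track(x, 500, 10), x)


def test_smoothing_impulse_spreads_over_window():
    x = np.zeros(301)
    x[150] = 1.0
    out = smooth_track(x, 510, 10)  # 51-bin window
    assert np.allclose(out[125:176], 1 / 51)
    assert out[:125].sum() == 0 and out[176:].sum() == 0
    assert np.isclose(out.sum(), 1.0)  # away from edges, mass is conserved


def test_smoothing_width_equal_bin_is_identity():
    x = np.arange(20.0)
    assert np.array_equal(smooth_track(x, 10, 10), x)


def test_smoothing_even_window_forced_odd():
    # width 40 / bin 10 -> 4 bins -> forced to 5
    x = np.zeros(21)
    x[10] = 5.0
    out = smooth_track(x, 40, 10)
    assert np.count_nonzero(out) == 5


def test_smoothing_requires_width_at_least_bin():
    with pytest.raises(ValueError):
        smooth_track(np.zeros(5), 5, 10)


# ---------------------------------------------------------------------------
# pipeline + QC report
# ---------------------------------------------------------------------------

def test_process_alignments_end_to_end(toy_genome):
    alns = [make_read(pos5=p, read_id=f"a{p}") for p in range(0, 800, 40)]
    alns += [make_read(pos5=10, n_k=2, read_id="mm"),
             make_read(chrom="chr2", pos5=30, n_k=2, read_id="mm")]
    res = process_alignments(alns, toy_genome,
                             TrackConfig(bin_size=10, fragment_length=50,
                                         smoothing_width=50,
                                         mode=MappingMode("multi_up_to_M")))
    stats = res.stats
    assert stats.total_reads == stats.mapped_unique + stats.mapped_multi + stats.unmapped
    assert stats.mapped_multi == 1
    assert stats.remaining == pytest.approx(stats.selected - stats.filtered_pcr)
    for chrom, _ in toy_genome:
        track = res.tracks[chrom]
        assert track.nbins == toy_genome.n_bins(chrom, 10)
        assert (track.raw >= 0).all()
        assert res.chrom_stats[chrom].mean_depth == pytest.approx(
            float(np.mean(track.normalized)))


def test_library_report_percentages_and_warnings():
    stats = LibraryStats(total_reads=100, mapped_unique=60, mapped_multi=10,
                         unmapped=30, selected=70.0, filtered_pcr=0.0,
                         remaining=70.0, genome_length=1000)
    text = library_report(stats)
    assert "70.00%" in text  # mapping ratio
    assert "WARNING" not in text

    bad = LibraryStats(total_reads=100, mapped_unique=40, mapped_multi=5,
                       unmapped=55, selected=45.0, filtered_pcr=20.0,
                       remaining=25.0, genome_length=1000)
    text = library_report(bad)
    assert "mapping ratio" in text and "over-amplification" in text


def test_library_report_handles_zero_reads():
    text = library_report(LibraryStats())
    assert "n/a" in text and "WARNING" not in text
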