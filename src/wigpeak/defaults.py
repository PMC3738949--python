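"""Single source of truth for default parameters.

Every default used by the library, the CLI and the documentation comes from
this table so the three can never drift apart.
"""

DEFAULTS: dict = {
    # track construction
    "bin_size": 10,            # bp per bin
    "fragment_length": 150,    # bp; single-end reads extended to this length
    "smoothing_width": 500,    # bp; centered moving average window
    # mapping-mode selection
    "max_multi": 10,           # M: keep reads mapping to <= M loci (mM mode)
    # sliding-window peak calling
    "window_bins": 30,         # contiguous bins per window
    "p_thresh": 1e-4,          # (i)  one-sided Wilcoxon rank-sum p <
    "fold_thresh": 3.0,        # (ii) ChIP/control window read-sum ratio >
    "chip_depth_ratio_thresh": 3.0,   # (iii) window ChIP max / chrom mean depth >
    "control_repeat_thresh": 10.0,    # (iv) control window mean / chrom mean depth <
    "intensity_thresh": 6.0,   # (v)  window ChIP max (normalized units) >
}
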