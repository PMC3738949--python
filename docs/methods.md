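# Methods

## Overview

`wigpeak` implements a two-stage ChIP-seq analysis. The first stage turns a
mapped-read file into per-chromosome binned coverage tracks ("wig" tracks);
the second scans a ChIP track against an input-control track with a sliding
window, applies five simultaneous significance thresholds, merges the
surviving windows into peaks, and estimates an empirical false discovery
rate by swapping the roles of ChIP and control. A seeded simulator with
planted ground truth makes the whole chain testable end to end.

Internal coordinates are 0-based half-open everywhere; 1-based conventions
(SAM, fixedStep wiggle) are converted only at the I/O boundary. All output
ordering follows the genome table.

## Track construction

**Mapping modes.** A read mapping to `n_k` loci contributes weight `1/n_k`
at each locus. Three selection modes are supported: unique-only (`m1`,
keep reads with `n_k = 1`), multi-up-to-M (`mM`, keep all loci of reads
with `n_k <= M`, default M = 10), and best-hit (`k1`, keep the single
best-scoring locus per read with its weight reset to 1; ties break
deterministically by chromosome order, then coordinate). The default is
unique-only — the conservative standard when the mapper's multi-hit
reporting is not trusted; `mM` recovers signal in repetitive regions at the
cost of ambiguity.

**Multiplicity.** `n_k` comes from the SAM `NH` tag when present.
Otherwise — and always for Bowtie-text and BED input, where no reliable
multiplicity field exists across tool versions — it is the number of loci
in the file sharing the read name, computed in a second pass over the
materialized records.

**PCR-duplicate filtering.** Reads whose strand-specific 5′ ends coincide
beyond a cap `T_b` are treated as over-amplification artifacts. With
`E(s) = N^s / L` the expected reads per base on strand `s` (`L` = genome
length), the cap is `T_b = max(1, ceil(10 · max_s E(s)))`; `E(s)·10` is
rarely integral, so the ceiling is taken before the max — the floor of 1
reproduces the "non-redundant fraction" rule at low depth. For each
(chromosome, 5′ end, strand) key with `c` reads, the first `min(c, T_b)`
in input order are kept. Strands are independent keys, and the filter is
idempotent. Filtering runs after mode selection and before binning, so the
QC report describes the reads the caller actually sees.

**Binning.** Each surviving alignment is extended from its 5′ end to the
expected sonication fragment length (default 150 bp; never shrunk below the
aligned length), clipped at the chromosome ends, and its weight `1/n_k` is
added to every bin (default 10 bp) the fragment overlaps:
`r_x = Σ_{k ∈ R} 1/n_k` for the fragment set `R` overlapping bin `x`.
Coverage-style assignment (full weight in every overlapped bin, rather than
5′-bin-only or overlap-proportional) matches the visual semantics of the
read-distribution figures. Implementation: a difference array over bin
indices plus a cumulative sum; an exact per-base oracle in the test suite
confirms equivalence.

**Normalization.** The modified-RPKM value of a bin is

    R_x = 1e6 · (r_x / N_i) · (L_i / 1e8)

with `N_i` the weighted read count and `L_i` the length of chromosome `i`:
reads per million mapped per 100 Mb of chromosome, applied per chromosome
as printed. `N_i` is the post-filter count, so the normalized track
describes exactly the data that were binned. Duplicating every read before
filtering leaves `R_x` unchanged (`r_x` and `N_i` scale together); a
chromosome with no reads is passed through unscaled with a warning.

**Smoothing.** A centered moving average of width 500 bp by default
(`round(width / bin)` bins, forced odd; edges use the truncated window) is
applied after normalization, in that order. Peak calling runs on the
smoothed track by default; `use_smoothed=False` / `--unsmoothed` switches
to the unsmoothed normalized values.

## Peak calling

The genome is scanned with a window of 30 contiguous bins (step 1 bin; the
merge step makes contiguous significance stride-insensitive). A window is
significant iff all five hold:

| # | quantity | default |
|---|----------|---------|
| i | one-sided Wilcoxon rank-sum p (ChIP > control) | < 1e-4 |
| ii | ChIP window sum / control window sum | > 3.0 |
| iii | max ChIP bin / ChIP chromosome mean depth | > 3.0 |
| iv | control window mean / control chromosome mean depth | < 10.0 |
| v | max ChIP bin (normalized units) | > 6.0 |

Inequalities are strict, exactly as stated. "Chromosome mean depth" is the
mean of the calling-layer values over *all* bins of the chromosome,
including zeros (all five quantities live in bin space). Threshold (iv)
rejects highly repetitive regions where the control itself piles up;
threshold (iii) guards against calling in shallow chromosomes; (v) makes
peak lists comparable across samples.

**Zero-control windows.** Fold enrichment floors the control window sum at
`control mean depth × window_bins × 0.1` (exposed as `control_floor_frac` /
`--control-floor`). This pseudo-count-style floor prevents division by zero
while still letting control-depleted windows pass.

**Rank-sum test.** For windows up to 9 bins per side the p-value is exact:
mid-ranks are doubled to integers and the permutation null of the size-n
rank sum is built by a shift-algorithm dynamic program; `p = P(rank sum ≥
observed)`. For larger windows (including the default 30) the normal
approximation with tie correction and continuity correction is used,
matching the standard asymptotic Mann–Whitney test. When every value is
identical the p-value is 1 (no evidence). P-values are not
multiplicity-corrected: the design relies on the conjunction with four
companion filters, and the swap-based empirical FDR is the advertised error
control.

**Efficiency.** `call_peaks` evaluates thresholds (ii)–(v) vectorized over
every window (cumulative sums and a sliding maximum) and runs the rank-sum
test only on windows passing those four — under the conjunction the p-value
of a window that already failed a cheap threshold can never matter, and it
dominates the cost on megabin chromosomes. The generator `window_scan`
remains the reference implementation computing every statistic for every
window; a regression test keeps the two routes identical. In the
diagnostic rejection counts, (ii)–(v) count over all windows and (i) counts
candidates rejected by p.

**Merging.** Overlapping or abutting significant windows merge into one
peak spanning their union. Peak statistics: p = min over member windows,
fold = max, max intensity and summit from the highest ChIP bin in the span
(leftmost on ties). Peak coordinates are whole bins, so `end − start` is a
multiple of the bin size.

**Empirical FDR.** `FDR = (# peaks calling control against ChIP) / (# ChIP
peaks)`, both directions with identical parameters. The estimate is
reported as NaN when there are no ChIP peaks and flagged as unreliable
below 100 ChIP peaks — with few peaks the ratio is dominated by small-count
noise and can move non-monotonically under stricter thresholds.
`fdr_threshold_sweep` re-runs both directions across a user-supplied
ascending series of intensity thresholds (threshold (v), the peak-ranking
statistic).

## Figures

Figures are assembled as a backend-independent data model (per-panel bar
positions, heights and colors) and then rendered with matplotlib; tests
assert on the model, never on pixels, and rendering is a pure function of
its inputs. Conventions: ChIP read bars green, control blue, ChIP/control
ratio orange; bins inside called peaks are red on the ChIP and ratio panels
(the control panel keeps its own color so the baseline stays readable).
Gene models draw exons as thick lines and introns as thin lines. Region
pdfs paginate at 1 Mb per page. The chromosome-wide macro view re-sums raw
counts into large bins (default 100 kb), renormalizes with the same
per-chromosome formula, and colors bars red where ChIP/control strictly
exceeds the cutoff (default 1.0), black otherwise; macro bins empty in both
samples (assembly gaps) are drawn at 0. An optional GC-content track
(fraction of G/C among non-N bases per 500 kb window; all-N windows NaN)
can be computed from a FASTA.

## Simulator

The generator emulates the regimes the caller must distinguish:

* **Background**: fragments uniform over the placeable genome, strand
  Bernoulli(½). Reads are single-end, 36 bp, from 150 bp fragments.
* **Sharp sites** (~1 kb): fragment midpoints uniform within ±fragment/2 of
  the site center — a point-source binding footprint.
* **Broad domains** (10–100 kb): fragment starts uniform over the domain.
* **Pseudo-binding sites**: identical enrichment planted in *both* samples,
  mimicking open-chromatin input bias; the control comparison must absorb
  them.
* **Repeat families**: `n` identical copies of a unit; a read landing in
  any copy is emitted at the same offset in every copy with `NH = n`, so
  weighted coverage is preserved and multi-mapping is the only mappability
  feature modeled.
* **PCR duplicates**: a configured fraction of reads re-emits an existing
  fragment at an identical 5′ end under a fresh read name.

Read counts split multinomially between background and the excess mass
`(fold − 1) × width` of each planted site, so measured enrichment
approaches the configured fold. Output is SAM (with NH tags), an optional
Bowtie-text/BED twin for the other parsers, and a truth BED6 with the fold
in the score column. Identical seeds give byte-identical files.

What the simulator does **not** model: sequencing errors and base
qualities, paired ends, GC or chromatin-accessibility bias, mappability
gradients, fragment-length dispersion. Passing tests therefore demonstrate
the correctness of the pipeline's bookkeeping and decision logic under the
stated generative model, not performance on real libraries.

### Canned study conditions

* `sharp_peak_config`: 10 Mb genome (2 × 5 Mb), 1M reads/sample, 20 sharp
  1 kb sites at folds 5–15 — the transcription-factor regime.
* `broad_domain_config`: 6 × 50 kb domains at fold 3.8, 1M reads/sample —
  the histone-mark regime. Per-chromosome normalization divides ChIP by
  `N_i` *including* the planted excess (~8%), so the effective normalized
  fold is ~3.5: robustly above the fold cutoff at bin 1000 (window-sum
  noise ~2%), while the domain intensity at bin 10 (~5 normalized units)
  sits below threshold (v) = 6. Broad settings (bin 1000 / smooth 2000)
  therefore recover the domains nearly in full, while sharp settings
  (bin 10 / smooth 500) fragment them — the intended contrast between the
  two parameter families.
* `null_config`: background only, 100k reads/sample — enough depth that the
  per-bin background (~1.6 normalized units) leaves the intensity threshold
  far out of reach by chance, at a cost that allows 100 replicates in the
  test suite.

## Numerical and degenerate-input choices

* Difference-array binning can leave a ~1e-16 negative residue after the
  cumulative sum; values are clamped at 0.
* `T_b` rounding: ceiling before the max with 1 (the rule's wording fixes
  no rounding; ceiling is the conservative choice).
* Empty control track: threshold (iv) passes (no repeat evidence); empty
  ChIP track: thresholds (iii)/(v) fail, so no peaks.
* Best-hit ties, duplicate survival, and merge summits are all resolved by
  first-seen / leftmost rules, making every pipeline stage deterministic;
  re-running on identical inputs reproduces peak lists bitwise.
* Text wig dialects round to 4 decimals (round-trip tolerance 1e-4); the
  binary dialect (documented in `wigpeak.io`) round-trips bit-exactly.

## Problem sizes used in the checks

Acceptance-style checks run the sharp condition at 1M reads/sample on
10 Mb, the broad condition identically, 100 null replicates at 100k
reads/sample, 1000 random small windows against the brute-force rank-sum
enumeration, and 100 random ≤10 kb toy genomes against the per-base
binning oracle. These sizes were chosen so the statistical claims (95%
sensitivity bounds, FDR ≤ 5%, null rate ≤ 1 peak/replicate) are stable
across seeds while the whole suite stays convenient to run on a laptop.

## Known limitations

* Single-end model only; no fragment-size estimation from the data.
* No mappability or GC correction; repeat handling is via read weighting.
* The per-chromosome normalization makes tracks of sparsely covered
  chromosomes noisy (the formula is applied as defined; a genome-wide
  variant would change cross-chromosome comparability).
* The asymptotic rank-sum p is used at the default window width; exact
  enumeration is reserved for ≤9 bins per side.
* No replicate handling (IDR-style reproducibility analysis is out of
  scope); the empirical FDR is the only error control, and it is unreliable
  when peak counts are small or when the "control" is itself a ChIP sample.
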