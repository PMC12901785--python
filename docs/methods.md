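# Methods

## Signal chain

**Recording model.** A recording is a channels × samples voltage matrix in
µV at a sampling rate of 19,754 Hz, with a list of chip-recalibration
timestamps and the ADC rail amplitude in its metadata. Cleaning produces a
recording-wide boolean *sample mask*; all downstream statistics are
computed over valid samples only, and masks only ever shrink (stages
compose by logical AND).

**Recalibration excision.** HD-MEA chips recalibrate periodically
(~every 400 ms), injecting artificial spike-like transients. Every
timestamp invalidates a symmetric border of 100 samples on either side
(201 samples ≈ 10.2 ms per event, the timestamp sample included;
overlapping borders merge). The *effective duration* used for firing
rates is the count of valid samples over the sampling rate.

**Flash removal.** A sample belongs to a "flash" when at least half of
all channels exceed 90% of the rail amplitude in absolute value; flagged
samples are invalidated (± an optional pad). The fractions are
conventions exposed in the configuration — instrument saturation episodes
are qualitative events, not precisely specified ones.

**Bandpass.** A linear-phase FIR designed by the Remez exchange
algorithm: passband 150–3000 Hz, transitions [100, 150] and
[3000, 3100] Hz, 513 taps, stopband weight 5. The narrow upper transition
is deliberate: wide, strongly asymmetric don't-care bands let the
exchange algorithm park large unconstrained peaks inside them (we
observed ~67 dB of transition-band gain with a [3000, 3300] band, which
destroys detection). The default design passes a 1 kHz tone within
±1 dB and attenuates 50 Hz mains by ~55 dB. Filtering is applied per
contiguous valid segment — invalid samples are excluded, not zero-filled,
because zero-filling creates step edges whose filter response mimics
spikes. The acquisition-side 100 Hz high-pass is treated as a property of
the input data and not re-applied.

## Spike detection

The event threshold at each sample is mean ± k·SD (k = 5) over a moving
window of ⌊5 ms · fs⌋ = 98 samples. Two window conventions are
implemented:

* *centered* — the window centred on the sample, the sample included;
* *trailing* (detector default) — the 98 samples strictly before it.

The trailing convention is load-bearing. Including a spike in its own
98-sample SD estimate raises the 5·SD threshold above the spike peak for
**any** amplitude: firing requires the filtered waveform's energy ratio
Σ(w/peak)² to stay below window/k² ≈ 3.9 samples, while any waveform
bandlimited to 150–3000 Hz at 19,754 Hz has ≥ ~3.5–5 (a matched filter
impulse response achieves the minimum ≈ 3.5). A centred event-including
window therefore never fires in practice; the causal window excludes the
event and detects normally. Trailing thresholds additionally require at
least half a window (49 samples) of valid history — SD estimates from a
handful of samples directly after a masked gap fire spuriously.

An excursion is a maximal run of consecutive valid samples strictly
beyond either threshold; runs shorter than 2 samples are discarded
(bandlimited spikes stay suprathreshold for several samples at ~20 kHz,
single-sample crossings are noise riding on a fluctuating SD estimate),
runs closer than a 1 ms refractory gap merge, and the spike time is the
sample of maximum absolute deviation from the local mean. Detection is
two-sided: extracellular spikes are predominantly negative, but positive
deviations count as well.

At the synthetic generator's default signal-to-noise ratio of 8 (80 µV
spikes in 10 µV noise) this detector scores ~0.99 sensitivity at ~0.03
false discovery against ground truth.

**Channel and organoid summaries.** Channel rate = spike count /
effective duration. Channels above 5 Hz (abnormal multi-unit rates,
typically electrode artifacts) are excluded *before* ranking; the
remaining channels are ranked by rate (ties broken by channel id) and the
top 30 kept. An organoid enters group statistics when the mean rate of
its selected channels is ≥ 0.5 Hz (the boundary itself is inclusive).

## Group statistics

Unpaired two-tailed t-tests accept raw values or published
(mean, spread, n) summaries; unlabeled "±" spreads default to SEM, the
reading under which published growth summaries reproduce their printed
p-value. One-way ANOVA uses the classical between/within decomposition;
pairwise comparisons use the pooled within-group mean square
(df = N − g) and the Šídák adjustment p_adj = 1 − (1 − p)^m with
m = number of requested comparisons (default: all pairs). The adjustment
is computed as −expm1(m·log1p(−p)) so that p_adj ≥ p holds down to
underflow. The outlier screen reduces the robust-fit-plus-FDR idea to the
one-sample location case: median centre, normal-consistent MAD scale,
two-tailed normal p per point, Benjamini–Hochberg flagging at q = 0.01.

## Transcriptomics

Genes are filtered to those with TPM > 0.1 in at least 7 of 20 samples
(idempotent). For a contrast A vs B, a gene is a DEG when all three hold
strictly: |mean_A − mean_B| > 4 (linear TPM), fold change
max/min > 2 (means floored at 0.01 TPM), and p < 0.05 from a two-tailed
pooled t-test on log₂(TPM + 1). The difference threshold is read in
linear TPM (the unit of the matrix) and the log offset is configurable —
both are conventions where the source analysis states only
"log-transformed data". No multiple-testing correction is applied at
this stage; the conjunction with the two effect-size thresholds is the
false-positive control (on a 5,000-gene null matrix the raw-p rate is
~5% and the DEG count ~0). Heatmap z-scores standardize each gene across
samples to mean 0 and unit sample SD (ddof = 1, the convention under
which a 2-sample row gives ∓0.7071).

**Overlap statistics.** RF = x·N/(n₁·n₂) with the exact hypergeometric
upper tail. The background N defaults to the number of genes surviving
the expression filter. For checks against the published overlap triple,
N is reconstructed by inverting the RF formula on the first printed case
(N = 26,295); the second case is then reproduced to rounding while the
third implies a slightly smaller background (~24.6k) — the printed
values are mutually inconsistent at any single N, and the package
reports its computed value (2.57 vs printed 2.4) rather than matching it.

**Enrichment.** Over-representation: per-set hypergeometric upper tail
against the background, Benjamini–Hochberg q across sets. Pre-ranked
GSEA: ranking metric sign(log₂FC)·(−log₁₀ p) with deterministic gene-id
tie-breaks; weighted KS running sum (weight 1); nulls by gene-set
permutation (n_perm = 1000), shared between sets of equal size —
statistically identical and much cheaper; NES by same-sign null means;
FDR from the pooled normalized null. Gene-set permutation rather than
phenotype permutation is forced by design: with n = 5 per group,
phenotype permutation is degenerate.

## Synthetic data

The MEA generator emulates spontaneous multi-unit activity: homogeneous
Poisson spike trains on an active channel subset, a stereotyped biphasic
waveform (~1 ms; sharp negative lobe, smaller positive rebound; ±20%
amplitude jitter), Gaussian noise (10 µV SD), 1 ms square recalibration
pulses on all channels at exact multiples of 400 ms, and 5 ms rail-level
flashes on 90% of channels at ~0.02 events/s. It does **not** model
bursting, waveform diversity across units, electrode drift, or
correlated noise — passing detection tests show threshold-crossing logic
is correct, not that the detector separates overlapping units.

The expression generator draws per-gene log₂-TPM baselines from
N(4, 2²), adds a maturation effect (+2 log₂ on 400 genes, 88% up) to
both 90-div groups, a treatment effect at 60 div (+2 log₂ on 40 genes,
80% of them drawn from the maturation-up set — the overlap structure the
representation factor probes) and an opposing one at 90 div (−2 log₂ on
60 genes), then Gaussian noise (0.25 log₂ units) and TPM = 2^x. Effects
are exact fold changes by construction; the generator does not model
library-size artifacts, count noise at low expression, or gene-gene
correlation, so calibration results speak to the statistics, not to
RNA-seq preprocessing.

The end-to-end synthetic study uses the emulated design: 8 organoids per
group (32 total), per-group mean rates 1.0/2.0/2.5/2.5 Hz
(mock-60/propofol-60/mock-90/propofol-90) with lognormal
organoid-to-organoid jitter (σ = 0.15), and two deliberately inactive
late-stage mock organoids (0.02 Hz) — the configuration under which 30 of
32 organoids (93.75%) pass the 0.5 Hz floor. Every simulated channel is
an active site: the study design keeps the top-30 most active channels
of a dense array, which are the firing ones, and simulating thousands of
silent sites would only dilute the organoid mean. Per-organoid recordings
default to 16 channels × 20 s (a scale chosen so a full run stays
desk-scale at ~30 s of compute; the statistics of interest are rate
ratios, which do not need 5-minute recordings to stabilize).

## Numerical and degenerate-input choices

* Moving-window variance uses cumulative sums after centring on the
  global valid mean (the E[x²] − E[x]² shortcut otherwise loses
  ~√ε·|x| of precision; a constant trace yields exactly SD 0).
* Hypergeometric tails are computed in log space (scipy), exact to
  1e-12 against full enumeration for all N ≤ 12.
* Fold changes floor group means at 0.01 TPM; zero-variance t-tests
  report p = 1 for identical groups.
* Constant genes cannot be z-scored and are reported by name; empty
  channel selections, n < 2 groups, overlaps exceeding min(n₁, n₂) and
  final concentrations above stock are errors, not silent results.
* All randomness flows from numpy `SeedSequence` spawns of one seed;
  identical configurations are byte-identical end to end.

## Known limitations

* The detector is a threshold crosser: no spike sorting, bursting, or
  network-synchrony metrics.
* The ROUT-style screen is a re-derivation for the constant-location
  case, not a reimplementation of the proprietary robust-regression
  variant.
* GSEA FDR follows the gene-set-permutation procedure; values are not
  comparable to phenotype-permutation FDRs on the same data.
* The synthetic study fixes treatment effects as step changes on
  log-expression; it cannot surface dose–response or pharmacokinetic
  structure (tissue-concentration decay is handled only as unit
  conversion).
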