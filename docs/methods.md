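# Methods

## Scope

`plinet` implements the interictal scalp-EEG network-analysis chain used
in clinical studies of temporal lobe epilepsy (TLE): preprocessing,
phase-lag-index (PLI) functional connectivity per frequency band,
weighted small-world metrics, minimum-spanning-tree (MST) metrics,
community structure, spectral summaries, and a cohort-level statistical
stage relating network features to seizure severity.  Because clinical
recordings of this kind are not publicly deposited, the package ships a
first-class synthetic-EEG cohort generator whose planted structure the
pipeline must recover; all validation rests on analytic oracles and on
that generator.

## Preprocessing

Recordings use the 25-electrode IFCN montage (10–20 plus the inferior
temporal chain F9/F10, T9/T10, P9/P10) at 500 Hz.  The chain is:

1. **Common average reference.** Subtract the instantaneous channel
   mean; the output mean across channels is zero at every sample.
2. **Broadband FIR band-pass, 0.1–45 Hz**, then per-band filters for
   delta (1–4), theta (4–7), alpha (8–13), beta (14–30), gamma
   (30–45 Hz) and the full band (1–45 Hz).  Applying the broadband
   filter before the per-band filters is a harmless composition and is
   the documented default.
3. **Epoching.** The first 90 s are cut into non-overlapping 10-s
   epochs (9 per recording) after filtering the continuous signal, so
   no filter transients sit at epoch boundaries.  A single 90-s epoch
   is available by configuration; connectivity stabilises for epochs
   longer than about 10 s, and both schemes are supported.

Filters are windowed-sinc (Hamming) linear-phase FIR designs with
transition width `max(1 Hz, 0.25·f_lo)` and the standard `3.3·fs/width`
tap count (odd), applied once with exact integer group-delay
compensation.  A symmetric FIR applied this way has exactly zero phase
response, which matters because PLI is a pure phase statistic; stop-band
attenuation is ≈ 53 dB.  ICA artifact removal is inherently manual and
is not implemented; `remove_components` accepts an externally supplied
unmixing matrix and zeroes chosen components.

## Connectivity: phase lag index

Per epoch and band, instantaneous phases come from the analytic signal
(frequency-domain Hilbert transform).  The first and last 0.5 s of each
epoch are discarded before any statistic to remove edge transients.  No
taper is applied before the analytic transform — tapering distorts
phase near epoch edges, and trimming makes it unnecessary; the Hann
taper is used only by the spectral estimator.

For channels *i, j*:

    PLI_ij = | mean_t sign( wrap(φ_i(t) − φ_j(t)) ) |

with the difference wrapped to (−π, π] and `sign(0) = 0` exactly (some
implementations map 0 → +1; the mathematical convention is kept and the
zero-lag case then yields PLI = 0, which is the statistic's defence
against volume conduction).  Per-epoch matrices are averaged
element-wise.  PLI is invariant to channel amplitude scaling and to
common phase offsets; both are property-tested, and the vectorised
implementation is tested to 1e−12 against a literal sign-mean double
loop.

## Weighted network metrics

Electrodes are nodes; PLI weights are affinities and `1/PLI` the edge
distance, with zero-PLI edges capped at affinity 1e−6 (distance 1e6) so
the graph stays formally connected while such edges never win a
shortest path.  Metrics are computed for the whole 25-node network and
the 16-node frontotemporal subnetwork (Fp1, Fp2, F3, F4, F7–F10,
T7–T10, P7–P10).

* **Mean PLI** — mean of the upper-triangle weights.
* **Clustering coefficient (CC)** — geometric-mean triangle intensity
  per node, averaged.  Because PLI weights already live in [0, 1], the
  default uses the raw weights, keeping CC in [0, 1] and monotone in
  every weight.  The Onnela convention of rescaling by the graph
  maximum is available (`norm="max"`); note that under max-rescaling a
  *localised* increase in coupling can lower CC (the maximum grows
  faster than the typical normalised triangle), which inverts the
  expected direction of the clinical effect — the raw-weight default
  avoids that pathology.
* **Characteristic path length (PL)** — mean shortest-path 1/PLI
  distance over all pairs (Dijkstra), arithmetic mean; lower PL means a
  more integrated network.

## Minimum spanning tree

Kruskal's algorithm on the 1/PLI distances, with ties broken by the
lexicographic label pair so trees are reproducible across platforms.
Summaries: diameter **D** in hops (a normalised `D/(M−1)` is also
emitted), leaf number/fraction **LN/LF**, betweenness centrality **BC**
(on a tree, the number of node pairs whose unique path crosses the
node; normalised by `(M−1)(M−2)/2` so BC_max ∈ (0, 1]), tree hierarchy
**TH = LN / (2·m·BC_max)** with `m = M−1` edges (TH of a star is then
exactly 0.5 at any size), and **kappa = ⟨k²⟩/⟨k⟩**, the broadness of
the degree distribution.  Raw (unnormalised) BC is emitted alongside.
Whether the clinical literature's D is hop count or summed distance is
ambiguous; hops are the dominant convention and the default here.

## Community structure

Weighted Newman modularity

    Q = 1/(2M) Σ_ij (a_ij − k_i k_j / 2M) δ(C_i, C_j)

with `a` the PLI weights, `k` node strengths, `2M` the total weight
counted both directions and δ = 1 within a module.  Q of the trivial
single-module partition is identically 0.  Detection enumerates every
set partition exactly for graphs up to 8 nodes and otherwise runs 20
seeded Louvain restarts keeping the best Q; if no split beats the
trivial partition the single module is returned.  The participation
coefficient `P_i = 1 − Σ_s (κ_is/k_i)²` (κ_is = strength of node *i*
into module *s*) is 0 for purely intra-modular nodes and bounded by
`1 − 1/N_M`; isolated nodes yield NaN with a warning.

## Spectral summaries

Welch periodograms (2-s Hann segments, 50 % overlap) estimate P(f).
Mean frequency is the power-weighted mean `Σ P(f)·f / Σ P(f)`,
evaluated on 1-Hz bins over 1–45 Hz by default — power above the 45-Hz
filter edge is zero, so a wider printed grid would only sum zeros.  The
frontal laterality index is

    LI = (P_left − P_right) / (P_left + P_right)

over the left (Fp1, F3, F7) and right (Fp2, F4, F8) frontal triples;
the band underlying a reported frontal LI is a free choice, so the
broadband value and all per-band values are emitted.

## Synthetic cohort generator

The generator is a parametric stand-in, not a biophysical model.  Each
channel is a sum of narrow-band Gaussian components (band-passed white
noise — not sinusoids, so PLI estimation faces realistic phase jitter)
with eyes-closed-like amplitudes (alpha dominant) plus 1/f noise.
Coupling is produced by shared band-limited oscillators injected into
chosen channels with constant per-node phase lags, imposed by
time-shifting the shared component by `lag/(2π·f_center)` seconds.  An
oscillator of strength *f* on a channel is injected with variance
`f/(1−f)` times the background variance, so each band's
signal-to-background ratio depends only on its own coupling and the
per-channel variance is predictable from the specification.

The default cohort emulates a TLE case–control study:

* **Patients** (left/right/bilateral in proportions 56/55/40) carry a
  theta oscillator over the affected frontotemporal chain with lags
  staggered in π/8 steps (every coupled pair has a nonzero lag, hence a
  nonzero PLI), hub-weighted gains falling from the temporal focus
  (1.0 → 0.5) and a weak contralateral spill-over (gain 0.3).  The
  hub profile is what drives the MST toward a star-like backbone —
  and hence a shorter diameter — as coupling grows.
* **Severity** is log-normal with median 40 (σ = 1.5; the implied SD
  ≈ 356 is close to the clinical scale's dispersion, while matching the
  reported interquartile range exactly would force implausibly extreme
  tails).  The severity→strength link is linear in log-severity
  (intercept 0.01, slope 0.045 per log-unit, Gaussian noise SD 0.025,
  clipped to [0.01, 0.30]), placing typical patients' theta-band
  signal-to-background ratios in the non-saturating range where the
  frontotemporal theta PLI spans roughly 0.15–0.45, as in clinical
  reports.
* **Everyone** additionally carries severity-independent background
  structure that real cohorts have and that matters for specificity
  testing: per-subject log-normal scaling of component amplitudes
  (log-SD 0.2), a widespread posterior-dominant resting-alpha network
  (stronger on average in controls — the control-group signature), a
  global broadband synchrony level, and a small random theta-synchrony
  patch (3 random electrodes, random lags).  Without these, broadband
  network features are noise-free duplicates of the theta features and
  any feature-selection test is meaningless.

All randomness flows from one root `SeedSequence`; identical
specifications give byte-identical cohorts.  What the generator does
**not** emulate: volume conduction and field spread, artifacts (ocular,
muscle, electrode), interictal spikes and ictal activity,
non-stationarity over the 90 s, and real electrode geometry.  Passing
recovery tests therefore shows the *pipeline* is sound, not that the
effect exists in any real population.

## Clinical covariates and statistics

Synthetic subject records carry the covariates a TLE severity study
collects (age, onset, duration, seizure-frequency class, drug
resistance, ASM count, histories, and binary/ordinal stand-ins for
seizure symptoms: aura, focal-to-bilateral generalisation, post-ictal
confusion, seizure duration).  Apart from the severity score they are
drawn independently of the planted coupling, so they act as inert
candidates for specificity.

The statistical stage mirrors SPSS-era clinical practice: one-way ANOVA
with Tukey HSD across lateralisation groups; Spearman rank correlation
between each metric and severity among patients; and stepwise linear
regression of the raw severity score (entry p < 0.05, removal
p > 0.10, forward with backward removal) on z-scored candidates, so
reported coefficients are standardized β.  Complete cases only;
constant and collinear candidates are excluded with a logged note.  No
multiple-testing correction is applied to the metric-wise tests by
default (matching the practice the pipeline reproduces); a
Benjamini–Hochberg helper is deliberately out of scope.  Note the
consequence of the stepwise entry rule: with k inert candidates the
null probability of an empty model is 0.95^k (≈ 0.74 at k = 6, ≈ 0.57
at k = 11) — stepwise selection is *not* a 5 % family-wise procedure,
and the tests assert exactly the rate the rule implies.

## Numerical choices and degenerate inputs

* Phase wrap uses (−π, π]; the −π boundary is folded to +π.
* PLI requires ≥ 100 phase samples and ≥ 2 channels; zero-variance
  channels raise an error naming the channel.
* Distances: 1/PLI with the 1e−6 affinity cap; PL errors on any
  infinite distance (unreachable with the cap).
* Kruskal tie-break: (distance, label pair) lexicographic.
* Louvain restarts draw child seeds from one generator; detection below
  9 nodes is exact enumeration.
* EDF output quantises to 16 bits over each channel's physical range;
  sub-second tails are dropped (EDF stores whole 1-s records).

## Problem sizes

Validation runs at desk scale by design: the end-to-end recovery cohort
is 60 patients + 20 controls at 90 s × 500 Hz × 25 channels; oracle
checks use graphs of up to ~10 nodes (where exhaustive enumeration over
spanning trees or set partitions is feasible) and calibration uses
100–1000 Monte-Carlo replicates.  These sizes make the full suite
reproducible on a single CPU while keeping every comparison against an
exact oracle.

## Known limitations

* The generator's coupling topology is low-rank (a few shared
  oscillators); real interictal networks are far richer, and metric
  collinearity here is stronger than in real data even after the
  background-variability components.
* The severity link and its calibration are stand-ins chosen to place
  network features in clinically reported ranges; effect sizes in the
  synthetic cohort are design choices, not estimates.
* Source localisation, artifact handling, and scalp-map rendering are
  out of scope.
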