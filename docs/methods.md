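# Methods

`organoidmea` analyses intra-organoid multi-electrode array (MEA)
recordings: extracellular voltage traces collected by soft pillar
electrodes embedded inside a 3D brain organoid. This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Signal chain

**Filtering.** Recordings are sampled at 24 414 Hz. Single-unit (SU)
activity is isolated with a 300–3000 Hz band-pass, local field potentials
with 0.1–300 Hz; a 60 Hz notch removes mains interference. The filter is
a 4th-order Butterworth applied forward–backward (zero phase), because
zero-phase filtering preserves spike timing; the notch is a narrow
band-stop (Q = 30) run in float64 regardless of input precision, since
its poles sit very close to the unit circle. Only the SU band feeds the
downstream network analysis. float32 input stays float32 end to end
(half the memory, several-fold faster; the worst-case deviation from a
float64 path is ~1e-4 µV against a 13 µV noise floor).

**Spike detection.** A sample is a spike peak when it is a local minimum
below `threshold_mult × SD` of its channel (default −5 × SD; spikes are
negative-going, hence the peak-is-minimum convention). The SD is
estimated robustly as `median(|x|)/0.6745`, which equals the Gaussian SD
on noise but is barely inflated by the spikes themselves; the raw sample
SD is available (`sd_estimator="raw"`) for comparison — whether the
original analysis used a spike-free segment or the whole trace is not
derivable, so both are offered with the robust form as default. Peaks
closer than `dead_time` (default 1 ms) merge to the deeper one, an
interpretation of sub-millisecond threshold re-crossings as one
refractory event. An all-zero channel (SD = 0) yields an empty train
rather than an error.

**Waveforms.** Each retained peak yields a snippet of the odd sample
count nearest `window × fs` (97 samples for 4 ms at 24 414 Hz; exact
ties resolve to the shorter length), centred on the peak. Spikes too
close to the recording edges are dropped and counted.

**Sorting.** Per channel — each electrode's clusters are reported
separately, so pooling across channels is deliberately not done —
waveforms are centred, projected onto their top two principal
components, and partitioned by k-means over k ∈ {2, 3}. The cluster
count is chosen by silhouette score by default; `k_selection="fixed"`
forces the first admissible k for the manual two-or-three workflow.
k-means uses k-means++ seeding with 10 restarts from the stage seed
(best inertia kept), making sorting deterministic given the seed and
invariant to common amplitude rescaling (PCA and k-means both commute
with a positive scalar on all waveforms up to the same relabelling).
Fewer than two distinct waveforms yield one trivial cluster.

**Spikeform similarity.** Pearson correlation between spikeform vectors.
Cluster sets (e.g. before vs after tilting an electrode) are compared by
greedy best-r matching of mean spikeforms with each mean used at most
once; the reported value is the mean r over matched pairs. Greedy
matching is the minimal completion of a pairwise comparison the source
workflow leaves unspecified.

## Burst detection

MaxInterval semantics with five thresholds: a burst opens at an ISI ≤
`max_isi_start`, extends while ISIs ≤ `max_isi_in`, bursts separated by
< `min_ibi` merge (absorbing any spikes between them), and bursts
failing `min_duration` or `min_spikes` are discarded. Burst start/end
are the first/last spike of the run. Two presets ship:

- `DEFAULT_BURST_PARAMS` = (300, 301, 10, 50, 200) — the five printed
  threshold values taken as-is, times in milliseconds (the only unit
  under which they are physically sensible).
- `ORGANOID_50MS_BURST_PARAMS` = (300 ms, 301 ms, 50 ms, 50 ms, 10
  spikes) — a usable preset for organoid firing rates: a 200-spike
  minimum is unreachable within plausible burst durations at ≤ 9 Hz
  mean rates, and 50 ms matches the minimum burst duration quoted with
  the maturation results. The pipeline default is this preset; the
  printed values remain available unchanged.

The detector is verified against an exhaustive candidate-run enumeration
for every parameterization tested, including `max_isi_start >
max_isi_in`.

## Synchronization score and network mapping

**SPIKE-distance.** The time-resolved, parameter-free dissimilarity
between two spike trains on [0, T]. With auxiliary spikes appended at 0
and T to both trains, at time t each train n has previous/following
spikes tP_n/tF_n, xP_n = t − tP_n, xF_n = tF_n − t, xISI_n = tF_n −
tP_n, and ΔtP_n (ΔtF_n) the distance from tP_n (tF_n) to the nearest
spike of the other train:

    S_n(t) = (ΔtP_n·xF_n + ΔtF_n·xP_n) / xISI_n
    S(t)   = (S_1·xISI_2 + S_2·xISI_1) / (2·⟨xISI⟩²),   ⟨xISI⟩ = (xISI_1+xISI_2)/2
    D      = (1/T) ∫₀ᵀ S(t) dt

S is piecewise linear between pooled spike times, so the integral is
evaluated exactly by trapezoids on that partition — no discretization
parameter exists. D = 0 iff the trains are identical. Tests verify the
closed form against a dense Riemann integration and an independently
coded scalar implementation (agreement ~1e-11).

**Score.** `score = clip(1 − D/⟨D_baseline⟩, 0, 1)`, where the baseline
mean is the SPIKE-distance averaged over `n_baseline` (default 1000)
pairs of sorted uniform-random trains on [0, T]. Baseline trains are
spike-count-matched to the observed pair, so the null is rate-matched
and the score reflects timing structure rather than firing rate; the
baseline-mean cache is keyed by the unordered count pair, which keeps
the 1000-surrogate normalization affordable over many electrode pairs.
Identical trains score exactly 1; independent trains score near 0, with
negative excursions clipped to 0 so the score lives on [0, 1].

**Network.** Channels with fewer than `min_spikes_active` spikes
(default 5) are excluded as inactive; with fewer than two active
channels the synchrony stage emits an empty matrix. Active electrodes
become nodes at their 3D coordinates; pairs scoring ≥ `edge_threshold`
(default 0.5, the boundary retained) become edges weighted by the
score. Communities are found by Louvain modularity optimization
(weighted, resolution 1) with 10 restarts from the stage seed, keeping
the best-modularity partition — Louvain is a greedy heuristic and
single runs can stall in local optima on weak-structure graphs (on
random 8-node graphs, restarts raise the fraction of runs within 95% of
the exhaustive-search optimum from ~86% to ~96%; the residual misses
are genuine local optima). Isolated nodes and members of singleton
communities are labelled "no community", matching how uncommitted nodes
are counted in maturation summaries. Network metrics: mean degree,
total edges, connected-node count, community count, no-community count,
mean and maximum community size.

## Tilt geometry

A pillar electrode of height h tilted by θ sweeps its tip along an arc
d = 2πhθ/360. Arc length, not the chord 2h·sin(θ/2), is used
throughout: the arc form is self-consistent with the minimum-height
relation h = d·360/(2πθ) and reproduces all four published working
points (138 µm, 161 µm, 234 µm, 0.009 µm) after rounding, which the
chord does not at the largest angle. The tilt angle recovered from
tracked tip coordinates is θ = atan(|x₂−x₁|/z₂). Trajectory fits are
ordinary least squares of θ and |x−x₁| against magnet displacement.
Known tension left unreconciled: the measured tip-displacement slope
(0.0140 µm/µm) is ~8% below the arc-relation prediction from the
measured angle slope (0.0152 µm/µm); the package reports both fits and
does not force agreement.

The swept detectable area of a tilting electrode is the area of the
union of its trajectories dilated by the tip radius r = √(A_tip/π)
(default A_tip = 78.5 µm², r ≈ 5 µm), computed as an exact polygonal
union rather than on a raster — the polygon union has no resolution
parameter and is verified against a Monte-Carlo point-in-union oracle
to 2%. A motionless trajectory contributes exactly one tip-sized disc
(ratio 1).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with maturation presets carrying published summary statistics:

| preset | rate (Hz) | mean ISI (s) | bursts/300 s | burst dur. (s) |
|--------|----------:|-------------:|-------------:|---------------:|
| 1mo    | 0.1*      | 10*          | 0*           | 0.5*           |
| 2mo    | 0.330     | 3.832        | 1.5          | 0.991          |
| 4mo    | 1.714*    | 1.701*       | 3.67*        | 1.215*         |
| 6mo    | 8.90      | 0.755        | 9            | 1.490          |

Starred values are placeholders, not measurements: the 4-month preset is
the geometric midpoint of the 2- and 6-month values, and the 1-month
preset is nominal sparse firing (traces exist for that age but no
printed rates). Burst counts are defined per 300 s recording and scale
linearly with the requested duration; 300 s is a package choice, as the
recording length behind the published per-recording counts is not
stated.

**Firing model.** Per community: burst windows (count Poisson with the
preset mean, lengths gamma-distributed with shape 9 so SD = mean/3
around the preset burst duration) define a two-state rate profile —
Poisson background plus a 25 Hz within-burst renewal process with a
3 ms refractory period. The background rate is set so the total
expected rate equals the preset rate. Synchrony uses mother-train
thinning: each channel draws an independent realization at fraction
(1 − sync_strength) of the rate profile and copies mother-train events
with probability sync_strength, jittered by Gaussian noise (default SD
2 ms). Expected per-channel rate is independent of sync_strength.
25 Hz within bursts keeps a ~1 s episode well above a 10-spike minimum
with ISIs far below the 300 ms threshold; the 3 ms refractory period
bounds the spike loss from the detector's 1 ms merge rule.

**Rendering.** Each spike inserts its unit's biphasic template (dominant
negative Gaussian lobe, smaller positive after-lobe, ≤ 2 ms support,
rescaled so the minimum equals −amplitude exactly at the centre sample)
at the nearest sample; 2–3 units per channel with amplitudes tapering
(1.0/0.75/0.55 × the 100 µV default). White Gaussian noise of 13 µV RMS
is added. Tilt events swap affected channels to a disjoint unit set
after a switch time, emulating contact with a new neuron group.

**What the generator does not emulate** — and hence what passing tests
do not show about real recordings: correlated or non-Gaussian noise,
electrode drift and impedance variation, waveform superposition effects
at coincident spikes, LFP-band oscillations, biophysical spike shapes,
and non-stationary firing beyond the two-state burst model. Tests
verify the analysis chain against its own assumptions, not against
biology.

## Determinism and numerics

All randomness flows from one root seed, split per stage by stage name
(SeedSequence over a CRC of the name, kept below 2³¹); repeated pipeline
runs are byte-identical. Scores are clipped to [0, 1]; a degenerate
(zero) baseline, empty trains in a distance, fewer than two spikes in an
ISI, and zero-variance spikeforms are signalled as errors rather than
returning sentinel values — except the rate fold-change after a
treatment, which returns `inf` for a silent pre-treatment train so
multi-channel sweeps keep running.

## Problem sizes

The packaged verification runs use desk-scale sizes chosen as a
compromise between statistical resolution and a desktop CPU: rate
recovery through the full detection chain uses 6 recordings × 60
channels × 300 s per preset in the reproduction script (processing one
channel's trace at a time, so peak memory stays near a single 300 s
channel) and 12–24 channels × 300 s in the test suite; the sweep of
synchrony strength uses 12 channels × 60 s with a 1000-fold (script) or
200-fold (tests) baseline normalization. Exhaustive-search checks
(bursts, modularity) run at sizes where enumeration is exact (≤ 30
spikes; 8 nodes, 4140 partitions).

## Known limitations

- The five printed burst thresholds conflict internally with the quoted
  50 ms minimum duration; the package ships both readings rather than
  guessing intent (see presets above).
- Louvain is heuristic; restarts reduce but do not eliminate local
  optima (quantified above).
- The synchronization-score baseline assumes the full recording
  duration T as the surrogate window; a normalized window would change
  scores for strongly bursty trains.
- Per-channel (not per-sorted-unit) spike trains feed the synchrony
  matrix; electrodes mixing several units report their pooled timing.
- Arc-length tip kinematics ignore elastic bending of the pillar, one
  candidate explanation for the 8% slope tension noted above.
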