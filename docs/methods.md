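# Methods

`tactrf` measures the neural tracking of continuous, unpredictable tactile
stimulation: it estimates a temporal response function (TRF) that maps the
low-frequency envelope of brush–skin friction onto multichannel EEG, and
tests that estimate against permutation nulls with spatiotemporal
cluster statistics. Because no public recordings accompany the protocol,
the package ships a forward simulator of the whole study, and every claim
the test suite makes is a claim about that simulator plus the estimation
machinery — see "What the simulation does and does not show" below.

## The encoding model

The stimulus feature is a single envelope `s(t)` in [0, 1], sampled at
64 Hz. For each EEG channel `r(t)` (z-scored per one-minute segment), the
TRF `w(τ)` solves the regularized least-squares problem

    min_w  Σ_t ( r(t) − Σ_τ w(τ) s(t−τ) − b )²  +  λ ‖w‖²

over lags τ from −400 to +600 ms. On the 64 Hz grid the lag indices run
from floor(−0.4·64) = −26 to ceil(0.6·64) = 39, i.e. 66 lags; the window
never shrinks under rounding. The intercept `b` is never penalized. The
solver uses the penalized normal equations `(XᵀX + λP) w = Xᵀy` with `P`
the identity zeroed at the intercept column; tests verify it against an
independent augmented-least-squares route (QR/SVD) to 1e-10 relative error.
Lagged design columns are zero-padded at segment edges rather than
trimmed; this biases weights near the edges by O(lag span / segment
length) ≈ 1.7% for one-minute segments, which is negligible against the
permutation nulls used for inference.

The ridge parameter comes from leave-one-out cross-validation over the
decade grid 1e-6…1e8: for each held-out segment the channel-mean MSE is
recorded at every grid value, each fold votes for its minimizer, and the
value winning the most folds is selected (ties toward the smaller λ —
less complexity). On the simulated study this procedure selects λ = 1e2,
which is kept fixed across subjects and conditions as the pipeline
default. The per-subject TRF is the unweighted average of the
leave-one-out fold models; grand averages are means across subjects
within a condition.

Note that λ is only meaningful relative to the scale of `XᵀX`; a plain
λI penalty is used here, so grids from toolboxes with internal rescaling
correspond to a relabeled grid, not different models.

## Preprocessing

Real recordings pass through: Hann-window FIR band-pass 1–40 Hz
(high-pass order 500, low-pass order 100, at 500 Hz) → downsample to
250 Hz → average reference → Hann-window FIR band-pass 0.5–6 Hz (orders
2000/200) → downsample to 64 Hz → epoch at stimulation onset shifted by
the fixed 89 ms sound-to-marker delay (nearest sample: 6 samples at
64 Hz; the EEG segment start moves later) → consecutive one-minute
segments → per-channel z-scoring. All FIR filters are applied zero-phase
by compensating the symmetric filter's group delay: a causal order-2000
FIR at 250 Hz would delay the signal by 4 s and corrupt TRF latencies.
Artifact removal (ICA, bad-channel interpolation) is out of scope; a
`cleaning_hook` lets users insert an external step between the broad
filter stage and re-referencing. Envelope extraction is |Hilbert| →
3rd-order Butterworth low-pass at 6 Hz (zero-phase by default, for the
same latency reason) → polyphase resample to 64 Hz (line-extrapolated
boundaries, since envelopes have nonzero mean and zero padding would ring)
→ division by the maximum, with an all-zero flag instead of 0/0.

## Statistics

*Null TRF.* Each permutation re-pairs every EEG segment with a different
envelope of the same condition (a derangement — no segment keeps its own
stimulus; for the 2-segment case the swap is the unique derangement),
refits the full leave-one-out-averaged subject TRF, and the null TRF is
the mean over 100 permutations. This is the noise floor of the method:
anything the mismatched model recovers is structure not attributable to
the stimulus pairing.

*Cluster test.* Tactile vs null (or vs control, or condition vs
condition) TRF arrays enter a paired spatiotemporal cluster-based
permutation test: element-wise paired t over subjects, thresholded at the
two-tailed α = 0.05 critical value (df = n−1; the sample-level threshold
is a convention, not a claim), sign-specific connected components under
scalp adjacency × lag contiguity, cluster statistic = summed t.
The Monte-Carlo null flips condition labels within random subject
subsets and records the maximum |sum t| per permutation; p-values count
the observed statistic (floor 1/(n_perm+1)) and are judged at 0.025 per
tail. Windows: 0–400 ms against null/control, 50–400 ms between
conditions. Adjacency is a 0.052 m distance threshold on the idealized
64-channel geodesic montage bundled with MNE — the smallest round value
at which no electrode is isolated; it yields a median of 5 neighbors.

*Effect sizes and behavior.* Cohen's d for paired contrasts uses the
small-sample correction (1 − 3/(4·df − 1)) and a 1000-resample percentile
bootstrap CI. d′ is z(hit) − z(false alarm) with the 1/(2N) adjustment
for extreme rates; equal rates give exactly 0.

*Minimum data.* For k = 2…9 one-minute segments, subject TRFs and their
null TRFs are refit on the first k segments; the per-subject scalar is
the mean TRF weight over the contralateral focal electrode set within
50–170 ms (the early positive response — the protocol does not fix this
scalar, so it is a documented package choice); tactile vs null enters a
paired t test at the Bonferroni-corrected α = 0.05/8 = 0.00625, with a
Shapiro–Wilk normality screen logged per k.

## The forward simulator

Brush strokes are a Poisson process (rate 1.5 strokes/s) thinned to
forbid overlap, with uniform 0.2–0.5 s durations and log-normal unit-mean
amplitudes (CV 0.3); each stroke is rendered as a raised-cosine bump and
the summed envelope is max-normalized. These rates put ≥97% of envelope
power below 6 Hz, matching the spectral concentration of the recorded
friction sound, while keeping the envelope broadband enough that the
ridge operating point λ = 1e2 does not smear the kernel: with slower,
longer strokes the design becomes so narrowband that even noise-free
estimation shifts peak latencies by 1–2 samples, violating forward-model
consistency (noise off ⇒ the TRF module recovers the kernel). Stroke
statistics were fixed by that consistency requirement plus the spectral
target, not by any downstream test.

The ground-truth kernel has a positive peak at 140 ms over the central
electrodes contralateral to the stimulated hand (E22/E25/E26/E27/E28 for
right-hand stimulation, E42/E45/E46/E48/E49 for left) and a negative
bilateral peak at 245 ms at 0.8× the amplitude, each Gaussian in lag
(σ = 30 ms) and in scalp distance from the focal centroid (σ = 0.045 m).
Peak latencies snap to the 64 Hz lag grid: 140.625 and 250.0 ms. EEG is
the causal convolution of envelope and kernel plus noise: per-channel
random-phase 1/f (α = 1, 60% of variance) + white (20%) + a shared 1/f
component with spatially smooth gains (20%), unit mean variance by
construction. SNR is the ratio of convolved-signal variance to noise
variance on the focal set, −10 dB by default; "SNR" is stated this
precisely because the term is otherwise ambiguous. Subjects differ by a
log-normal kernel amplitude factor (CV 0.2). A single master seed plus
per-(subject, condition, trial) spawn keys make any trial reproducible
in isolation; the control condition generates envelopes but adds no
kernel contribution to its EEG.

Simulated stimulus and response are aligned by construction, so the
simulated path segments with zero onset delay; the 89 ms correction
applies to real recordings only.

## What the simulation does and does not show

Passing tests demonstrate that the estimation and inference machinery
recovers what was planted under realistic noise and study dimensions:
grand-average peak latencies within one sample of truth at SNR −10 dB,
exactly one significant positive and one negative cluster against the
null, tactile > null for every simulated subject, detection from 2
minutes of data, and type-I error within binomial bounds on pure-noise
experiments. They do not certify performance on real EEG: the simulator
omits artifacts, bad channels, inter-subject latency and topography
variability, non-stationary noise, and any nonlinearity of the
envelope–response relation. Two visible consequences: simulated effect
sizes (d ≈ 10 against the null) far exceed those reported for real
recordings (d ≈ 1–2), because between-subject variability is limited to
an amplitude factor; and the minimum-data analysis detects at 2 minutes
where real data needed 3. The simulator is a correctness instrument, not
a power calculator.

## Numerical choices and degenerate inputs

- Ridge at λ = 0 on a singular system raises with a suggestion to use
  λ > 0 (the 66-column lagged design of a sub-6 Hz envelope is
  near-singular; the CV grid never visits 0).
- Zero-variance channels fail z-scoring loudly (name included); zero
  variance in paired differences caps t at a ±1e6 sentinel (logged)
  rather than ±inf, and identical inputs give d = 0 by convention while
  a nonzero constant difference is an error.
- All-zero audio or stroke trains flag `all_zero` instead of dividing by
  zero; infeasible stroke packing (rate × max duration > 1) is an error.
- EDF output quantizes to 16 bits over each channel's range
  (round-trip error ≤ half a step); WAV stores float32 verbatim.
- Analysis problem sizes in the validation suite: the recovery analysis
  runs the full 27-subject design; the cluster test uses 500 Monte-Carlo
  permutations and the type-I study 200 replicates × 500 permutations,
  which bound the p-value resolution at 1/501 and the error-rate estimate
  at ±2·SE(0.05, 200) ≈ ±0.031.
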