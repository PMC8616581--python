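# Methods

`larvanet` re-implements, as a tested library, the quantitative machinery of
a larval *Drosophila* chemotaxis-and-circuits workflow: behavioral metrics
from midline tracks, a linear–nonlinear–Poisson (LNP) reverse-correlation
analysis of turn initiation, strong-connection filtering and similarity
clustering of a paired electron-microscopy connectome, and calcium-response
scoring with a variance decomposition. Because the raw assets of such a
study (behavioral video, EM volume, imaging stacks) are not shipped, a
synthetic-data layer generates inputs with the statistical structure each
analysis assumes; every pipeline stage can therefore be exercised
end-to-end, including full simulate-then-recover round trips.

## Behavioral metrics (`larvanet.trajectory`)

**Track filtering.** Objects tracked for less than 5 s or moving less than
one body length are rejected. "Moved" defaults to total path length (net
displacement would reject curled-but-active animals); `travel_metric="net"`
switches to net displacement.

**Turn angle.** The tracker's posture metric: fit a line to the posterior
2/3 of the 11 midline points (7 points) and take the anterior-1/5 point (2
points; index 0 is the head) most distant from it. The fit is total least
squares (perpendicular residuals) because spines have arbitrary
orientation. The defining quantity is a *distance* d; we convert to an
angle arctan(d / L) where L is the arc length along the spine from the
fitted segment's anterior end (point index 4) to the chosen point, which
makes the metric scale-invariant; the raw distance is exposed alongside
(`turn_angle(..., return_distance=True)`) since the original tracker's
units are ambiguous.

**Turn detection.** Maximal intervals with |turn angle| above a threshold
(default 20°) for at least 0.2 s. Head sweeps are the constant-sign
excursions of the signed bend within a turn; the accepted sweep is the one
whose side the post-turn heading change follows. Heading is the direction
of centroid velocity smoothed over 0.5 s (the tracker does not define
heading; this is our choice). Real trackers use richer posture state
machines — thresholded bend detection can split a multi-sweep turn whose
bend crosses zero into two events, so event *counts* on real data are
tracker-dependent; scripted-track tests pin the behavior implemented here.

**Navigation index.** Mean velocity along the gradient divided by mean
crawling speed, pooled over all frames of all tracks: +1/−1 for uniform
straight up/down-gradient crawling, 0 for unbiased motion.

**Orientation-conditioned turn rates.** Turn starts and run frames are
binned by heading relative to up-gradient (default 30° bins); per-bin rate
is N_turn/(N_frames·Δt) reported in turns/min with Poisson counting SEs.
The toward (|θ| ≤ 15°) vs away (|θ−180°| ≤ 15°) contrast uses a Welch Z
test: z = (m_a − m_b)/√(se_a² + se_b²), two-sided normal p.

**Stimulation-window statistics.** For pulsed-light screens (defaults:
15 s pulses at 30 s and 75 s), the onset response averages each metric over
0–5 s after light on, normalized to the 5 s pre-light baseline; the offset
response averages 2–7 s after light off, normalized to the last 5 s of
light. Turn angle is baseline-subtracted (degrees); speed is a fraction of
baseline. Statistics pool both pulses, then mean ± SE across tracks. The
5 s baseline lengths are our choice; windows are arguments.

## LNP reverse correlation (`larvanet.revcorr`)

The light stimulus is a Brownian random walk of red-light intensity on
[0, 255] updated at 112 Hz; behavior is sampled at 14 Hz (Δt = 1/14 s).

1. **Turn-triggered average (TTA).** Mean stimulus in 0.1 s lag bins around
   turn onsets (default window −10 s to +5 s; turns with truncated windows
   are excluded).
2. **Kernel fit.** The mean-subtracted, time-reversed pre-turn TTA is
   fitted by the impulse response of a third-order linear system,
   parameterized as three identical cascaded first-order stages,
   h(t) = k (t/τ)² e^(−t/τ) (the generic three-pole form; fitting uses
   pre-turn lags only, on causality grounds). Support is truncated where
   |h| < 10⁻³·max|h|.
3. **Filtering.** The mean-subtracted stimulus, block-averaged onto the
   14 Hz frame grid, is causally convolved with the kernel, which is scaled
   so the filtered signal x_f has unit variance over the entire stimulus
   history; the initial kernel-length transient is flagged.
4. **Rate function.** r(x_f) = N_turn(x_f)/N_all(x_f) · 1/Δt over x_f bins
   of width 0.25, where N_all counts frames in runs (turn-capable). The SE
   is the Poisson counting error √N_turn/N_all · 1/Δt. (Some sources print
   the SE formula identically to the rate — an evident typo.) The identity
   Σ r·N_all·Δt = N_turn holds exactly and is asserted in tests.
5. **Ratio of Gaussians (ROG).** With a Gaussian turn-triggered ensemble,
   r_ROG(x) = r̄ · [e^(−(x−μ)²/2σ²)/σ] / e^(−x²/2), with r̄ = N_turn/T
   (T = total run time), μ and σ² the mean and population variance of x_f
   at turn starts (sampled at the frame containing the turn start).
6. **Head-sweep-triggered averages.** As the TTA but time-locked to first
   head sweeps of a turn, split by accepted/rejected; the decision follows
   sweep onset, so positive lags are informative.

`TurnLNP(stimulus, turn_times, run_mask).fit()` runs 1–5 and returns a
results object with the fitted kernel, rate table, ROG parameters,
`summary()`, and plotting helpers.

### Identifiability and uncertainty

Two properties matter when validating recovery on simulated data:

* **Sign gauge.** (h, μ) → (−h, −μ) leaves the LNP model invariant, and
  reverse correlation recovers the pair only up to this joint flip. Recovery
  tests align the gauge (flip both if the kernel correlates negatively with
  truth) before comparing.
* **Shared-stimulus dependence.** Every larva sees the same stimulus, so
  turn-triggered x_f samples are strongly dependent across larvae; naive
  σ/√N standard errors understate the Monte-Carlo uncertainty severalfold.
  `TurnLNPResults.block_standard_errors()` estimates SEs from contiguous
  time blocks (default 10) and is what recovery tests use; the naive iid
  SEs are reported by `summary()` for reference.

## Connectome analysis (`larvanet.connectome`)

All rules operate on hemilateral (left/right homolog) neuron pairs;
ipsilateral and contralateral synapses both count.

* **Strong/reliable connections.** A pair-to-pair connection is strong iff
  the left and right presynaptic homologs each contribute ≥ 3 synapses onto
  the postsynaptic pair and the sum is ≥ 10. The sum is read as counting
  synapses onto both postsynaptic homologs combined; the thresholds are
  arguments. Unpaired neurons are excluded from the rule (it is defined on
  pairs) but retained in input-fraction denominators.
* **False-positive model.** With per-contact false-positive rate p = 0.0167
  (one error per 60 contacts) and uncorrelated errors, an entirely spurious
  n-contact connection occurs at rate pⁿ — 0.00028 for n = 2, one in
  ~3,586. Three coincident errors per side make the 3/3/10 rule safe.
* **Similarity.** Binary pair-level matrices are compared by
  matches/(matches + mismatches) over rows (outputs) or columns (inputs) —
  the Jaccard similarity of the supports; pairs with empty supports are
  null. Hierarchical clustering uses average linkage on 1 − similarity
  (configurable; the original analysis does not print its linkage), with a
  Newick export of the dendrogram.
* **Classification.** MB2ON: strong input from ≥ 1 MBON pair. LHN
  membership is an annotation input (its defining criterion depends on
  upstream reconstruction not contained in an adjacency matrix). CN
  (convergence neuron): reliable MBON *and* reliable LHN input. Weak
  (< 3 synapses) or asymmetric (≥ 3 on one side only) KC input is
  disregarded (`kc_input_reliable` records this). A strong output onto a
  dopaminergic pair sets the feedback-neuron (FBN) flag. Axo-axonic input
  exclusion would require synapse-polarity annotations and is applied only
  if an edge-level flag is supplied.
* **Valence prediction.** Using strong MBON inputs only, with ACh counted
  excitatory and GABA/Glu inhibitory: predicted positive when excitatory
  input from positive-valence MBON(s) combines with inhibitory input from
  negative-valence MBON(s), or when ≥ 2 negative-valence MBONs provide
  inhibitory input; predicted negative when ≥ 2 positive-valence MBONs
  provide inhibitory input. The qualifying combined input fraction must be
  ≥ 5% of the pair's total input. Unknown transmitters are excluded with a
  warning; if both rules fire (not observed in practice) the prediction is
  "none" with a warning.

## Calcium scoring (`larvanet.calcium`)

Ratiometric normalization is F_t = F_GCaMP/median(F_GCaMP) −
F_tdTom/median(F_tdTom). (A printed variant divides the second term by
median(F_GCaMP); that form is reachable with `literal=True` but is almost
certainly a typesetting error — the corrected form makes identical channels
cancel exactly.) ΔF/F₀ uses F₀ = mean over the 5 s before each
stimulation, separately per stimulation. Scores per epoch: ON = mean ΔF/F₀
over the first 3 s of stimulation; OFF = mean (and peak) over the 8 s after
it; amplitude = |max − min| ΔF/F₀ over the baseline-through-stimulation
span; abs_response = |mean during| − |mean baseline|. Repeated
stimulations are averaged per trial. QC is declarative: manifest rows
flagged `qc_pass = 0` are dropped, trace rows flagged `artifact` are
discarded, and multiple ROIs (hemispheres) of one trial are averaged before
scoring.

Paired comparisons use the Wilcoxon signed-rank test (two-sided; Pratt
handling of zero differences; exact null for n ≤ 25 without zeros, normal
approximation otherwise). The variance decomposition is a one-way ANOVA
with individual identity as the factor: F = MS_between/MS_within and
r² = SS_between/SS_total. Note r² estimates the inter-individual variance
*fraction of the ANOVA decomposition*: at k individuals × n trials its
expectation is (k−1)(nσ_b²+σ_w²) / [(k−1)(nσ_b²+σ_w²) + k(n−1)σ_w²],
approaching σ_b²/(σ_b²+σ_w²) only as n grows — tests compare against the
finite-sample form.

## Synthetic data (`larvanet.simulate`)

The generators emulate the statistical structure the analyses assume, not
the physics of the assays.

* **Stimulus.** Reflected (not clipped — clipping creates sticky
  boundaries and distorts increment variance) Gaussian random walk on
  [0, 255] at 112 Hz. The step SD (default 25 intensity units/update) is
  not printed in any protocol we re-implement; it was chosen so the walk
  decorrelates in ~0.2 s, fast relative to the ~0.5 s behavioral kernel —
  rapid flicker, as such experiments use. Blue channel constant.
* **LNP larvae.** All larvae share one stimulus. Per frame in a run, a turn
  starts with probability r_ROG(x_f)·Δt (error if this ever reaches 1),
  where x_f comes from the true kernel (default three-pole, τ = 0.5 s),
  standardized to unit variance. A turn is a sequence of ≤ 3 alternating
  0.5 s head sweeps; a sweep is accepted with probability
  sigmoid(slope·Δx_f) (logistic link in the change of x_f over the sweep —
  the qualitative property the analysis probes), forced on the last. On
  acceptance the heading changes 30–120° toward the accepted side and the
  run resumes; larvae are stationary while turning. Default nonlinearity:
  r̄ = 0.067 turns/s (4 turns/min, the scale larval assays report),
  μ = −0.5, σ² = 0.64. Spines are rendered as a straight posterior with the
  four anterior points progressively rotated by the bend angle — only the
  geometry the turn-angle metric consumes is meaningful.
* **Known limitation (refractory occupancy).** Because turns take ~1 s,
  larvae leave the run pool preferentially when x_f favors turning; the
  run-frame ensemble of x_f is then slightly displaced from N(0, 1) and
  the recovered (r̄, μ, σ) acquire a bias that grows with r̄ × turn
  duration (at 12 turns/min the μ bias reaches ~10%; at the default
  4 turns/min it is within one block-SE at 50 larvae × 600 s). The same
  effect exists in real recordings; passing round-trip tests therefore
  show estimator correctness at realistic turn rates, not immunity to
  refractory bias in general.
* **Gradient larvae.** Run-and-turn motion with per-frame turn rate
  base·(1 − modulation·cos θ), θ the heading relative to up-gradient
  (|modulation| ≤ 1; any monotone angular modulation would do — cosine is
  analytically convenient). Heading changes after a 1 s turn are uniform
  30–120° to a random side. Defaults: base rate 0.1 turns/s, speed
  0.8 mm/s, body length 4 mm. Post-turn heading distributions and run-speed
  statistics are conventions exposed as arguments, not measured values.
* **Connectome.** Homolog pairs per class (MBON/LHN/KC/PN/DAN/other); true
  pair-level connections are Bernoulli(p_connect) with per-side synapse
  counts drawn iid from a shifted geometric on {1, 2, …} (heavy-tailed;
  no published count distribution exists) and split 80/20
  ipsi/contralateral. Spurious contacts per (pre, post) neuron cell follow
  P(S = n) = (1 − p)pⁿ, so a fully spurious n-contact connection occurs at
  rate pⁿ exactly as the validation model assumes. Truth tables record
  per-side true counts and the strong flag they imply.
* **Calcium.** Individual amplitudes a_i ~ N(mean, σ_b²), trial amplitudes
  a_ij ~ N(a_i, σ_w²); the GCaMP trace is baseline·(1 + a_ij·g(t)) with a
  saturating-rise (τ = 0.2 s) / exponential-decay (τ = 1.5 s) transient per
  epoch, times multiplicative noise; tdTomato is constant up to noise
  (present only to exercise ratiometric normalization). Default epochs:
  four 3 s stimulations, ~15 s apart, at a 5 Hz volumetric frame rate.

What the generators do *not* emulate — peristalsis and contour dynamics,
plume physics beyond the heading-dependent rate law, neuron morphology,
class-structured wiring, photobleaching, motion artifacts — bounds what
passing tests demonstrate: correctness of the computations under the stated
statistical assumptions, not robustness to every pathology of real data.

## Numerical choices

* TTA bins are half-open with a 10⁻⁹ guard so samples on a bin edge bin
  deterministically; event times are quantized to the nearest stimulus
  sample (9 ms at 112 Hz, immaterial against 0.1 s bins).
* Kernel-fit initial values come from the TTA peak (τ₀ = t_peak/2,
  gain₀ = peak/(4e⁻²)); a flat TTA returns a zero-gain kernel flagged
  `degenerate` rather than an error.
* σ² of the turn-triggered ensemble uses the population (divide-by-N)
  estimator, matching its definition as a conditional expectation.
* Similarity matrices are symmetrized and their diagonal zeroed before
  linkage; all-null rows are dropped with a warning.
* ANOVA with zero total variance returns F = NaN (flagged) and r² = 0 by
  convention; zero within-variance with nonzero between returns F = inf,
  p = 0.
* Problem sizes in tests (e.g. 50 larvae × 600 s for the LNP round trip,
  200-neuron connectomes, 24 × 8 calcium designs) are chosen so Monte-Carlo
  error is small relative to the tolerances being asserted while the full
  suite stays fast.
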