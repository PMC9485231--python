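# Methods

`touchcode` implements the analysis chain used to characterise how touch is
represented across layers 2–4 of mouse barrel cortex during a two-whisker
pole task recorded with volumetric GCaMP calcium imaging. The package works
at the level of imaging-rate data: per-frame whisker curvature change (Δκ,
the force proxy; negative for protraction touches, positive for
retractions), touch-event tables, lick times, and per-neuron ΔF/F traces.
Everything upstream of that — whisker tracking, touch detection, motion
correction, segmentation — is outside the package's scope.

## The encoding model

The core object is a per-neuron generative model of touch-evoked ΔF/F:

    r_model(t) = d_session · [ (j_w2w1 · a_w1(t) + j_w1w2 · a_w2(t)) * g ](t)

with the per-whisker, per-frame drive

    a_w(t) = s_pro · log10(−Δκ_pro(t) + o_pro) + s_ret · log10(Δκ_ret(t) + o_ret)

where the protraction term applies on frames with Δκ < 0 and the retraction
term on frames with Δκ > 0. Log arguments are floored at 1, so each term is
non-negative and the offsets `o` act as soft thresholds on the minimal
force needed to elicit a response. The kernel `g` is the standard
indicator-impulse shape, a difference of exponentials
`exp(−t/τ_decay) − exp(−t/τ_rise)` normalised so its sampled peak is 1,
truncated at 5 τ_decay (tail < 1% of peak-normalised area). `d` is one
scaling per imaging session, constrained to [0, 1] with the maximum pinned
at 1 to absorb slow drift without trading off against the slopes. The
cross-whisker gains `j ∈ [0, 10]` scale the drive of the second-touching
whisker on multi-whisker trials whose first two touches are less than
200 ms apart (gain 1 elsewhere); values below 1 are suppression, above 1
enhancement. A Gaussian noise variance σ² completes the generative
description. σ² is estimated as the mean square of the negative ΔF/F
samples — the half-normal maximum-likelihood estimate, which equals the
noise variance when the trace is zero-centred and responses are
non-negative — and is never added to the point prediction: the prediction
is the model mean.

### Parameter constraints

| parameter | units | range | role |
|---|---|---|---|
| s_pro, s_ret | ΔF/F per decade of Δκ | ≥ 0 | response slope per direction |
| o_pro, o_ret | Δκ units | (0.05, 10] | soft force threshold |
| τ_rise | s | [0.1, 0.5] | indicator rise (physiological range) |
| τ_decay | s | [1, 5] | indicator decay |
| d | — | [0, 1], max = 1 | per-session scaling |
| j_w1w2, j_w2w1 | — | [0, 10] | cross-whisker interaction |

### Fitting

Fitting minimises mean squared error by block coordinate descent, per
whisker, on that whisker's single-whisker trials plus an equal-count random
sample of touchless trials. Blocks per cycle: (1) offsets by bounded scalar
search with the two slopes solved in closed form (non-negative 2×2 least
squares) at each offset evaluation; (2) τ_rise then τ_decay by bounded
scalar search; (3) per-session scalings in closed form, renormalised so
max d = 1 with the residual scale folded into the slopes. Cycles stop when
the relative SSE improvement falls below 1e−6 (cap 25 cycles). The
full-data fit uses 3 random restarts (seeded); cross-validation folds
warm-start from the full-data solution. Within-trial convolution is
implemented as a lower-triangular Toeplitz matmul, which is faster than FFT
convolution at trial lengths of ~70 frames.

The two per-whisker fits each estimate the shared kernel and session
scalings. They are combined by an explained-variance-weighted average
(floored at 0) rather than a plain mean: for a neuron driven by one whisker
only, the other whisker's fit carries no information about τ or d, and a
plain mean would bias d toward 1. After merging, one more slope/offset pass
per whisker runs with the merged kernel and scalings held fixed. The
interaction gains are fit last; because the prediction is linear in each
gain, they have closed-form least-squares solutions clipped to [0, 10].
With no qualifying multi-whisker trials the gains stay at 1 and a warning
flag is returned.

Cross-validation partitions whole trials into 5 folds, stratified by trial
type so every training set contains single-whisker and touchless trials.
Each frame's cross-validated prediction comes from the fold that held its
trial out. The encoding score per single-whisker touch type is the Pearson
correlation between that pooled cross-validated prediction and the data
over the concatenated frames of that type's trials (a trial's type is the
whisker × direction of its touches; the generator draws one direction per
whisker per trial so the assignment is unambiguous). Undefined correlations
(zero-variance trace or prediction) score 0 — such neurons carry no
evidence of touch coding.

### Classification

A touch type "passes" when its score exceeds both 0.1 and the 99th
percentile of shuffle-null scores for activity-matched neurons. The null is
built by refitting each neuron once on its trace circularly shifted by at
least 10 s (about one trial length) with Δκ left in place; neurons of a
subvolume are grouped into 10 equal-count bins by calcium event rate, and a
bin's null set pools its members' four per-type shuffled scores. Calcium
events are defined as upward crossings of 3× the half-normal noise scale
with at least 1 s separation; the trace-shift shuffle leaves the event rate
unchanged, so bin assignment is stable. Labels follow from the pass
pattern: exactly one passing type → unidirectional single-whisker (uSW);
both types of one whisker and none of the other → bidirectional (bSW); at
least one type per whisker → multi-whisker (MW), even if neither whisker is
bidirectional; none → non-touch.

## Response probability

A neuron responds on a touch trial when the post-touch mean (first touch to
two frames past the final touch) exceeds the 6-frame pre-touch baseline by
the neuron's half-normal σ AND exceeds the 99th percentile of 100
circular-shift shuffles of the same post-touch statistic. The responsive
pool admits neurons responding on ≥ 10% of trials of some touch type; a
variant admits neurons whose response probability beats the 99th percentile
of shuffled response probabilities. Both rules are implemented and the
conjunction is the default, each selectable, because the fraction rule and
the shuffled-percentile rule answer slightly different questions and the
analyses that consume the pool reference both. Null draws are keyed by
(seed, neuron, trial) so response outcomes are invariant to trial storage
order. Touch-evoked calcium events are events whose onset falls inside a
trial's touch window; the top-percentile concentration statistic ranks
neurons by that count (ties broken by neuron id) and reports the share of
events carried by the top 1% (at least one neuron, flagged below 100
neurons).

A caveat the synthetic experiments make visible: for trials with a single
brief touch the post-touch window spans only ~3–4 frames, most of the
indicator rise falls outside it, and the shuffle null (which revisits the
neuron's own response epochs) is strict — so per-trial response
probabilities are conservative for sparse, brief-touch trials. This is a
property of the windowing rule, not of the implementation.

## Decoding

The per-trial response is the mean ΔF/F from the first touch to the first
lick, capped at 2 s after the first touch (the cap also applies when no
lick occurred). Force decoding contrasts the strong vs weak Δκ tertiles
within one single-whisker touch type; identity decoding contrasts
whisker-1-only vs whisker-2-only trials; both require ≥ 10 trials per
class. The AUC uses the rank-sum identity with midranks — identical to the
threshold-sweep construction, with exact tie handling — oriented so
strong/whisker-1 is the positive class; an unsigned variant folds to
max(AUC, 1 − AUC).

## Correlations and ensembles

Pairwise Pearson correlations are computed over all frames or restricted
to non-touch epochs (excluding 1 s before to 10 s after every touch,
windows unioned). Zero-variance traces yield undefined correlations that
are excluded, not zeroed. Class-level summaries average uSW subtypes
(whisker × direction) and bSW whiskers separately before combining; MW
neurons are pooled. Per-layer analyses use the subvolume with the most
neurons of that layer, keeping all pairs simultaneously recorded.

Ensemble detection: the threshold is twice the 99.5th percentile of all
pairwise correlations, capped at 0.99 (on strongly correlated populations
twice the percentile can exceed 1, which would forbid all ensembles).
Average-linkage hierarchical clustering on distance 1 − r supplies seeds:
every dendrogram cluster of 3–5 members whose mean mutual correlation
clears the threshold, discarding seeds strictly contained in a larger
passing seed. Each seed grows greedily — at each step the candidate with
the highest mean correlation to the members joins if the grown ensemble's
mean within-correlation stays at or above the threshold, ties broken by
lower index. Ensembles overlapping by ≥ 75% (intersection over union)
merge when the union still clears the threshold, iterated to a fixed
point; ensembles under 3 members are discarded. An ensemble is a "touch
ensemble" when ≥ 50% of members are touch-classified (inclusive).

A structural property worth knowing: the growth rule only returns compact
ensembles when within-ensemble correlation sits modestly above the
threshold (up to roughly 1.3–1.5×). If the coupling is much stronger, the
mean within-correlation stays above the threshold while weakly correlated
neurons are absorbed, and the ensemble balloons until dilution; if more
than ~0.5% of all pairs lie inside ensembles, the 99.5th percentile itself
rises toward the within-ensemble correlation and detection dies at the
cap. The synthetic generator's default coupling is placed in the workable
band (see below).

## Population operations

Normalised depth maps the L1–L2, L2–L3 and L3–L4 borders to 0, 1 and 2
(the L2–L3 border is defined as the midpoint of the other two), with L4
depths extending past 2 by the same per-layer scaling. Layer comparisons
exclude neurons within a 50 μm slice centred on the L2–L3 and L3–L4
borders. L4 noise matching linearly scales each superficial trace by the
ratio of the L4 animal-level mean top-1% ΔF/F to the cell's own top-1%
mean (per-cell scaling with an animal-level L4 reference; a single
animal-level α is available as an option) and then adds Gaussian noise at
the scale fitted to pooled negative L4 samples, so classification can be
re-run at L4-like signal-to-noise. The 7/2 field-of-view extrapolation
multiplies per-layer touch-class frequencies by 3.5, reflecting an imaged
field spanning ~7 barrels with only 2 spared whiskers.

## Synthetic data

The generator emulates the task conditions: 10 s trials at 7 Hz, half
touchless, touch trials split evenly among whisker-1-only, whisker-2-only
and multi-whisker, 1–4 touches per trial of 1–2 frames each, one touch
direction per whisker per trial, multi-whisker inter-touch intervals
uniform over 0–400 ms (so the 200 ms interaction gate sees both sides),
and a first lick 0.5–2.5 s after the first touch (so the 2 s decoding cap
binds on both sides). Per-touch |Δκ| is log-uniform over (0.5, 50) in the
working curvature unit, chosen jointly with offsets o ~ U(0.5, 2) so the
log10 drive spans ~0–2 decades and the offsets genuinely threshold weak
touches; the published Δκ distribution is graphical only, so this is a
stand-in for its shape, not a claim about the data. Neurons are drawn from
the four classes at configurable per-layer counts (defaults follow the
study's per-layer frequency estimates), with slopes U(0.8, 2.5),
τ_rise U(0.1, 0.45) s, τ_decay U(1.2, 3.5) s, per-session d U(0.5, 1)
max-rescaled, and layer-dependent noise SD 0.10/0.13/0.18 for L2/L3/L4
(noise grows with imaging depth). Traces are the model's forward
prediction plus Gaussian noise — the generator and the fitted model share
one forward code path.

Planted ensembles add a shared latent event drive to their members:
Poisson events at 0.20 Hz, per-event amplitude 0.064 (jittered ±20% per
member) convolved with each member's own kernel, present during touch and
non-touch epochs alike. The coupling was calibrated once so that the
within-ensemble correlation lands at roughly 1.1–1.4× the detection
threshold — above twice the background 99.5th percentile, inside the band
where the greedy detector recovers compact memberships (see the structural
property above). Planted membership recovery at this coupling is
seed-dependent at the margin: over held-out generator seeds the
per-ensemble minimum Jaccard clears 0.8 in roughly nine cases in ten, with
the residual spread driven by the merge step unioning chance extras.

What the generator does not emulate: correlated noise between neighbouring
neurons (neuropil contamination), slow baseline drift within a session,
whisker-motion-locked activity outside touches, behavioural state changes,
and non-stationary touch kinematics. Passing tests therefore demonstrate
that the pipeline recovers structure the model family can express under
realistic noise — not that real cortical data satisfies the model.

## Validation experiments and problem sizes

`touchcode.experiments` packages four simulation studies used by the test
suite and by `scripts/acceptance.py`:

- **Parameter/class recovery** — 50 neurons per class (non-touch/uSW/bSW/MW)
  at 120 trials: median relative errors of the identifiable parameters
  (slopes and offsets of truly responsive terms, kernel time constants and
  session scalings of touch neurons) and the fraction of shuffle-calibrated
  labels matching the generating class. The test suite runs 8 per class.
- **AUC oracle** — 200 random tied-integer instances of up to 50 trials per
  group, compared against an all-pairs brute-force count.
- **Null calibration** — 100 pure-noise neurons: per-type classification
  false-positive rate and per-trial/pool response false-positive rates
  (40 neurons in the test suite).
- **Ensemble recovery** — planted ensembles of sizes 5/8/12 on a 300-neuron
  uncorrelated background over 150 touchless trials, plus a matched null
  without ensembles.

These sizes keep a full reproduction run in the single-digit minutes on
one core while leaving the recovery statistics well-resolved.

## Known limitations

- Offsets of touch types a neuron does not respond to are unidentifiable
  (the slope is 0); recovery statistics cover the active terms only.
- τ_rise spans 1–3 frames at 7 Hz; its recovery leans on high trial counts
  and clean kernel shape, and degrades faster with noise than τ_decay's.
- The Methods-style ≥10% pool rule and the shuffled-probability pool rule
  genuinely differ; the package keeps both rather than resolving them.
- The per-trial response criterion is conservative for brief single
  touches (see above).
- Ensemble detection inherits the threshold rule's narrow workable
  coupling band; on data with pervasive strong correlations the threshold
  cap (0.99, flagged) governs.
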