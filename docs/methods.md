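# Methods

This note documents the models, conventions and design choices behind
`crutchload`, in the order the pipeline applies them.

## Units and prescription arithmetic

All loads are kilogram-force (the clinical reporting unit; the constant
`NEWTONS_PER_KGF = 9.80665` is exposed for conversion but Newtons never
appear in any record), times are milliseconds, rates hertz.  The
accuracy tolerance is parameterised as the *half-width* of the correct
window as a fraction of the ideal load (default 0.05, i.e. a 95–105 %
window, sometimes loosely described as a "±10 %" full window width);
the balance tolerance is a fraction of the ideal *total* load (0.05 of
a 50 kgf ideal total gives the 2.5 kgf limit).  Both interpretations
are fixed by the worked 100 kg example they must reproduce
(47.5–52.5 / 23.75–26.25 / 2.5 kgf).  Window bounds are inclusive:
95.00 % and 105.00 % classify as correct, and the bounds in percent
space are computed as `100 ± 100·a` so that the default window edges
are exactly representable in floating point.  Classification always
operates on unrounded percents; two-decimal rounding is applied only
for reporting (and when classifying an already-rounded dataset, the
printed values are classified as given).

Sampling rates are accepted anywhere in [10, 80] Hz with presets 20,
40, 80; the acquisition hardware's documented presets are the three,
but nothing in the processing depends on the preset list.

## Sensor calibration

The millivolt→kgf map is linear, `(raw − offset) × gain`, clamped below
at zero (noise around the zero-load offset must not produce negative
force) and flagged above the saturation bound `max_mv`.  A
two-parameter affine model per sensor is the minimum that makes the
conversion well-defined and is standard for strain-gauge force sensors;
the calibration file carries `{sensor_id, gain_kgf_per_mv, offset_mv,
max_mv}`.

## Support detection

A support opens when the force rises to the onset threshold and closes
when it falls below half that threshold.  The hysteresis (release at
50 % of onset) prevents chatter when the signal hovers near the
threshold.  Defaults:

* `onset_threshold = max(1 kgf, 2 % of the ideal total)` — scale-aware,
  so a heavier prescription does not detect fingertip pressure as a
  support, with a 1 kgf floor above sensor noise;
* `min_support_duration = 200 ms` — genuine crutch stances last on the
  order of a second; 200 ms rejects spikes without excluding fast gait;
* ties in the peak resolve to the earliest sample, making peak times
  deterministic.

The support's offset is taken at the release-threshold crossing; peak
load is the maximum sample in the interval (no interpolation — see the
discretization bound below for what this costs).

Fluency uses `scipy.signal.find_peaks` with prominence threshold
`0.10 × support maximum`: a second local maximum counts only if the
trough separating it drops at least 10 % of the peak below the smaller
neighbouring maximum.  Smooth single-hump supports count 1.

Left/right supports pair into strides greedily by onset proximity,
each support joining at most one stride, with a pairing horizon of one
cadence period (estimated as the median inter-onset interval; unbounded
when a side has fewer than two supports).  Greedy 1:1 nearest-onset
matching is the simplest deterministic rule consistent with alternating
bilateral gait; unpaired supports become single-sided strides, which
downstream count as simultaneity violations and imbalances but still
contribute their load to the step counter.

## Feedback semantics

Bar colour rules reconcile continuous concurrent feedback with terminal
correctness judgments:

* **overload** is visible while it happens — the bar turns red the
  instant the displayed value crosses the upper guide line and stays
  red until the support ends;
* **underload** can only be confirmed once the support is over (the
  rising/falling signal is always briefly below the window), so
  under-window values are green during loading and a confirmed
  underloaded support is revealed by a 300 ms red flash immediately
  after it;
* **balance** mode is red exactly while the left/right difference
  exceeds the limit during simultaneous loading, with the bar position
  the signed difference scaled by the limit and clamped to [−1, 1].
  Balance mode is refused in unilateral gait.

Each wrong stride emits one 300 ms terminal beep at the later support
offset: high-pitched for crutch *underload*, because underloading the
crutches means overloading the healing limb — the clinically risky
direction gets the most annoying sound — and standard for crutch
overload.  In balance mode, one beep per maximal violation episode
(rather than per violating sample) avoids beep storms; beeps for
imbalance are emitted only in balance mode.  The 300 ms duration is
shorter than the inter-stride gap at any realistic cadence, so beeps
never overlap.

## Synthetic walks

Each simulated support is a raised cosine
`P · ½(1 − cos(2π(t−onset)/D))` over duration `D` — smooth,
single-peaked, analytically tractable.  Per stride, the total peak is
drawn from `Normal(target_pct_mean, target_pct_sd)` (in percent of the
ideal total, truncated at 0), split by a drawn left share, and the two
onsets offset by a drawn asynchrony.  Defaults are the pilot's walk
structure: 10 strides, 1.5 s cadence, 1.1 s supports, 80 Hz, an evenly
split compliant walker (target 100 %, SD 3 %), ±20 ms asynchrony SD and
0.2 kgf sensor noise.

Loading hesitation ("fluctuation") is injected as a multiplicative
raised-cosine notch centred at mid-support, 40 % of the support wide,
with depth `d`; the hump is rescaled afterwards so the programmed peak
is still attained.  A mid-support notch is used because a notch on the
steeply descending limb of the raised cosine would merely steepen the
descent without creating a second local maximum; the mid-support dip
produces two prominent peaks whose trough depth scales with `d`, so
`d = 0.5` is detected as non-fluent at the default 10 % prominence and
`d = 0.05` is not.

Peak recovery error is bounded by the discretization bound
`½(1 − cos(π·Δt/D))` (the programmed peak falls mid-support and the
nearest sample can miss it by at most that fraction) plus a noise term;
at 80 Hz with 1.1 s supports the discretization bound is ≈ 1.6 × 10⁻⁴.
What the simulator does **not** emulate: muscle dynamics, foot
ground-reaction forces, within-support asymmetry of loading and
unloading, learning effects across walks, or correlated sensor noise.
Passing round-trip tests therefore demonstrates the pipeline's
correctness on well-formed signals, not clinical performance on
hardware data.

## The bundled pilot dataset

`crutchload.signal_io.load_pilot_fixture()` returns the pilot study's
400 recorded supports (10 healthy experienced subjects × 4 walks × 10
supports; walk 0 without feedback, walks 1–3 with double-bar feedback),
each a peak load in percent of the ideal total with its
correct/overload/underload annotation.  The file is checksummed at
load.  Three internal inconsistencies of the original write-up are
handled explicitly, with the per-support annotations always governing:

* the narrative's walk-2 error total (28) disagrees with the
  annotations (29);
* subject 9's feedback-walk error progression is stated as 8, 5, 5 but
  the annotations give 8, 6, 5;
* the subject-8 walk-0 summary cell (mean 62.14, range 61.09–72.87)
  contradicts its own support values, which give mean 69.40 and range
  61.09–80.62 (the walk includes 80.62).

`pilot_report` recomputes everything from the supports and attaches
discrepancy notes rather than silently resolving them.

## Wilcoxon matched-pairs signed-rank test

Zero differences are dropped (Wilcoxon's original rule — required, for
example, to make the baseline-vs-walk-1 overload comparison an n = 8
problem when two subjects have zero change), absolute differences are
midranked, and for `n ≤ 20` the two-sided p is
`min(1, 2·P(W⁺ ≤ min(w⁺, w⁻)))` with the null distribution of W⁺ built
by exact subset-sum convolution over the observed (possibly tied)
ranks — equivalent to enumerating all 2ⁿ sign assignments, and exact in
the presence of ties where classical tables are not.  Larger samples
fall back to the normal approximation with the standard tie-corrected
variance.  The distribution of W⁺ is symmetric under sign flips even
with midranks, so doubling the lower tail of the smaller rank sum is
the usual two-sided convention.

Which paired metric underlies a published walk-comparison p-value is
often ambiguous; `compare_walks` therefore exposes the metric choice
(overload / underload / total error counts, or mean percent).  On the
bundled dataset the per-subject *overload-error counts* reproduce the
expected significance pattern: baseline vs each feedback walk
significant at 0.05 (exact p = 0.0156, 0.0254, 0.0156), underload
comparisons not significant.

## Problem sizes

The test suite and the acceptance script run entirely on the bundled
400-support dataset, closed-form checks, and simulated walks of 10–200
strides at 80 Hz (about 1.4 × 10³ samples per side per walk; 100 seeds
for the round-trip properties) — sizes at which every check completes
in seconds on one CPU while still exercising each pipeline stage.
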