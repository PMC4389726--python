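# Methods

This note documents the models, conventions and numerical choices behind
`rivulet`: what each component assumes, which knobs matter, what the
synthetic fixtures do and do not emulate, and where the design was
genuinely open.

## The stream model

An observable sequence is a push-based stream obeying the grammar
`NEXT* (COMPLETED | ERROR)?` per subscription: any number of values, then at
most one terminal. Operators are functions from streams to streams; they
may not reorder a single stream or emit after a terminal. There is no
backpressure — producers push and consumers keep up — which matches the
event-driven acquisition setting the engine targets (a camera does not wait
for your code).

All timing is **virtual**: integer ticks on a scheduler that executes queued
actions in `(time, sequence-number)` order, sequence numbers being
assignment order. Two consequences matter:

1. **Determinism.** Any pipeline on scripted inputs yields a byte-identical
   log on every run. Wall-clock execution would be a drop-in replacement of
   the scheduler, deliberately excluded from the test surface.
2. **A total order for simultaneous events.** Real systems leave the order
   of same-instant events on different devices undefined. Here, events at
   one tick execute in the order their sources scheduled them — for scripted
   hot sources, creation order. Every tie in the operator suite (merge
   ordering, sample-vs-completion races, a video frame sharing a tick with a
   split trigger) resolves by this one rule. This is a *choice*, not a fact
   about asynchronous hardware; the oracle in `rivulet.oracle` encodes the
   same rule, so the equivalence tests pin it down exactly.

Cold sources replay their script relative to each subscription; hot sources
(subjects) broadcast to current subscribers, and a late subscriber to a
terminated subject receives the terminal immediately (this is what lets
`merge` over already-finished streams complete correctly).

### Operator conventions worth stating

- `sample(src, trigger)` re-emits an unchanged latest value on every
  trigger. Some reactive libraries emit only distinct-since-last-trigger;
  here every trigger acts, because the motivating use (save a snapshot per
  key press) wants exactly that. The output completes when the *data*
  stream completes; trigger completion merely stops sampling.
- `take(n)` emits COMPLETED at the nth element's own tick (not one tick
  later). This same-tick completion is what makes state-machine exit and
  next-state entry share a tick.
- `repeat` restarts a blueprint on completion at the completion tick, and
  refuses to spin: a blueprint completing at its own subscription tick twice
  consecutively raises a zero-time-loop error instead of freezing the
  scheduler at one tick.
- Externalized properties are a stream plus a binding object. The whole
  visibility contract is: an update at tick t is read by every element the
  target processes after it; same-tick conflicts resolve to the last writer
  in scheduling order. Operators read bound parameters per element, so no
  operator-specific plumbing is needed.

## Windows

Three slicing modes produce streams-of-streams; each window is itself a hot
stream relaying source elements at their original ticks (no buffering
delay).

- **Count** windows open at source elements 0, skip, 2·skip, … and close
  after `count` elements or at source completion. Trailing partial windows
  *are* emitted: conservation (`select_many(identity)` rebuilds the source
  exactly when count = skip) is treated as the primary property, and
  dropping partials is left to compositions that want it (the moving
  average does). When skip < count windows overlap; each interior element
  then appears in count/skip windows on average (exactly count/skip when
  skip divides count; otherwise the multiplicity alternates between the
  floor and ceiling of that ratio — no single integer is correct).
- **Time** windows are half-open intervals `[k·d, (k+1)·d)` from the
  subscription tick; a boundary element belongs to the later window.
  Element-free intervals still yield empty windows so interval index equals
  elapsed time; they materialize when the stream next advances. A source
  completing exactly on a boundary does not open the zero-length next
  interval.
- **Trigger** windows: the first opens at subscription, each boundary event
  closes one and opens the next, and source completion closes the last. A
  boundary sharing a tick with a source element or terminal loses the tie
  (source streams are created first).

`select_many` instantiates a fresh inner dataflow per window — separate
parameter stores, separate operator state — and merges the outputs by time,
ties to the lower window id. The moving average is purely a composition:
`window_count(k, 1)` → per-window mean at completion, partials dropped, so
the output is time-shifted by the k−1 future samples each mean waits for.

## Dataflow graphs

Workflows are DAGs of typed nodes (source / transform / condition / sink /
property / combinator / nested) with positional edges: the k-th inbound
edge feeds input slot k, which is how `sample` distinguishes data from
trigger. Validation reports diagnostics (cycles via `networkx`, arity by
category, slot contiguity, group placeholder structure, unknown operators)
rather than raising; the builder instantiates nodes in deterministic
topological order and attaches recorders to terminal and `tap: true` nodes.
Nested groups compile with `group_input` placeholders bound to the node's
inputs and a single `group_output`; the same group description under
`select_many` is instantiated once per window. The YAML format and its
JSON-Schema (docs/workflow.schema.json) are an original design for this
engine.

## Vision operators

Frames are 8-bit grayscale arrays, origin top-left, x = column,
y = row (downward). The tracking chain is threshold → largest 8-connected
component (ties by earliest first pixel in raster scan; `scipy.ndimage`
labels, a flood-fill oracle checks) → image moments:

- centroid `(M10/M00, M01/M00)`;
- orientation `0.5·atan2(2µ11′, µ20′−µ02′)` in degrees, range (−90°, 90°],
  measured from +x toward +y (downward) — stated explicitly because image
  coordinates flip the usual sign convention;
- major axis `4·sqrt(λ1)` with λ1 the larger eigenvalue of the normalized
  second-moment matrix (the ellipse-model axis; for a 1×9 bar of pixels
  this gives 4·sqrt(80/12) ≈ 10.33).

Color segmentation is reduced to an intensity-range threshold (with an
invert flag for dark-object tracking): the segmentation logic, not the
color space, is the load-bearing part. The ROI monitor uses half-open
rectangles (`x0 ≤ cx < x1`), starts in the "outside" state, and emits
strictly alternating ENTER/EXIT events carrying the digital-output level.

The raw frame container is a single JSON header line (rows, cols, dtype,
fixed-width count patched on close) followed by concatenated row-major
bytes — a deliberately codec-free, bit-exact format so that triggered video
splitting can be verified by byte equality.

## Electrophysiology operators

Signals travel as channels×samples buffers with absolute start indices.
Every operator carries its state across buffer boundaries, making results
independent of chunking ("buffer-split invariance", asserted to 1e-9 for
the filter and exactly for the detector).

- **Band-pass**: a first-order Butterworth band-pass biquad (bilinear
  transform, `scipy.signal.butter`/`sosfilt` with persistent per-channel
  state). Causal only — zero-phase filtering needs future samples and is
  rejected as unrealizable online. Unity gain sits at the geometric mean of
  the corners; DC is fully rejected.
- **Spike detection**: a crossing of the (signed) threshold opens a search
  span of `refractory` samples; the event lands on the extremum in that
  span (trough alignment for negative thresholds), and crossings inside the
  span are suppressed. Trough alignment rather than crossing alignment
  keeps spike-triggered averages sharp. A span cut short by end-of-stream
  is flushed with the samples seen. Events therefore trail the signal by up
  to `refractory` samples — the price of alignment in a causal system.
  The default fixture threshold is 5× the noise standard deviation, the
  standard multiple-of-noise rule; with 8-sigma troughs this leaves wide
  margins on both false positives and misses.
- **Triggered extraction** keeps `pre + post` samples of history and emits
  an all-channel slice `[i−pre, i+post]` per event once the lookahead has
  arrived; events too close to the stream edge (or arriving after their
  context was trimmed) are dropped and counted. When events come from the
  in-pipeline detector, configure `post ≥ refractory` so detection latency
  never outruns retention.
- **Raw int16**: little-endian, sample-major interleaved (c0s0, c1s0, …),
  values clipped to the int16 range on write — the common flat layout for
  extracellular recordings.

## Task control

A state is a nested stream: entry side effects fire at activation, and
`take(1)` of an exit-trigger blueprint produces the single event that
advances the chain; `repeat` loops trials. The equivalence of this
formulation with an explicit state-machine interpreter is tested on
scripted inputs, transition by transition.

The reaction-time task (Ready arms a delay timer; Go listens for the first
key) ignores keys during Ready — the Go state simply is not subscribed yet,
so the semantics fall out of subscription timing rather than a filter. A
key sharing the stimulus tick is likewise ignored (it was scheduled before
Go subscribed); reaction times are strictly positive.

The foraging site is a coincidence detector: an availability event arms the
site for `w` ticks (inclusive at both ends); the first sample while armed
collects the reward at the sample tick and disarms; a new availability
while armed *replaces* the pending one (a single-item site — the old item
is gone), with no queueing. `w` has no default: "closely follows" is
task-specific. Multi-site foraging is literal replication — per-site
dataflows merged with site tags, sharing nothing — so per-site reward lists
are provably identical to single-site runs, while a flat product-state
machine would need `states^sites` states (`fsm_explosion_count` reports the
comparison, counting 4 dataflow nodes per site: availability, sampling,
coincidence, reward).

Under Poisson availability (rate λ_A) and sampling (rate λ_S) schedules the
arming rule gives, per availability with gap g to the next one, a reward
probability `1 − exp(−λ_S · min(w+1, g))` (w+1 because both endpoints of
the window are armed ticks; independence across availabilities holds
because armed tick-sets are disjoint). The acceptance suite checks the
realized reward count against this closed form within 3 standard errors —
and, separately, checks the event list itself against a brute-force sweep
oracle, so the statistical check never stands alone.

## Synthetic fixtures

Generators are pure functions of their config (seed included); same config,
same bytes.

- **Video**: a bright disc (radius 6 px, Lissajous path) or a centered
  oscillating bar (length 40, width 7, ±55°) rendered with a one-pixel soft
  edge over Gaussian pixel noise (σ = 5 by default, σ = 10 in the recovery
  checks) on a 120×90 field. Ground truth is the continuous center/angle
  per frame. Not emulated: occlusion, background clutter, illumination
  drift, shape change — so passing recovery tests demonstrates the
  correctness of the operator chain, not robustness to real-world imaging.
- **Spikes**: multichannel unit-variance Gaussian noise plus a biphasic
  template (sharp ~0.1 ms trough, slower positive overshoot, ~1.5 ms total
  at 30 kHz), renormalized so the trough depth is exactly SNR·σ, injected at
  scripted times or uniformly with a minimum gap (drawn exactly via the
  gap-compressed-interval construction — no rejection loop). Attenuated
  copies (gain 0.3) appear on non-target channels. Real recordings add
  drift, correlated noise and overlapping units; none are modeled.
- **Event schedules**: homogeneous Poisson on the tick grid (exponential
  gaps, floored, deduplicated — equivalently, a tick carries an event with
  probability 1 − e^(−λ)) or explicit lists.

Default study sizes: 300-frame tracking runs, 100 injected spikes in 3 s of
4-channel 30 kHz signal, 2×10⁶-tick foraging runs (~10⁴ availabilities at
λ_A = 1/200, λ_S = 1/50, w = 60), 100 scripted reaction-time trials, and
500 random scripts per operator for the oracle suite. The full test suite
runs in a few seconds; `scripts/acceptance.py` in under ten.

## Known limitations

- Virtual time is integer-tick and single-threaded; the engine demonstrates
  semantics, not real-time throughput, and no hardware I/O exists.
- The cross-stream simultaneity order is a documented convention, not a
  property of asynchronous devices.
- `sample` repeating unchanged values, emission of partial count-windows,
  and trough (vs crossing) spike alignment are all deliberate choices where
  reasonable alternatives exist; each is pinned by tests so changing one is
  an API change, not a refactor.
- The workflow builder covers the operator registry shipped here; arbitrary
  user code enters through registered named functions, not inline script
  evaluation.
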