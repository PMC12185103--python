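# Methods

## Frames and geometry

Positions are tracked at 30 Hz in room-frame coordinates (cm, origin at the
arena centre, 41 cm radius) together with the accumulated rotation angle
θ(t) = 6·rpm·t degrees. The arena-frame position is the rigid rotation of
the room-frame point by −θ; angles are degrees, counterclockwise positive,
and θ is never wrapped so revolution counts stay recoverable. The rotation
direction is not constrained anywhere: the rate is signed and both signs are
exercised in tests.

Sector membership is half-open on the leading edge, `[center − w/2,
center + w/2)` after reduction modulo 360, which makes membership exactly
complementary between a sector and its complement and deterministic under
ties. A point at the origin has no polar angle and is an error rather than a
default — silent defaults corrupt sector statistics. The near/far partition
scans candidate 20° seed sectors on a 1° grid, takes the minimum-occupancy
centre (ties to the smallest angle), then grows the sector by 1° on each
edge until it holds at least half the recording time; the far half is the
complement. A width-0 sector is legal and denotes "empty" (the coverage = 1
limit).

## Behavioral endpoints

Distance is the sum of room-frame steps, ignoring steps under 0.32 cm (the
tracker's stated resolution) so jitter does not accumulate. An entrance is
an outside→inside transition preceded by ≥ 1.5 s continuously outside;
the refractory interval debounces boundary chatter and is exposed in the
config, as the acquisition hardware's own debounce is not documented. The
pre-session state counts as "outside", so a trial starting inside the zone
registers an entrance at t = 0. Trials that never enter report the session
length with a censored flag (keeps group averages finite, mirroring how
latency maxima saturate in the task software). All endpoints accept a time
window, which is how the first-5-minute counts feeding the savings index
are produced; the savings index itself requires a nonzero count on the
first conflict trial and errors otherwise.

## Single units

The burst ratio divides the count of inter-spike intervals ≤ 30 ms by the
count in the closed interval [100, 130] ms; each interval is attributed
once, which is symmetric and order-free where "number of spikes with ISI"
would be ambiguous. A zero denominator yields NaN (excluded from group
means) rather than infinity. Classification uses only the waveform-duration
and rate gates; burstiness is recorded but not gated on, since no numeric
burst threshold is established. Mean rates default to the whole recording,
configurable to a window. Only hippocampal units classified pyramidal, with
at least 50 session spikes (configurable), enter the overdispersion and
frame-preference analyses.

## Overdispersion

Rate maps are ratio-of-smoothed-histograms on 2.5 cm bins with a Gaussian
kernel of σ = 1 bin; bins with under 0.5 s raw occupancy are masked and
queries there return NaN, never zero. These constants are conventional and
configurable. The expectation frame defaults to whichever frame gives the
cell the higher Skaggs information ("auto"), and is reported with the
output; it can be forced to room or arena. Episodes are consecutive,
non-overlapping 5 s blocks. `exp` accumulates rate(bin at sample)·Δt along
the trajectory; `z = (obs − exp)/√exp`. Retention requires `exp > 0` and
`exp` greater than the cell's mean count per episode — the "greater than
the cell's mean firing" rule read in count units, the only dimensionally
consistent reading; a rate-unit variant is equivalent after dividing both
sides by the episode length. Episodes touching a masked bin are dropped and
logged, not imputed. The analysis map is the plug-in estimate from the same
session; the calibration suite instead scores against the *generative*
tuning (the simulator's Gaussian), which makes episode counts exact Poisson
sums and pins var(z) = 1 — separating the statistic's calibration from
plug-in map error. Variances are compared as `F = var_a/var_b` with
(n−1, n−1) degrees of freedom and a two-sided p.

## Momentary positional information and SFEP

Sessions are cut into ⌊duration/0.133 s⌋ windows; the activity level i is
the spike count in the window, and the window's location is the tracker
sample nearest the window centre (deterministic; no cross-boundary
averaging), binned on a 16×16 grid over the arena square separately per
frame. Counts above the session's 99th percentile pool into a top level,
stabilising the tails of p(i|x). Spatial bins with fewer than 10 windows
are invalid for that frame: their windows are excluded from that frame's
I series and hence from ΔI. Conditionals, joint and marginal are all
estimated from the same (valid-bin) window population, so the conditional
rows sum to one and the marginal is their occupancy mixture.

`I_pos = |p(i|x)·log₂(p(i|x)/p(i))|` per the absolute-value convention;
`ΔI = I_room − I_arena`; the ensemble series is the per-window mean over
cells (windows with no valid cell excluded). SFEP is the fraction of
non-tied windows with positive ensemble ΔI. Exact ties are measure-zero in
real data but common in degenerate tests; they are excluded from both the
proportion and the runs test, and an all-tied series is an error.

The runs test is the classical Wald–Wolfowitz normal approximation on the
series dichotomized at its mean, ties dropped, no continuity correction.
On the ensemble ΔI series the run count is far *below* chance (alternation
every few seconds versus 133 ms windows), so the attached `runs_z` is
reported sign-flipped: positive means slower-than-chance alternation. The
preference map is the per-room-bin fraction of room-preferring windows
(≥ 10 windows per bin, else masked), and the near/far summary is the
window-count-weighted mean of the map over each partition sector.

## CO covariance network

Optical densities are normalized by the slope of a per-batch linear fit of
standard OD against section thickness (activity per µm); the normalization
is pluggable since Pearson correlations are invariant to any common
rescaling. Replicate readings and hemispheres are averaged per
subject × region; missing cells drop the subject pairwise. Every unordered
pair of the 14 canonical regions (91 pairs) gets a Pearson r and two-sided
p (≥ 4 subjects required); Benjamini–Hochberg at q = 0.01 within each
group's 91 tests marks the FDR tier, and p < 0.05 marks the loose tier —
both are reported, and the graph carries the FDR flag on its p < 0.05
edges (a nested subset by construction). Group differences per edge use
Fisher's z with SE = √(1/(n₁−3) + 1/(n₂−3)). The two-proportion comparison
uses the pooled z statistic; this is the documented formula and no attempt
is made to reproduce externally quoted variants.

## Synthetic sessions

The generator is an explicit statistical stand-in, not a biophysical
model; its manifest records every generative parameter.

* **Trajectory** — exact Ornstein–Uhlenbeck velocity updates per 1/30 s
  step (relaxation τ = 1 s, per-component stationary scale 8 cm/s, mean
  speed ≈ 10 cm/s, typical foraging), with specular reflection of position
  and velocity at the wall. Avoidance adds a tangential acceleration away
  from the zone's centre line with Gaussian angular falloff; gain 4 deflates
  zone occupancy several-fold while leaving the near half well sampled, as
  in retention sessions where animals skirt the zone without entering it.
* **State** — `none`: permanently room. `dwell`: strict alternation with
  exponential dwells whose frame-specific means are 2·mean_dwell·p_room and
  2·mean_dwell·(1−p_room), so the long-run room fraction is exactly p_room
  and the overall mean dwell equals mean_dwell at p_room = 0.5.
  `proximity`: exponential renewals; at each renewal the frame is drawn
  with probability p_room_near or p_room_far according to the current
  position's half of the room frame.
* **Spiking** — Gaussian tuning in the cell's own frame (σ = 9 cm, peak
  20–30 spikes/s, baseline 3 spikes/s), suppressed to baseline when the
  latent state disagrees with the cell's frame, multiplied by the per-pass
  gain (piecewise constant on 5 s blocks), then Poisson counts per sample
  bin with uniform within-bin jitter — an exact inhomogeneous-Poisson
  oracle at bin resolution. Field centres follow a sunflower layout so
  small ensembles tile the disk. One master seed spawns independent
  substreams for trajectory, state, gain and cells, so components are
  individually reproducible and a fixed seed is bit-identical.

The 3 spikes/s baseline deserves a note: with near-silent baselines, a
suppressed cell's *silence* at its field location is itself informative
about that frame (the absolute-value I_pos is large for surprising i = 0),
so majority-frame cells carry a persistent preference and SFEP distorts
sigmoidally away from the generative room fraction. Realistic out-of-field
discharge keeps the per-window classification approximately linear in the
latent fraction, which is what the recovery suite measures.

## What passing tests do and do not show

The calibration and recovery suites demonstrate that the implemented
statistics are unbiased and correctly standardized *under their own
modeling assumptions* (Poisson spiking, piecewise-constant states and
gains, Gaussian tuning, ideal tracking). Real recordings add theta
rhythmicity, rate remapping, behavioral state changes, sorting
contamination and tracking noise, none of which the generator emulates;
passing here validates the analysis code, not the biological
interpretation of any particular dataset. Problem sizes in the suites
(sessions of 20 min–1 h, ensembles of 12–60 cells, 1000-replicate
calibrations) were chosen as the smallest that estimate each quantity with
comfortable margin over its tolerance.

Known limitations: the exp-threshold episode filter couples retention to
map quality for plug-in maps; the burst-ratio denominator window makes the
statistic undefined for strongly non-bursty sparse cells; the SFEP near/far
summary needs both partition sectors mapped, so extreme avoidance (near
half nearly unvisited) can leave it undefined; and the proportion-test
formula is the pooled variant only.
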