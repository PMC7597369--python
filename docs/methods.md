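# Methods

## The measurement being modeled

Two fluorescently tagged proteins — the PCNA sliding clamp and the catalytic
subunit of DNA polymerase δ — are imaged in a living nucleus in alternating
channels. The acquisition clock is interleaved: PCNA frames at
`t = k·Δ` and Pol δ frames at `t = k·Δ + Δ/2`, with `Δ = 1.34 s` per channel
(the filter-wheel dead time is folded into Δ). Chromatin-bound molecules are
immobile on this timescale and appear as diffraction-limited spots; freely
diffusing molecules are motion-blurred away. A binding event is a track: the
same molecule localized in consecutive frames within a diffusion-bounded
radius. All positions are carried in nanometers (origin at the field corner,
a pixel's integer index is its coordinate), all times in seconds; frames and
pixels appear only at I/O boundaries.

## Synthetic data generator

The generator produces ground truth with the statistical structure the
analysis assumes, so each stage can be validated by parameter recovery.

**Residence times.** Event durations are drawn from a two-component
exponential mixture, default weights (0.96, 0.04) and time constants
(1.0 s, 12.4 s): a dominant short-lived "probing" population and a minor
stable population. Events are placed uniformly over an axis-aligned ellipse
(semiaxes 8.0 × 6.0 µm, a typical nuclear projection) centered in the
512 × 512 px field, with start times uniform over the 1000-frame (~22 min)
acquisition.

**Colocalized pairs.** A configurable fraction (default 0.021) of the
*observable* Pol δ tracks — those spanning at least two frames; the
closed-form observability of an exponential dwell τ on a grid Δ is
`exp(−Δ/τ)·(τ/Δ)·(1 − exp(−Δ/τ))` — receive a PCNA partner at the same
position up to a uniform-in-disc offset (default ≤ 20 nm). Arrival and
departure order classes are drawn from configurable categoricals (defaults
0.79/0.10/0.11 for PCNA-first/Pol δ-first/simultaneous arrivals and
0.84/0.09/0.07 for Pol δ-first/PCNA-first/simultaneous departures). Planted
non-simultaneous gaps are at least two frame intervals so the class survives
discretization; the Pol δ duration of a pair is drawn from the residence
mixture conditioned on the two-frame qualifying minimum and padded only when
the drawn classes require a longer overlap (e.g. Pol δ arriving first needs
the partner to start inside the Pol δ interval). That conditioning alone
reproduces a ~4 s median colocalization time from the stated mixture.

**Hubs.** Each of `hub_count` (default 20) hub centers hosts a chain of
revisits: member positions uniform within `hub_radius` (default 84 nm) of the
center, durations from the stable population conditioned to span ≥ 2 frames
(so every member survives the long-event map filter and planted latencies
stay well-defined), and waiting times between a departure and the next
arrival drawn from a three-exponential latency mixture, default weights
(0.37, 0.40, 0.23) and constants (8, 25, 200) s.

**Observation effects.** Each event is retained with a per-channel label
fraction; its visible lifetime is `min(duration, bleach time)` with the
bleach time exponential per molecule (defaults 99.3 s for the Pol δ dye,
166.8 s for the PCNA dye — single-exponential bleaching, matching how bleach
rates are estimated); localizations get isotropic Gaussian noise (default
σ = 25 nm per axis, consistent with a 47 nm two-channel colocalization gate);
interior frames blink away with probability 0.05 in runs of at most three
frames; and continuous times are discretized onto the interleaved grid only
at emission. Movies are rendered as 2D Gaussian PSFs (σ = 1.5 px) on a
constant background with Poisson shot noise, 16-bit.

What the generator does **not** emulate: diffusing unbound molecules (motion
blur removes them in acquisition), 3D defocus, camera EM-gain statistics
beyond Poisson noise, drift, chromatic offset, and cell-to-cell parameter
variability (all cells share one parameter set). Passing recovery tests
therefore show the analysis is correct for data obeying its assumptions, not
that real nuclei obey them. Two known composition properties of the defaults:
hub members are all stable binders, and detection thins short events roughly
twofold, so the *observed* stable-population share in a default simulation
(~20–25%) exceeds the generating 4%; and detection losses (bleach truncation,
noise at the 47 nm gate) make the observed colocalization frequency roughly
half the planted fraction.

## Tracking

Spots are detected as local maxima above a threshold over the frame median
and refined by least-squares 2D Gaussian fits in a 9 × 9 px window; fits that
fail, leave the window, or have widths outside 0.5–3 px are rejected.
Raw (unsubtracted) movies can be background-corrected first with a
rolling-ball filter (radius 50 px). Linking is per-frame optimal bipartite
assignment (Jonker–Volgenant via `scipy.optimize.linear_sum_assignment`)
under the gating radius `r_max(Δt) = √(4·D·Δt)` with `D = 0.05 µm²/s`;
a track may bridge blind gaps totaling ≤ 5 s (three per-channel frames).
Track duration follows the spanned-frames convention
`(last − first + 1)·Δ`, so the shortest observable event lasts exactly Δ.
Tracks touching the first or last movie frame are flagged censored; censored
tracks are excluded from residence-time fitting (their durations are lower
bounds that would bias exponential fits) but retained for maps and
colocalization. Nuclear filtering keeps tracks whose mean position lies
inside (or on) the ROI polygon.

## Colocalization and binding order

A Pol δ track qualifies if its duration exceeds 1.34 s. A qualifying track
pairs with a PCNA track when their closed bound intervals overlap on the
interleaved clock (boundary contact counts) and the distance between their
time-averaged positions *over the overlap window* is below 47 nm — averaging
suppresses localization noise; a per-frame minimum-distance mode is available
behind a flag. Pairing is Pol δ-centric and one-to-one: candidates are
accepted in order of increasing separation, ties broken by longer overlap.
Because the channels are never sampled at the same instant, arrivals or
departures within one frame interval are classified simultaneous; otherwise
the sign of the start (end) difference decides. Frequencies are reported per
qualifying Pol δ track. The chance level is estimated by redrawing every
track's mean position uniformly over the nuclear ROI (channel-independent,
durations and frames preserved). Class fractions carry bootstrap SDs
(resampling events with replacement, default 1,000 replicates); the quadrant
table crosses non-simultaneous arrival and departure classes and reports each
quadrant's share plus median partner-alone-before, colocalized, and
partner-alone-after intervals with bootstrap 95% CIs.

## Survival analysis

Residence analysis fits the empirical survival curve (1 − CDF) of a cell's
uncensored track durations with `S(t) = Σ fᵢ·exp(−(t − t₀)/τᵢ)`,
`fᵢ ≥ 0, Σfᵢ = 1`. Numerical choices, in order of importance:

- **Left shift.** Durations below one frame interval cannot exist, so the
  support starts at the minimum observed duration. For exponential dwells
  sampled on a frame grid the quantized survival values at the support points
  are exactly geometric with the true τ, making the left-shifted fit free of
  discretization bias.
- **Weighted least squares + likelihood polish.** The curve is fitted by
  Levenberg–Marquardt least squares with residuals weighted by the inverse
  binomial standard deviation of the empirical survival values
  (`√(s(1−s)/n + 1/n²)`), over multi-start initializations (weights via
  softmax, τ via log transform). Plain unweighted LS on the 1 − CDF is far
  less efficient for a minor component (empirically ~2.4× the SD of the
  maximum-likelihood estimate for a 4% component at n = 10,000), so when raw
  durations are available the WLS optimum — and several distinct runner-up
  optima, since merged-component basins exist — is polished by Nelder–Mead
  maximum likelihood and the best likelihood wins. Durations detected to lie
  on a regular lattice get the exact discrete (geometric-mixture) likelihood;
  continuous data get the left-truncated density. Curve-only input falls back
  to pure WLS (`method="wls"`).
- **Model selection.** Corrected AIC, on the log-likelihood when durations
  are available and on the least-squares objective otherwise. Fits whose
  extra component is unidentifiable (weight < 10⁻³ or adjacent τ ratio
  < 1.3) are excluded from the comparison; ties go to the smaller model.
  An F-test alternative is not provided.
- **Binned mode.** A 1 s-binned survival curve is available
  (`survival_curve(..., bin_width=1.0)`) for comparison with histogram-based
  protocols; the unbinned curve is the default.

For two components the package reports T₁ (short, unstable) and T₂ (long,
stable) with population percentages `100·fᵢ`. Per-cell fits feed group
comparisons (two-sample Kruskal–Wallis with tie correction; all-identical
input returns p = 1, flagged). No photobleach correction is applied by
default; `bleach_corrected_tau` inverts the competing-rate sum
`1/τ_obs = 1/τ_true + 1/τ_bleach` when a bleach constant is known.

## Hubs and revisit latencies

Event maps use track mean positions of long-lived (> 1.7 s) events, binned on
a 10-fold expanded grid (8.4 nm pixels). The 168 nm octagon window is a fixed
20 × 20 px raster (square with 6 px corner cuts, 316 px; shipped as a text
fixture and pinned bit-exactly because "octagon" admits several
rasterizations); the window anchored at pixel p covers pixels p−10…p+9 per
axis. Window counts are computed by stamping each event's kernel footprint
(identical to, and tested against, a naive per-pixel scan). Seed pixels with
≥ 3 events form hubs as 8-connected components; an event belongs to a
component when any window covering it is a seed pixel, with nearest-centroid
tie-breaking, and each event counts once. Hubs per cell are normalized per
1,000 binding events. Latencies are gaps between consecutive member events
(negatives from overlapping events clamped to zero and flagged).

Latency fits pool cells, as the per-cell counts are small. Two measurement
facts drive the protocol: (1) a measured gap is the true gap plus the two
frame phases, a lattice-valued quantity whose head (gaps under two frame
intervals) is aliased — conditional on a gap of at least two frames, the gap
distribution is again an exact geometric mixture with the true constants, so
gaps < 2Δ are excluded and the fit is left-truncated; (2) hub membership is
purely spatial, so a stray background event temporally outside a chain can
create one extreme gap — bounded by the ~22 min acquisition in study-scale
movies, which is why latencies are pooled from many movie-length cells rather
than one artificially long movie.

## Pipeline, determinism, problem sizes

Every run writes its resolved configuration; all randomness flows from one
seed (per-cell seeds are derived offsets). Identical configuration and seed
give byte-identical track tables, reports and SVG figures (fixed SVG hash
salt, no timestamps). The test suite validates stages oracle-first: brute
force O(n²) pair scans, exhaustive assignment enumeration, ray-casting
point-in-polygon, direct binning, flood fill, closed forms
(binomial bootstrap SD, competing-exponential rate sum,
Dvoretzky–Kiefer–Wolfowitz bands) and independent second-implementation
samplers. Routine problem sizes were chosen to make sampling error small
relative to the tolerances while keeping the full suite and the acceptance
script each within a few minutes on one core: 10,000 durations for mixture
recovery, 100 replicates for model-selection rates, 500 tracks per channel
for oracle equivalence, 200 randomization seeds for null calibration, 30
pooled cells for latency recovery, 5,000 events for the bleach closed form.

## Known limitations

- The simultaneity tolerance equals one frame interval; faster exchange is
  unresolvable by construction.
- Exponential-mixture decompositions with τ ratios below ~3 are weakly
  identifiable at realistic n; the degeneracy guard reports, but cannot
  rescue, such fits.
- Hub membership has no temporal criterion, so chance spatial coincidences
  contribute occasional spurious revisit gaps (quantified above).
- The randomization null redraws positions uniformly; it does not preserve
  any spatial clustering of binding sites, so it is a null for *pair*
  association only.
- Censored-track exclusion slightly depletes long dwell times in short
  movies; no survival-analysis right-censoring correction is applied.
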