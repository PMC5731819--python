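# Methods

## Kinetic model

Each surface-tethered DNA molecule is an independent continuous-time Markov
chain whose state is the set of DNA-bound proteins. Dwell times in a state
with total exit rate λ are exponential with mean 1/λ; transitions are chosen
with probability proportional to their rates (exact stochastic simulation).
Association is pseudo-first-order, `kon_per_conc × conc` (1/(nM·s) × nM),
because the nM-scale solution reservoir is not depleted by the femtomoles of
protein bound at the surface. Molecules never interact; there is no burn-in —
trajectories start in the empty state, or with a pre-loaded clamp where the
experimental protocol loads and washes before acquisition begins.

Scheme presets:

- **loading_ATP** — loader and clamp arrive as a pre-formed complex
  (co-arrival is one atomic transition); the loader departs alone at 1/0.41
  s⁻¹; the loaded clamp persists (1/1429.7 s⁻¹). A loaded clamp blocks
  further loading on that molecule.
- **loading_ATPgS** — without ATP hydrolysis the loader-clamp complex arrives
  and releases as one unit (atomic co-departure, 1/2.7 s⁻¹).
- **unloading** — loader arrivals at a pre-loaded clamp branch with fixed
  probability 0.47 into a productive path (clamp released after an
  exponential lag of mean 4.1 s; the loader remains through a second
  exponential stage so its total dwell has mean 10.8 s = 4.1 + 6.7) and with
  probability 0.53 into a non-productive visit (loader departs at 1/2.5 s⁻¹,
  clamp stays). After a productive unload the molecule is empty and, with no
  clamp in solution, absorbing. The branch probability is treated as
  concentration-independent.
- **pol3_on_clamp / pol1_dna / clamp_alone** — single-species on/off cycles;
  the loaded clamp in `pol3_on_clamp` outlives the movie by two orders of
  magnitude and is treated as permanently present.
- **competition** — any subset of {Pol IIIcore, Pol IV, Pol II} on a loaded
  clamp. Pol IIIcore and Pol IV may occupy the clamp's two grooves
  simultaneously with fully independent kinetics (an optional koff multiplier
  during co-occupancy exists, default 1 = strict independence); Pol II is
  mutually exclusive with both. An option sets the initial occupancy.
- **tau_complex** — the τ clamp loader tethers Pol IIIcore: loader+polymerase
  arrive together and release together (joint dwell 1/14.8 s⁻¹). The tethered
  polymerase's effective local concentration is enormous, modeled as a ~0.1 s
  mean rebinding time — far below frame resolution, so consecutive visits
  merge into one apparent binding event, which is exactly the observable
  consequence of tethering.

Association rates are free parameters (published work reports lifetimes and
lags, not kon). Where a printed release-to-arrival lag exists it fixes the
arrival rate (20.3 s at 30 nM polymerase → kon = 1/(20.3·30) nM⁻¹s⁻¹);
otherwise a surface arrival time of ~10 s at the working concentration is
used as a realistic default.

The independence model for co-localization: once both polymerases are bound
and dissociate memorylessly, the overlap ends at the summed rates, so its
mean duration is 1/(1/τ_A + 1/τ_B) — for 15.7 s and 14.2 s lifetimes, 7.46 s.

## Acquisition model

Channels are exposed sequentially inside an acquisition cycle: 50 ms exposure,
one frame per channel slot every 220 ms (0.086 s single-channel, where no
filter changes are needed). The per-channel frame periods (0.66/0.44/0.086 s)
are direct configuration constants rather than being derived from exposure +
switching time, because the published timing numbers are not mutually
derivable; this reproduces all three frame rates without inventing a readout
model. Interval (stroboscopic) mode takes one cycle every, e.g., 10 s.

Labeling is a Bernoulli(p_label) draw per *binding arrival* of a protein copy
(a departing protein is replaced from solution by a fresh, independently
labeled copy). Photobleaching is a constant hazard per second of illumination
accrued only during that dye's exposures, so the apparent on-DNA lifetime of
an otherwise immortal dye is (1/hazard) × cycle/exposure — the duty-cycle law
that motivates interval imaging. Hazards are calibrated from the dyes'
measured apparent lifetimes on DNA-bound clamps (274.4 s Atto 488, 145.7 s
Atto 565, 93.0 s Atto 647N); each scenario attributes those apparents to the
continuous-mode schedule of its own channel count, since the exact
illumination schedule of the dye measurements is not recorded. Interval-mode
runs then correctly enjoy the duty-cycle extension.

Intensity at a sample is background + Σ(brightness of bound, labeled,
unbleached dyes in that channel) + additive Gaussian noise, point-sampled at
the start of each exposure (exposures are far shorter than any simulated
kinetic time scale). Brightness is constant per dye; there is no blinking.
Default scale: background 20, brightness 10, noise SD 1 (SNR 10).

## Detection

Per-trace background location/scale are the median and MAD (× 1.4826). A
binding interval is a maximal run of samples above `low` SD over background
containing at least one sample above `high` SD (hysteresis); gaps of at most
`max_gap` frames are bridged; runs shorter than `min_length` are dropped.
Library defaults: high 4, low 2, gap 1, min length 1 — these detect
single-frame collision events while rejecting isolated spikes in a single
trace (~10³ samples). At dataset scale (10⁶–10⁷ background samples per run) a
4 SD seed threshold would admit hundreds of fake single-frame events, so the
scenario presets seed at 5 SD, which keeps the expected false-positive count
below one per run while leaving SNR-10 events untouched. The dwell convention
is (frames in run) × per-channel period: a single-frame event has a dwell of
one period, and sub-frame events appear as single-frame events. Intervals
touching the first/last frame are flagged left/right censored.

The median/MAD background requires occupancy below ~50%. Scenarios whose
traces are nearly always-on (the pre-loaded clamp in interval mode, Pol I at
these rates, the tethered τ-complex channel) instead threshold off explicit
background statistics, as an analyst would from empty surface regions or
camera calibration; these are configuration inputs, not fitted values.

Optional spot detection on synthetic image stacks: local maxima above a
robust threshold on the maximum-intensity projection, centroid refinement,
a greedy exclusion radius implementing the "well separated" criterion, and
fixed-aperture trace extraction.

## Event classification

Under sequential channel acquisition, two proteins arriving at the same
instant are recorded at worst one frame apart, so *simultaneous* means start
frames within ±1 frame; the same tolerance applies to co-departure.

- **Loading**: a co-arriving loader+clamp pair; records loader dwell, whether
  the clamp persists, and a co-release flag (the ATPγS signature).
- **Unloading**: a loader interval beginning while a clamp interval is
  already in progress. Productive if the clamp signal ends during the visit
  (or within one frame after); the lag is (clamp end frame − loader start
  frame) × period. Loader arrivals with no concurrent clamp are "solo".
- **Exchange**: all polymerase intervals of a molecule in time order; each
  consecutive cross-species pair is classified exactly once — a switch when
  disjoint (lag = gap) or a co-localization when overlapping (duration =
  overlap; first-in and first-out species recorded to test arrival/departure
  independence). Percentages are over all classified cross-species pairs.
  Pairs whose first member is right-censored are unclassifiable and skipped;
  censored events are excluded from lag/duration means but counted in
  direction tallies. Per-molecule tallying is available via the event
  records' molecule ids.
- **Label efficiency**: for an obligate pair scored as A-only / B-only /
  both, p_A = n_both/(n_both + n_B_only) — each label's efficiency is
  estimated from the events certified by the partner's label; doubly-dark
  events are invisible and carry no information. Binomial standard errors.

## Dwell-time fitting

Two estimators:

- `fit_exponential_histogram` — the field-standard one-parameter exponential:
  bin width ≈ τ/2 (rounded to whole frame periods, since detected dwells are
  frame-quantized; bin origin 0), least squares of
  N(t_mid) = (n·Δ/τ)·exp(−t_mid/τ) with the amplitude pinned by count
  normalization, iterated re-binning until τ moves < 1% (a revisited bin
  width, or a return to the previous-but-one τ, terminates the occasional
  two-cycle between adjacent binnings). A free-amplitude two-parameter
  variant exists for sensitivity analysis. Optional first-bin exclusion for
  distributions whose first bin is depleted by a competing fast process;
  default off. Right-censored dwells are excluded, matching what a histogram
  of complete dwells can contain.
- `fit_exponential_mle` — exponential maximum likelihood. Continuous case:
  τ̂ = total observed time / number of uncensored events (censored dwells
  contribute survival time). Frame-quantized case: conditioned on detection
  (k ≥ 1 frames), k − 1 is geometric with ratio q = exp(−Δ/τ), giving the
  closed form q̂ = S/(S + n_unc) with S = Σ(k−1); this removes the +Δ/2
  discretization bias of a naive mean. Left-censored intervals are retained
  in the MLE: the residual life of an exponential dwell measured from the
  first frame is itself Exp(τ).

`bootstrap_sem` provides a seeded nonparametric bootstrap of any estimator.

## Photobleaching and reported lifetimes

Bleaching and dissociation are competing exponential risks:
1/τ_app = 1/τ + 1/τ_bleach. Every lifetime is reported twice: the raw fitted
value (also the headline `tau_<species>` name) — the like-for-like comparison
with published apparent lifetimes measured under the same illumination — and
a corrected value obtained by inverting the composition law with the
calibrated hazard, which estimates the generating dissociation rate
regardless of duty cycle. The corrected value is the meaningful one where
bleaching is not a small perturbation (the interval-mode clamp lifetime, Pol
I on Atto 647N). For the ATPγS joint complex, co-release classification
requires both dyes to survive to the joint departure, so the two hazards add
in the correction. The same survival argument thins the observed unloading
lag density by exp(−L·Σ 1/τ_bleach); the unloading report therefore includes
a dye-survival-corrected mean lag alongside the raw one.

## Scenario runner and seeds

A `ScenarioConfig` is fully serializable (YAML) and hashable; a run derives
independent child seeds for simulation and rendering from one seed via
`numpy.random.SeedSequence`, so identical (config, seed) reproduces reports
bit for bit. The standard run size is 2000 molecules — large enough that
recovery standard errors sit well below the published standard errors being
compared against, while a full scenario completes in a few seconds on one
CPU. Recovery checks use combined standard errors (recovery s.e.m. plus the
published s.e.m. of the installed value, where one exists), with |z| ≤ 3 as
the pass criterion in run reports.

## What the generator does and does not emulate

Emulated: exponential binding kinetics with atomic co-arrivals/co-departures,
interleaved stroboscopic sampling, per-copy incomplete labeling, duty-cycle
photobleaching, background and Gaussian noise, censoring at movie edges,
frame quantization. Not emulated: spot overlap and field-level optics (unless
the optional movie renderer is used), stage drift and registration error,
dye blinking, EMCCD gain statistics, protein depletion, DNA synthesis
kinetics. Passing recoveries therefore validate the analysis chain against
the stated stochastic model of the measurement, not against every real-world
imaging artifact.

## Known limitations and deliberate simplifications

- The consecutive-pair exchange classifier's observed release-to-arrival lag
  spans same-species re-arrivals and unlabeled (dark) intermediate events, so
  it does not equal the per-species arrival time except in single-competitor
  designs; the competition presets accordingly make no lag recovery claim.
- With unequal dissociation rates the switch-direction split is close to, but
  not exactly, 50/50 even at equal concentrations and arrival rates; exact
  evenness holds for fully exchangeable species.
- Under tethering (τ-complex) the model's free second groove overstates
  co-localization frequency relative to a clamp whose grooves are already
  occupied by the polymerase-exonuclease pair; the tethering signature tested
  is the first-in asymmetry, which is robust to this.
- Co-localization durations carry a +1-frame quantization offset from the
  inclusive overlap convention; for short-lived mutants this offset exceeds
  the statistical error, so overlap-duration recovery is only claimed for
  wild-type lifetimes at the 3-color frame rate.
- A ~2% residual of ATPγS co-departures is classified as non-co-release when
  a quick rebinding is gap-bridged in one interleaved channel but not the
  other; the generator's co-departure itself is atomic.
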