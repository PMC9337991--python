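# Methods

This note documents the models implemented in `riboquant`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user should know before trusting a
number.

## Construct model

A construct is the RNA product of a single-round transcription template.
Coordinates are 1-based and inclusive, matching how nucleotide positions
are annotated on gels ("position A35"). The *halt site* is the position at
which the polymerase stalls during the initiation phase (the initiation
nucleotide mix lacks CTP, so the stall occurs at the first C of the
transcript); the halt site belongs to the initiation region, so the
initiation region is `[1, halt]` and the elongation region of a product
ending at `end` is `(halt, end]`. This boundary convention is fixed and
tested; the biology does not force either choice, but every downstream U
count depends on it being stated.

Transcript species labels form the closed set `{T, T1, T2, FL}` — one or
two internal terminators plus the full-length product. Arbitrary extra
terminators are out of scope; the formulas below are written for these
cases and stay unambiguous because of it. DNA-alphabet input (T
characters) is transcribed to U with a logged notice. Terminator 3' ends
are user inputs: gel sizing gives only approximate product lengths, so no
attempt is made to call terminator ends from sequence (no hairpin
prediction, no folding).

## Radiolabel correction and termination fractions

Single-round transcription incorporates [α-³²P]-UTP at fraction `f_init`
during initiation and `f_elong` during elongation. The relative
radioactivity of a species is

    R = u_init * f_init + u_elong * f_elong.

Two presets carry the published labelling schemes: `single-2022`
(`f_init = 0.07, f_elong = 0.002`) and `tandem-2022` (`0.03, 0.004`). The
tandem scheme's elongation fraction is printed inconsistently in its
source (0.3% in one equation, 0.4% in the assay description); the preset
uses 0.004 and arbitrary values are accepted.

For a single terminator, percent termination is `100 * T / (T + FL * X)`
with `X = R_T / R_FL`. For tandem constructs the printed correction-factor
expression is dimensionally inconsistent as a single ratio; it is
implemented as two pairwise factors `X_T2 = R_T1/R_T2` and
`X_FL = R_T1/R_FL`, which reduces to the single-terminator definition and
is algebraically identical to normalizing corrected counts `I_s / R_s`.
`tandem_fractions` computes both routes and raises if they disagree beyond
rounding — the identity is an internal consistency check, not an
assumption. All fractions are reported in `[0, 1]`; percent appears only
at presentation surfaces. No background subtraction is applied by default
(an optional per-lane constant exists, default 0).

## In-line probing quantification

Per lane, band volumes are divided by a designated constant-intensity
reference band (removing loading/exposure differences — any common lane
scale cancels exactly). Each modulated site is then rescaled to fraction
bound using two anchor lanes,

    f = (I_norm - I_zero) / (I_sat - I_zero),

with the no-ligand lane defining 0 and the highest-concentration lane
defining 1 by default (overridable: true saturation of the top lane is
not guaranteed). The anchor difference carries the sign, so suppressed
and enhanced sites need no special-casing. Multiple quantified sites are
averaged into one curve before fitting; per-site curves remain available
for diagnostics.

### Dose-response fit

`fit_kd` fits `f(L) = bottom + top * L^h / (L^h + K_D^h)` by bounded
least squares on log₁₀ concentration. The zero-concentration lane anchors
the scale but is excluded from the regression (log undefined). Choices
that matter:

* **Hill slope** is pinned at 1 by default (one-to-one binding); the
  free-slope fit is the stoichiometry check and recovers h from data
  generated at other slopes.
* **Free plateaus (default).** The top lane used as the f = 1 anchor may
  not be saturating: with K_D = 15 mM and a 100 mM top lane the true
  fraction bound at the anchor is only 0.87, and pinning top = 1 then
  biases K_D low by ~20%. A free top absorbs this, plus any common-mode
  multiplicative error in the saturating anchor; a free bottom absorbs
  the additive offset that noise in the zero-anchor lane imposes on the
  whole curve. This is the standard four-parameter-logistic family of
  dose-response fitting. Pinned modes (`top_mode="fixed-1"`,
  `bottom_mode="fixed-0"`) are retained; with them, noiseless data whose
  anchor sits at 45×K_D shows the predictable ~4–6% K_D underestimate
  that the tests document.
* **Variance weights.** Band noise is multiplicative, so the
  fraction-bound error of a lane scales with its normalized band level
  divided by the anchor span. Weights are propagated from the measured
  bands (relative weights only); this mainly stops low-signal lanes of
  strongly suppressed sites from being drowned out by baseline-level
  lanes.
* Fits hitting the iteration cap raise with the best iterate attached;
  fewer than 4 distinct nonzero concentrations is an error; a mean
  relative anchor-band change below 0.5 warns of weak modulation, and
  fraction-bound values outside [-0.2, 1.2] warn of anchor failure.

### Ion selectivity

`classify_ion_response` scores each ion of a panel by the
direction-aligned mean relative change of normalized intensity at the
declared modulated sites versus a no-ligand baseline; signing each site by
its known direction lets incoherent band noise cancel while a coherent
structural response accumulates. Replicate lanes per ion (and replicate
baselines) are averaged on the normalized scale. An ion is modulating when
its effect exceeds `effect_threshold` (default 0.2) times the strongest
effect in the panel; a threshold of 0 is accepted but warned as
degenerate. Single-lane verdicts at 10% band noise are fragile with only
two or three quantified sites — realistic verdicts rest on many modulated
bands and replicate lanes, which is how the tests exercise it.

## Tandem logic-gate model

Each switch maps its ligand concentration to a read-through probability
through a Hill response bounded by a floor and a ceiling:

    ON:  p = p_floor + (p_ceil - p_floor) * θ(L),   θ = L^h/(L^h + k_half^h)
    OFF: p = p_ceil  - (p_ceil - p_floor) * θ(L)

The switches act independently and in fixed order (T1 upstream of T2);
the transcript partition `(1-p1, p1(1-p2), p1·p2)` sums to 1 exactly and
matches exhaustive enumeration of the four per-molecule outcomes.

Calibrated defaults: switch 1 (Na⁺, ON) `p_floor 0.02, p_ceil 0.80, h 1`
— the ceiling matches the ~80% maximal T1 read-through observed at
saturating Na⁺; switch 2 (c-di-AMP, OFF) `p_floor 0.05, p_ceil 0.95,
h 2` — the floor keeps the full-length fraction at or below ~5% under
saturating c-di-AMP, and the slope reflects that these riboswitches bind
two c-di-AMP molecules. These are calibrations to observed extremes, not
fitted values. Dose-response midpoints are user parameters — no midpoints
are published for the tandem construct — with placeholders of 2.2 mM
(Na⁺, borrowed from the well-characterized aptamer's K_D scale) and 1 μM
(c-di-AMP, typical second-messenger scale). The truth table evaluates the
four (low, high) ligand corners (defaults 0 and 1000 × k_half), calls a
corner ON when its FL fraction reaches `on_threshold` (default 0.3,
arbitrary but fixed and exposed), and reports whether the pattern is
material nonimplication. The fidelity score, `min(FL over expected-ON
corners) - max(FL over expected-OFF corners)`, is positive iff some
threshold separates the gate; it is a convenience metric of this package,
not a published statistic. Kinetic, co-transcriptional and
folding-thermodynamic effects are deliberately out of scope.

## Synthetic data generators

The generators exist because the original gel densitometry is not
deposited; they produce data with exactly the statistical structure the
analyses assume, which is what makes the recovery tests meaningful and
also bounds what they show.

* **Probing titrations.** Modulated sites follow
  `baseline + amplitude * saturation * θ(L)` with a single shared K_D;
  reference/inert sites are flat. The default grid is a zero-ligand lane
  plus 12 log-spaced concentrations from 0.01 to 100 mM (~3 per decade),
  mirroring a 10 μM–100 mM titration. A `saturation < 1` parameter exists
  because full saturation of the site response at the top lane is not
  guaranteed in real assays.
* **Transcription lanes.** Each of n molecules passes each terminator
  independently (binomial sampling); band volume = count × R × lane scale
  × noise. True counts are returned as a side-car oracle.
* **Noise** is multiplicative lognormal per band with unit mean
  (densitometry noise scales with band volume), default cv 0.10. The real
  assays publish no noise model; this is the stand-in the recovery
  experiments are calibrated against.
* **Ion panels** generate the selective ion's lane at θ(L) and every other
  ion's at 0 — rejection is total by construction, which encodes (not
  tests) the selectivity claim.
* **Random constructs** place exactly one C in the initiation region (its
  last position, the halt site), end each terminator on a six-U run by
  default, and draw remaining positions uniformly. Defaults give the
  170-nt single-terminator geometry (13-nt initiation region).
* The ~4 mM Na⁺ contributed by transcription buffer is modelled as an
  additive offset to nominal supplementation (`effective_na_mM`,
  switchable off).

Everything is a pure function of parameters and seed. What the generators
do **not** emulate: gel physics (band shapes, smearing, saturation of the
phosphor screen), correlated noise between bands in a lane beyond the
shared reference, RNA degradation ladders, partial digestion references,
or any kinetic structure. Passing recovery tests therefore shows the
equations and estimators are correct under the assumed noise structure —
not that the assumptions hold on any particular real gel.

## Problem sizes and determinism

Recovery experiments use 100 replicate titrations per condition and 10⁵
molecules per transcription lane; the Monte-Carlo/analytic partition
comparison uses 3-binomial-SE bands at n = 10⁵. These sizes give the
medians and fractions sub-percent precision while keeping the full test
suite and the acceptance script fast. All randomness flows through
explicit numpy generators seeded from user-supplied integers; identical
configuration yields byte-identical result files, and every result JSON
embeds the configuration hash.

## Known limitations

* Terminator end positions and halt sites are inputs; nothing is inferred
  from sequence beyond the first-C rule.
* The K⁺-competition effect on Na⁺ affinity (apparent K_D worsening in
  high-K⁺ buffer) is observed in the source assays but has no model here
  and is not guessed.
* The gate model treats switch responses as equilibrium dose-responses of
  the transcribing population; real co-transcriptional decisions are
  kinetic.
* `fraction_bound` can exceed [0, 1] under noise (flagged, not clipped);
  downstream consumers should treat the flag as an anchor-quality signal.
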