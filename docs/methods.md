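# Methods

This note documents the models, numerical choices and limitations behind
`fibremech`, in the order the pipeline runs.

## Calibration

The cantilever is treated as a rectangular beam. Thickness is recovered
from the thermal normal spring constant through `k_n = E·w·t³/(4·l³)`;
the cube root is numerically benign and validated against a bracketing
root-finder. The effective lateral spring constant is computed as the
product of a lateral beam stiffness `k_l = G·w·t³/(3·l·(h + t/2))` and a
lateral optical sensitivity `S_l = E·(h + t/2)·InvOLS/(2·G·l)`. Both the
shear modulus `G` and the lever arm `(h + t/2)` cancel in the product,
so the code evaluates the reduced form `k_e = E·w·t³·InvOLS/(6·l²)`; the
cancellation is asserted by tests. The intermediate `k_l` and `S_l` are
exposed for inspection but are not calibration-authoritative on their
own — only their product is.

InvOLS is fitted as the slope of deflection [V] versus distance [m] over
the contact window and then inverted (fitting V-vs-m rather than m-vs-V;
the difference is below noise for linear segments but the convention is
fixed). The contact window is user-supplied by default; an automatic
detector takes the longest suffix whose linear fit has R² ≥ 0.999. The
automatic window may admit a few baseline samples, which perturbs the
slope at the percent level — acceptable for QC use, not a replacement
for a hand-picked window.

## Strain conventions

Two readings of the recorded Y-position channel are implemented:

* **geometric** (default): the channel is the lateral pull distance `d`;
  half-length `L' = √(a² + d²)`, `ε = (L' − a)/a`, `sin α = d/L'`. This
  gives ε = 0 at zero displacement.
* **literal**: the channel is read directly as the half-length,
  `ε = (l' − a)/a`. Retained for replication of the original
  processing; at zero displacement it would give ε = −1, which is why it
  is not the default.

The two agree in the large-displacement limit. Every curve records which
convention produced it; reports never silently mix them.

Samples with `sin α` below the floor (the angle where geometric strain
reaches 0.02) are masked during trace conversion rather than errored:
the 1/sin α factor amplifies noise without bound near zero angle. The
standalone force operation raises instead, since a scalar call at zero
angle is a caller error.

## Continuous pulls

Rupture detection looks for the first sample whose stress falls more
than 50 % below the maximum of the preceding 5 samples and returns the
last sample before the drop; both knobs are configurable and recorded.
A minimum-peak guard of 0.05 MPa — the same level used as the
"distinguishable from background" threshold in the cyclic analysis —
prevents pure-noise traces from ever flagging a rupture. Returning the
last pre-drop sample (rather than the local maximum of the window) keeps
the detected rupture within one sample of an instantaneous break even at
1 % noise.

Toughness integrates stress over strain by the trapezoidal rule with the
origin prepended (the curve starts at the masking floor, ε ≈ 0.02; the
missing sliver is below 0.03 % of the total for realistic curves).
Modulus 1 is a free-intercept least-squares slope on ε ∈ [0.1, 1.5] —
the lower bound skips slack/straightening noise at very low strains;
modulus 2 on the final 0.3 strain before rupture. Windows shrink with a
logged warning when the curve is short; windows with fewer than 5 points
yield NaN plus a flag rather than a fabricated number.

The tangent modulus differentiates first (centred differences) and then
smooths with a 50-sample adjacent average whose window shrinks
symmetrically at the edges. Differentiating before smoothing and the
converse differ only at the edges; the derivative-first order is fixed
and documented. Row statistics interpolate each fibre's stress onto a
common strain grid (step 0.01) and drop fibres from grid points beyond
their extensibility, so `n` decreases along the grid as fibres rupture.

## Stress relaxation

Holds are fitted with σ(t) = σ₀ + σ₁·e^{−t/τ₁} + σ₂·e^{−t/τ₂}, all
parameters bounded non-negative, time constants log-parameterized, with
`scipy.optimize.least_squares` (TRF) at tolerance 1e-10. Components are
fitted unordered and sorted afterwards so τ₁ < τ₂ — hard ordering
constraints create their own local minima.

Two starting points are used. The first is analytic: σ₀ from the mean of
the final 10 % of the hold, τ₂ from the log-linear slope of (σ − σ₀)
over the last half, τ₁ = τ₂/10, amplitudes by non-negative linear least
squares. On 120 s holds the slow component (τ₂ ≈ 90 s) has barely more
than one time constant of coverage, and this start can collapse into a
merged single-exponential minimum; a second start therefore scans a
coarse log-spaced (τ₁, τ₂) grid, solving amplitudes exactly by NNLS at
each node, and the lower-cost fit wins. With both starts the planted
time constants are recovered to machine precision at zero noise and with
sub-percent cohort-mean bias at 1 % noise.

The decay clock starts at the first sample whose Y-position equals the
hold position — the phase boundary sample that centred-difference
velocity labelling attributes to the pull. σ_max is that sample's stress
after an optional 3-sample median prefilter that suppresses single-sample
spikes. Constant holds are returned as degenerate (σ₁ = σ₂ = 0) with a
flag; fits with τ₂/τ₁ < 1.5 are flagged single-exponential-like. Flagged
fits are excluded from group summaries and the exclusions are counted.

Moduli divide amplitudes by the hold strain, Eᵢ = σᵢ/ε, with
E_max = E₀ + E₁ + E₂ reconstructing the t = 0 modulus; the elastic
proportion E₀/E_max and fast contribution E₁/(E₁+E₂) need no strain or
calibration at all, which is why they may be compared across measurement
days and crosslinking states while absolute stresses may not. Binned
summaries use 0.5-strain bins; bins below strain 0.5 carry a caveat flag
because the stress change over a hold approaches the instrument's
sensitivity there.

## Cyclic loading

Drift correction builds a piecewise-linear baseline through the median
lateral value of each zero-strain dwell (|y − y_home| < 0.1 μm for at
least 1 s), placing anchors at most 5 s apart inside long dwells and
extending the outermost anchor slopes beyond the first and last dwell.
The correction is idempotent, and its magnitude is logged against the
drift band observed on the instrument (0.015–0.293 V) as a QC warning,
never an error.

Loss% is reported in both conventions — retained% = AUC_i/AUC₁·100 (the
ratio itself) and loss% = 100 − retained% — with loss% as the headline
column: the ratio formula fixes the ingredients, while the narrative
meaning of an energy *loss* that grows with strain fixes the direction.
Hysteresis% is (AUC_pull − AUC_release)/AUC_pull·100 with both areas by
trapezoid over strain and non-positive-stress samples excluded.
Characteristic strain interpolates the first crossing of 0.05 MPa; it is
the one cyclic metric that is *not* calibration-invariant, since the
threshold is absolute.

## The synthetic generator

The generator is the inverse of the pipeline and defines the conditions
under which the package is validated. It emulates: a smoothed-bilinear
constitutive curve (softplus knee so the tangent modulus shows the three
regions — flat, rising, plateau); instantaneous rupture at a truncated-
normal per-fibre strain; hold decays
σ(t) = σ_peak·[f₀ + (1−f₀)(f_fast·e^{−t/τ₁} + (1−f_fast)·e^{−t/τ₂})],
so f₀ maps exactly onto the measured elastic proportion; instrument
geometry and schedule (10 μm wells, 0.1 μm/s, 10 samples/s, 2 μm steps,
120 s holds); multiplicative lateral noise, an optional additive noise
floor and an optional linear drift; and, in cyclic mode, permanent
elongation plus a release-branch dissipation factor.

Default parameter choices, made once: low/high moduli 2 and 8 MPa and a
stiffening onset at strain 2 (MPa-range fibre stiffness with rupture
stresses around 10 MPa); cross-section 180 nm × 180 nm; `k_e` = 1e-7 N/V
so rupture-level lateral signals land in the 2.26–8.02 V band seen on
the instrument; relaxation parameters at the reported cohort means
(τ₁ = 7.3 s, τ₂ = 90.4 s, f₀ = 0.568); cohort sizes WT 26, α390 20,
α220 23; variant presets scale mean rupture strain by the reported
extensibility ratios (1.009, 0.882), and the α220 preset uses the
reported ~16 % fast contribution. No value is reported for the wild-type
fast contribution, so its default (0.35) is arbitrary and marked as such
in the preset provenance.

The cyclic permanent-elongation rule needs two parameters rather than
one: a retention rate *c* defining the target p\* = c·(ε_peak − ε_yield)₊
and a per-cycle approach fraction. A single immediate-jump rule would
make the second and third cycles of a strain step identical, whereas
repeated cycles at one strain should keep softening slightly — which is
also what makes hysteresis strictly decrease within a step.

What the generator does **not** emulate: protofibril-level mechanics
(branching, unfolding, crosslink chemistry — no quantitative parameters
exist for them), strain-dependent relaxation, fibre thinning (true
stress), slipping or branch attachment, instrument resonances, or
non-stationary noise. Passing tests therefore demonstrate that the
*analysis* is correct and unbiased under realistic signal, noise, drift
and protocol structure — not that the fibre model captures every feature
of real fibrin data.

## Problem sizes and reproducibility

Validation cohorts use 50 incremental-pull traces (five holds each, 250
fits) for relaxation recovery, 100 repeats for Monte-Carlo fitter
studies, and 25 fibres per group for fold-change recovery; these sizes
give sampling error comfortably below the tolerances asserted while
keeping each study in the seconds-to-minutes range. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`
substreams keyed by fibre counter, so cohorts are bit-reproducible and
independent of generation order.

## Known limitations

* Engineering stress only: fibre thinning during the pull is
  unobservable in this geometry, so high-strain stiffness is
  systematically underestimated — comparably across variants.
* The double-exponential decomposition is a model choice; holds whose
  decay is effectively single-exponential are flagged, not forced.
* τ₂ ≈ 90 s against 120 s holds is intrinsically at the edge of
  identifiability; per-hold τ₂ scatter at 1 % noise is several percent
  even though cohort means are unbiased.
* Automatic phase segmentation assumes a clean commanded Y-position
  channel; heavily corrupted position data would need manual windows.
* Slipped or branched fibres must be excluded upstream (by fluorescence
  inspection); the package only honours exclusion flags.
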