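# Methods

This note documents the models behind `pulmomech`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the underlying laboratory procedure leaves the algorithm
open.

## Whole-lung model and the occlusion analysis

The forward model is a single-compartment linear lung with one Maxwell body:

    Ptr = PEEP + Raw·V' + Est·V + Pve,      dPve/dt = E2·V' − Pve/τ,  τ = R2/E2.

This is the minimal model that reproduces the occlusion signature: when flow
stops, the resistive term vanishes within one sample (the fast drop ΔP₁) and
the Maxwell pressure decays exponentially to the plateau
Pel = PEEP + Est·VT (the slow phase ΔP₂). Units are cmH₂O, ml and s
throughout; elastances in cmH₂O·ml⁻¹, resistances in cmH₂O·s·ml⁻¹.

Generator conventions the instrument does not dictate (chosen once):

* volume-controlled breaths at 100 min⁻¹ with **constant inspiratory flow**
  over 40% of the cycle and passive first-order expiration (time constant
  Te/6) rescaled so the volume returns exactly to zero each breath;
* the intubation-cannula drop k₁·V' + k₂·V'·|V'| is **added** by the
  generator so the analysis-side correction is genuinely exercised;
* additive Gaussian noise on pressure only; flow is recorded noiselessly.
  Seeds are explicit arguments; one seeded generator per call.

Analysis defaults (all in `VentConfig`): occlusions are maximal runs with
|V'| below 2% of peak inspiratory flow lasting ≥ 2 s, accepted only when the
integrated volume at the window start is within 25% of VT (i.e. the window
begins at end-inspiration). Pel is the mean over the last 0.2 s of the 5-s
read-out. Volume is integrated trapezoidally and re-zeroed at inspiration
onsets rather than high-pass filtered, keeping VT exact.

**Inflection point.** The laboratory literature names Pi but not an
algorithm. We use a two-segment continuous piecewise-linear (hinge) least
squares fit spanning 0.05 s before to 0.5 s after onset, breakpoint chosen
over post-onset sample positions; Pi is the fitted pressure at the
breakpoint. On sampled exponential decays this under-reads the viscoelastic
pressure by 1–3% (a straight line fitted to a convex decay), so Edyn — and
the Edyn/Est ratio — carry that small, documented bias; Est, read from the
plateau, does not. Very fast decays (τ ≲ 0.1 s) are intrinsically
under-resolved at 100 Hz; the viscoelastic defaults use τ = 0.3 s.
`synthgen.params_for_ratio` exploits the linearity of Pve in E2 to configure
the Maxwell element for any requested Edyn/Est ratio exactly at occlusion
onset.

The anti-aliasing analog filter of the acquisition chain is not modeled;
analysis assumes pre-filtered signals.

## AFM nanomechanics

**Hertz fit.** The deflection-space form
d = d₀ + c·[(z − z₀) − (d − d₀)]², c = 3·E·tanθ/(4·k·(1 − ν²)), has the
closed-form physical root u = [(2cx + 1) − √(4cx + 1)]/(2c), which both the
generator and the fit use, so the roundtrip has no discretization error.
Defaults: θ = 20°, ν = 0.5, k = 0.03 N/m. The fit restricts data to
indentations ≤ 500 nm; because δ depends on (z₀, d₀), the mask is
re-evaluated after each inner fit until stable. No lower indentation cutoff
is applied by default — synthetic curves are ideal pyramids — but
`HertzFitConfig.min_indentation` (≈300 nm) is available for blunted-tip
validity on real data. The optimizer is bounded trust-region least squares
with two E starts (1 and 20 kPa) and z₀ initialized at the maximum-curvature
point of d(z); restarts guard against contact-point local minima. A fit
ending unsuccessfully or with fewer than 10 in-contact samples is returned
with `converged=False` and excluded from hierarchical averaging (failed
counts are reported). Hierarchy: point E = mean of its 5 curves, site E =
mean of its 5 points, region E = mean across 3 sites.

**G\*(f).** Force and indentation phasors are estimated by one joint
least-squares regression on [constant, linear drift, cos/sin at each
stimulus frequency]. Unlike raw discrete-transform bins this is exact for
any record length (no leakage at 0.35 Hz over finite records); with the
default frequencies (0.35, 1.15, 3.55, 11.45 Hz — pairwise non-sum/
non-difference) and a 140-s record every component also spans an integer
number of periods. The drag term i·f·b(h) is subtracted with b(h) taken as
required metadata (units N·s/m); when generation and analysis use the same
b(h) the correction cancels exactly, which is asserted as a test. A
frequency whose indentation amplitude falls below 10⁻³ nm or 5 regression
standard errors is flagged as degenerate excitation.

**Two power-law fit.** (i·f)^x is expanded as f^x·(cos(πx/2) + i·sin(πx/2));
the complex residuals at all valid frequencies are minimized over
(A > 0, B ≥ 0, α ∈ [0, 1)) with a multi-start α grid
{0.01, 0.05, 0.1, 0.2, 0.3, 0.5}. At α = 3/4 the two terms coincide and only
A + B is identified — the fit still converges to a perfect-residual solution
and the degeneracy is documented by a dedicated test. The multifrequency
generator distributes the composite 75-nm amplitude equally across
components (amplitude/n per sine); the response is linear, so this choice
only fixes the excitation scale.

## Morphometry

Binarization is Otsu's global threshold on the grayscale (luminance of RGB)
with a polarity flag (`dark_tissue` default, matching bright-field H&E-like
renderings). **Vessel removal** cannot be a bare connected-component area
threshold: the septal network itself is one large component and vessels
drawn over septa merge with it. Instead, a binary opening with a disk
(default radius 5 μm, wider than any septal wall) isolates solid structures;
opened components larger than the area threshold (default 5000 μm²) are
dilated back and removed. A guard skips removal when the captured area
exceeds half the tissue (a dense field is not a vessel). A manual exclusion
mask always overrides. Specks below 20 μm² are dropped.

The probe grid places 11 vertical and 9 horizontal equally spaced lines with
a 2% per-side margin, deterministically (no random offset). L<sub>m</sub> is
estimated as the **mean interior airspace chord**: maximal air runs along
each probe bounded by septal tissue on both sides (open-ended runs at probe
ends carry no second intercept and are excluded). On an ideal square lattice
this equals pitch − wall exactly, it is exact in the all-tissue degenerate
limit (1 px chords), and it is robust to the synthetic-lattice phase
accident of a probe line lying inside an axis-aligned wall. The raw
skeleton-run count (one count per maximal run of skeleton pixels on a probe;
runs longer than 10 px flagged as probe-parallel walls and counted once) is
also reported and drives the cross-point audit image. Per-animal
L<sub>m</sub> is the mean over that animal's images.

The lattice generator renders bright airspace (gray 220) and darker tissue
(gray 90) with Gaussian gray noise; a square lattice is the default because
its chord length has an exact closed form; a honeycomb option exists for
realism checks. What the generator does **not** emulate: stain variability,
out-of-focus blur, oblique and curved septa, alveolar ducts, and tissue
shrinkage — so passing tests demonstrate the correctness of the measurement
chain, not segmentation robustness on real slides.

## Statistics

Two-group comparisons: unpaired equal-variance t-test, switched to
Mann-Whitney U when either group fails Shapiro-Wilk at α = 0.05; the gate
decision is always reported. Groups smaller than 3 or with zero variance
are treated as non-normal by the gate; two zero-variance groups resolve by
definition (statistic 0, p 1 on a tie). Factorial analyses use Type II sums
of squares by default (the studied designs are near-balanced; Type III
available by override). The repeated-measures variant is the univariate
mixed-design partitioning (one between-, one within-subject factor); no
sphericity correction beyond the univariate approach. Holm-Šidák adjustment
is the step-down 1 − (1 − p₍ᵢ₎)^(m−i+1) with running-maximum monotonicity.
Because the original study reports only significance calls, statistical
routines are validated against closed-form oracles and calibration (type-I
error 0.05 ± 0.01 under the null), never against printed p values.

## Synthetic cohorts

Between-animal variation is lognormal (mean-one corrected, so the expected
group mean equals the specified mean) applied independently to each
mechanical parameter; CV defaults to 5%. Cohort recovery experiments use
n = 7 per group — at CV 5% the standard error of a group-mean contrast is
≈1.7 percentage points, which sets the tolerance of the percent-difference
recovery checks.

## Problem sizes and determinism

Default test/demo sizes keep the full suite light: ventilation recordings
use 4–6 conditioning breaths per occlusion (the laboratory's 1 min of
ventilation adds nothing to a noiseless or mildly noisy simulation),
multifrequency records 140 s at 50–100 Hz, lattice images 400–1200 px at
1 μm/px, and the demo study n = 2–6 per group with a reduced AFM hierarchy
(the full 3 × 5 × 5 design is exercised in the aggregation tests). Every
stochastic path takes an explicit seed; reports echo the configuration,
seeds and package version, and rerunning a study with the same config is
byte-identical.

## Known limitations

* The breakpoint estimate of Pi biases Edyn low by a few percent on sampled
  exponential decays (see above); alternative operational definitions of the
  inflection point would shift Edyn comparably.
* The Maxwell-body lung is linear: no recruitment, airway-tree
  heterogeneity, or nonlinear tissue elasticity; chest-wall mechanics enter
  only as an additive elastance.
* The Hertz model assumes an ideal pyramid; tip bluntness is handled only by
  the optional minimum-indentation window, not by tip-shape deconvolution.
* L<sub>m</sub> on axis-aligned lattices is sensitive to probe/wall phase at
  the percent level; multi-field (phase-offset) averaging is recommended and
  used in the package's own ratio tests.
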