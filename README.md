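# pulmomech

Lung mechanics across three scales, in one tested Python package:

* **Whole-organ**: static and dynamic elastance (E<sub>st</sub>, E<sub>dyn</sub>)
  from volume-controlled ventilation recordings by the end-inspiratory
  airway occlusion method, with intubation-cannula pressure correction and
  chest-wall decomposition (total − lung).
* **Matrix**: local stiffness of decellularized lung extracellular matrix
  from AFM approach curves via the pyramidal Hertz model, the complex shear
  modulus G\*(f) from small-amplitude multifrequency oscillations, and the
  two power-law viscoelastic model fitted in the complex plane.
* **Microstructure**: alveolar mean linear intercept (L<sub>m</sub>) from
  section images by vessel removal, binarization, skeletonization and
  probe-grid intercept counting.

A synthetic-data module generates all three modalities with known ground
truth (a single-compartment lung with one Maxwell body, exact Hertz/G\*
forward models, and septal-wall lattice images), so every analysis stage is
verifiable end to end without animal data. The intended users are
respiratory-physiology and tissue-biomechanics groups comparing healthy and
connective-tissue-disease (e.g. Marfan) rodent cohorts.

## The models

**Occlusion method.** During ventilation the airway is occluded at
end-inspiration; tracheal pressure shows a fast resistive drop ΔP₁ to an
inflection point P<sub>i</sub>, then a slow viscoelastic decay ΔP₂ to a
plateau P<sub>el</sub> (read after 5 s). With tidal volume V<sub>T</sub>:

    Est  = (Pel − PEEP) / VT        Edyn = (Pi − PEEP) / VT

**Pyramidal Hertz model.** For a four-sided pyramidal tip of semi-included
angle θ on an incompressible sample (ν = 0.5),

    F = 3 E tanθ / (4 (1 − ν²)) · δ²,     δ = (z − z₀) − (d − d₀),

fitted for (E, z₀, d₀) by bounded nonlinear least squares up to 500 nm
indentation.

**Complex shear modulus and the two power-law model.**

    G*(f) = (1 − ν) / (3 δ₀ tanθ) · [F(f)/δ(f) − i f b(h)]
    G*(f) = A (i f)^α + B (i f)^(3/4)      (f normalized to 1 Hz)

with F(f), δ(f) from leakage-free sinusoidal regression and b(h) the
cantilever drag coefficient at the working sample thickness.

**Mean linear intercept.** A grid of 11 vertical + 9 horizontal probe lines
is intersected with the binarized, skeletonized septal structure; L<sub>m</sub>
is the mean airspace chord length (summed chord length / number of chords),
which equals pitch − wall thickness on an ideal square lattice.

## Worked example

```python
from pulmomech.synthgen import ManeuverSpec, params_for_ratio, simulate_ventilation
from pulmomech.ventmech import compute_elastances

maneuver = ManeuverSpec(VT=0.30, n_breaths_before_occlusion=6,
                        cannula_k1=0.3, cannula_k2=0.02)
params = params_for_ratio(22.4, maneuver, ratio=1.15, tau=0.3)
rec = simulate_ventilation(params, maneuver)       # 2 occlusions, 100 Hz
res = compute_elastances(rec)                      # correct, detect, measure
print(f"Est  = {res.Est_mean:.2f} cmH2O/ml")
print(f"Edyn = {res.Edyn_mean:.2f} cmH2O/ml")
print(f"Edyn/Est = {res.ratio_dyn_st:.3f}")
```

prints

```
Est  = 22.40 cmH2O/ml
Edyn = 25.53 cmH2O/ml
Edyn/Est = 1.140
```

The generator was configured for a healthy adult mouse lung
(E<sub>st</sub> = 22.4 cmH₂O·ml⁻¹, viscoelastic element tuned so the
dynamic-to-static ratio is 1.15); the analysis recovers the static
elastance exactly from the occlusion plateau (P<sub>el</sub> = 6.72 cmH₂O at
V<sub>T</sub> = 0.30 ml) and the ratio to about 1%, the small deficit coming
from the breakpoint estimate of P<sub>i</sub> on the sampled decay.

The same pattern works for the other modalities
(`synthgen.simulate_force_curve` → `afmmech.fit_hertz`,
`synthgen.simulate_multifreq` → `afmmech.compute_gstar` →
`afmmech.fit_two_powerlaw`, `synthgen.generate_alveolar_image` →
`morpho.compute_lm`), and `pipeline.run_study` drives a full multi-group
study from one YAML config. A CLI mirrors the library:

```bash
pulmomech fixtures demo --seed 0
pulmomech vent analyze demo/recording_noiseless.tsv
pulmomech lm demo/alveolar_lattice.png --px-size 1.0
pulmomech afm gstar demo/multifreq_noiseless.tsv --out gs.json
pulmomech afm powerlaw gs.json
pulmomech study run            # bundled demo configuration
```

## Layout

| module | role |
| --- | --- |
| `pulmomech.synthgen` | ventilation, AFM and histology generators + cohorts |
| `pulmomech.ventmech` | occlusion detection and elastance extraction |
| `pulmomech.afmmech` | Hertz fit, G\*(f), two power-law model, calibration |
| `pulmomech.morpho` | binarize / skeletonize / probe-grid L<sub>m</sub> |
| `pulmomech.stats` | gated two-group tests, two-way (RM) ANOVA, Holm-Šidák |
| `pulmomech.pipeline` | study orchestration, fixtures, provenance |

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and known limitations.
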