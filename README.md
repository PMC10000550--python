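# nasometry

Automatic nasal anthropometry from three-view 2D photogrammetry.

Rhinoplasty planning and follow-up rely on anthropometric measurements of the
nose — distances such as the nasal width al–al or the tip protrusion sn–prn,
and angles such as the nasolabial or nasofrontal angle.  Collecting them with
callipers and a goniometer is slow and operator-dependent.  `nasometry`
implements the photogrammetric alternative: three standardized photographs per
subject (frontal, lateral/profile, mental/basal), a small convolutional
network that regresses the soft-tissue landmark positions in each view, and a
measurement layer that converts landmark pixels into calibrated millimetre
distances, degrees, neoclassical proportion verdicts and a nasal-bridge
classification.

## What it computes

* **37 landmarks** — 23 named soft-tissue points (9 midline such as nasion n,
  pronasale prn, subnasale sn; 14 bilateral such as alare al, cheilion ch),
  expanded per side, with per-view visibility conventions.
* **12 linear measurements** d1–d12 (mf–mf, n–sn, n–prn, sn–prn, al–al,
  ac–ac, en–en, ac–prn, sbal–sn, c′–c′, cw–cw, al′–c′), each measured as a
  2D Euclidean distance in its source view and converted to millimetres via

  `D = α·Σᵢ kᵢ·c^{2i}` (scale/distortion factor),
  frontal `d = d_px·D`, lateral `d = d_px·(d_s/d_f)·D`,
  mental `d = d_px·(d_m/d_f)·D·T`,

  where α is the mm-per-pixel constant, kᵢ the radial-distortion
  coefficients, d_f/d_s/d_m per-view reference lengths and
  `T = d(g–prn)_mental / d(g–prn)_lateral` the head-tilt cosine of the basal
  view.
* **10 angles** g1–g10 (nasofrontal g–n–prn, nasomental, facial convexity,
  nasal tip, nasolabial, nasofacial, kyphion n–k–r when a dorsal hump is
  present, alar slope, interaxial and nostril-axis angles), computed as
  `θ = arccos(u·w / |u||w|)` on the view-plane vectors.
* **Eight neoclassical canons** (e.g. naso-oral ch–ch = 1.5·(al–al),
  nasofacial al–al = 0.25·(zy–zy), n–sn = 0.43·(n–gn)) with raw observed
  ratios and tolerance-based verdicts.
* **Bridge classification** from the signed deviation δ (mm) of the rhinion
  from the n–prn line: straight |δ| ≤ 1, convex δ > 1, concave
  −5 ≤ δ < −1, broken δ < −5.
* **Evaluation** — normalized mean error (NME, %) of predicted landmarks
  with the 8% per-landmark failure rule, and absolute measurement errors
  `e = |d − d̂|`.

Because clinical photograph sets are not redistributable, the package ships a
parametric synthetic-face generator (`nasometry.synth`) producing consistent
three-view images with exact ground-truth landmarks, controllable bridge
shape and a green studio background; all tests and examples run on it.

## Worked example

```python
from nasometry import sample_face, project, measure_participant
from nasometry.calibration import CalibrationParams

face = sample_face(seed=7, overrides={"bridge_delta": -3.0, "tilt_deg": 0.0})
views = {v: project(face, v) for v in ("frontal", "lateral", "mental")}
report = measure_participant(views, calib=CalibrationParams(alpha=face.alpha_eff))

print(round(report.linear[4].value, 2), "mm  nasal width (al-al)")
print(round(report.angular[4].value, 1), "deg  nasolabial angle (c-sn-ls)")
print(report.bridge.bridge_class, round(report.bridge.delta_mm, 2), "mm")
```

prints

```
33.89 mm  nasal width (al-al)
131.2 deg  nasolabial angle (c-sn-ls)
concave -3.0 mm
```

— the generated face's alar width in millimetres, its nasolabial angle, and
the bridge verdict: the rhinion was placed 3 mm posterior of the n–prn line,
so the profile is classified concave.

The same pipeline is scriptable from the shell:

```
nasometry synth --n 5 --seed 1 --out data/
nasometry train --data data/ --view frontal --out models/
nasometry detect --model models/detector_frontal.npz --data data/ --out pred/
nasometry measure --data pred/ --out reports/
nasometry evaluate --pred pred/ --truth data/ --out eval/
```

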