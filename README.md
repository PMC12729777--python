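# cytomech

Analysis toolkit for studying how uniaxial cyclic compression reorients the
actin cytoskeleton of adherent cells and what that reorientation does to
cell-membrane strain.  It is aimed at cell-mechanics groups who combine a
compression bioreactor with fluorescence imaging and finite-element
modelling: the package covers the whole computational chain — quantifying
actin-filament orientation from single-cell images, characterising the
device's stress transduction, simulating a viscoelastic cell with basal
stress fibers, and turning membrane strain into damage and viability
statistics — and ships a synthetic-data module so every stage can be tested
without microscope or bioreactor time.

## The quantities at the core

**Filament orientation.**  A cell outline is segmented and fitted with an
ellipse; the major axis is the cell long axis.  Bright linear filaments are
detected with Canny edges plus a probabilistic Hough line transform and
each filament's acute angle α ∈ [0°, 90°] to the long axis is measured.
The summary statistic is the **mean orientation value**

    mean orientation value = 1 − α̅ / 45°

which is +1 for filaments parallel to the long axis and −1 for
perpendicular ones.

**Device transduction.**  The gel Young's modulus E comes from an
ordinary-least-squares fit of the linear portion of an unconfined
engineering stress–strain curve; a drive voltage V(t) maps to cell-level
stress through σ(t) = E·g·V(t)/h (actuator gain g, gel thickness h); and
measured stress traces are fitted with y = A·sin(ωt + φ) + C by nonlinear
least squares.

**Cell model.**  A half-ellipsoid cell (nucleus embedded, base fixed) is
meshed with linear tetrahedra.  Cytoplasm and nucleus are standard linear
solids — shear modulus G(t) = G∞ + (G0 − G∞)·e^(−t/τ) with elastic bulk
response — and basal stress fibers are elastic truss chains embedded at a
configurable angle α to the long axis.  A stiff-platen contact models the
agarose overlay; transient solves report the membrane's average and peak
maximum principal strain.

**Damage statistics.**  Membrane elements above a tensile strain threshold
count as damaged (DE); cyclic-versus-static damage is summarised as
(1 − DE_cyclic/DE_static)·100 %, viability as ND/T·100 %, with Pearson
correlation (after a Kolmogorov–Smirnov normality check), Student's t-test
and one-way ANOVA for cohort analysis.

## Worked example

```python
import numpy as np
from cytomech import synthetic as syn, orientation as oq, device as dev

# draw a cell at 30 deg with four filaments at alpha = 25 deg, plus noise
img, truth = syn.generate_cell_image(
    axis_angle=30.0, filament_angles=[25.0] * 4, noise_sd=10.0, seed=7)
res = oq.quantify_image(img)
print(res.n_filaments, round(res.mean_angle, 2),
      round(res.mean_orientation_value, 4))
# -> 4 24.78 0.4493        (truth: 4 filaments at 25 deg -> value 0.4444)

# fit the measured device stress-duration curve
t = np.arange(1000) / 100.0
y = 51.777 * np.sin(3.144 * t + 281.516) + 192.474
p = dev.fit_sinusoid(dev.StressTrace(times=t, stress=y))
print(p.amplitude, p.angular_frequency, p.offset)
# -> 51.77700000000001 3.1439999999999997 192.474
```

The quantified angle (24.78°) sits within 0.3° of the drawn 25°, and the
sinusoid fit returns the generating coefficients to machine precision.

Linking orientation to membrane strain:

```python
from cytomech.pipeline import alpha_strain_sweep
print(alpha_strain_sweep(alphas=(0, 45, 90), target_elements=2000).round(4))
#    alpha_deg  avg_max_principal  peak_max_principal
#          0.0             0.0179              0.0968
#         45.0             0.0186              0.0991
#         90.0             0.0194              0.0991
```

Average membrane strain rises as the filaments rotate away from the long
axis — the mechanism by which compression-induced reorientation changes a
cell's mechanical exposure.

A command-line interface mirrors the library:

```sh
cytomech synth image --seed 4 --out scene/
cytomech orient --images scene/ --out results.csv
cytomech device fit-sinusoid --trace stress.csv
cytomech fe run --alpha 30 --freq 1 --out run/
```

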