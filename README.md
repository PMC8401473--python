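# breastfem

Patient-specific biomechanical registration of supine functional breast
images (PET-like) onto prone structural images (MR-like).

Breast MRI is acquired prone, PET/CT supine; between the two postures
gravity deforms the breast by centimetres, far beyond what intensity-based
registration handles gracefully. `breastfem` closes the gap mechanically:
it builds a finite-element model of the individual breast from the
structural supine image, simulates the supine-to-prone posture change
under gravity, personalises the tissue stiffness so the simulated nipple
motion matches the observed one, and finishes with a chest-wall landmark
refinement. Accuracy is scored by the 3D target registration error (TRE)
of lesion centroids. It is aimed at researchers in deformable medical
image registration and soft-tissue biomechanics.

## The model in brief

Tissues (adipose, fibro-glandular, skin) are nearly incompressible
neo-Hookean solids,

```
psi = mu/2 (Ibar_1 - 3) + K/2 (J - 1)^2,      Ibar_1 = J^(-2/3) tr(F^T F)
mu  = E / 2(1+nu),   K = E / 3(1-2nu),        nu = 0.49
```

discretised with 8-node hexahedra (selective reduced integration against
volumetric locking) and a tension-field membrane skin. Because every
image is acquired under load, the unloaded geometry is first recovered by
a fixed-point iteration; the prone prediction is the gravity solve of
that reference. The only free parameter is the adipose Young's modulus
`E`: a log-spaced grid search over `E in (0.5, 500) kPa` (fibro-glandular
slaved at 7.5x) matches the simulated nipple displacement `Vn` to the
target `Vmax` measured by rigid chest-wall pre-registration, stopping
when `|Vmax - Vn| <= 1 mm`:

```
argmin |Vmax - Vn|   subject to  E in [lb, ub]
```

No clinical data ships with the package; a seeded phantom generator
produces hemispherical two-tissue breasts with known ground-truth moduli,
lesions and landmarks, and forward-simulates their prone appearance, so
every stage can be validated against exact truth. See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
from breastfem import (PhantomSpec, make_supine_phantom,
                       make_prone_ground_truth, BreastRegistrationModel)

spec = PhantomSpec(breast_radius=32.0, seed=7)        # true E_adipose = 2 kPa
case = make_supine_phantom(spec)
case = make_prone_ground_truth(case, element_size=4.0)

model = BreastRegistrationModel.from_case(case, element_size=4.0)
results = model.fit(tol=1.0)
print(results.summary())
print("TRE: %.2f mm" % results.tre(case.lesion_centroid_prone))
```

prints:

```
Patient-specific biomechanical registration
===========================================================
mesh elements                                          1146
element size (mm)                                      4.00
target nipple displacement Vmax                    1.911 mm
simulated nipple displacement Vn                   1.552 mm
|Vmax - Vn| at termination                         0.359 mm
stopping tolerance                                 1.000 mm
grid trials                                              10
converged                                              True
-----------------------------------------------------------
estimated moduli (kPa)          E        nu      rho(kg/m3)
  adipose                   2.462      0.49         950
  fibroglandular           18.465      0.49        1020
  skin                   1000.000      0.49        1000
-----------------------------------------------------------
admissible E range (kPa)                       (0.5, 500.0)
TRE: 0.51 mm
```

Reading it: the rigid chest-wall pre-registration left a 1.91 mm nipple
displacement for gravity to explain on this small (32 mm) phantom; the
grid search found that an adipose modulus of 2.46 kPa (ground truth:
2.0) reproduces it to 0.36 mm, inside the 1 mm stopping rule; warping
the PET-like volume with that model and refining on the chest landmarks
lands the lesion centroid 0.51 mm from its true prone position — about
a quarter voxel.

The same pipeline is scriptable from the shell:

```bash
breastfem all --out run1 --seed 7        # phantom -> ... -> TRE report
breastfem phantom --density 0.27 --seed 7 --out hk_like
```

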