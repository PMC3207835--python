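# scintcam

Monte Carlo scintillation-camera simulation and NEMA-style image-quality
analysis for the three isotopes used in liver radioembolization:
**99mTc** (the scout-dose surrogate, a 140.5 keV gamma emitter),
**90Y** (the most common therapy isotope, a pure beta emitter imageable
only through its Bremsstrahlung continuum), and **166Ho** (a combined
beta–gamma emitter usable for both scout and therapy dose).

Radioembolization delivers beta-emitting microspheres to liver tumors
through the hepatic artery; planar and SPECT scintillation-camera images
verify where the activity went.  How well that works differs sharply
between the three isotopes, and the package quantifies the difference with
a simulated camera (hexagonal-hole collimators, 3/8″ NaI(Tl) crystal,
backscatter compartment) and the standard metrics:

* **Spatial resolution** — FWHM/FWTM of the line-spread function of a
  28 cm line source in PMMA, per NEMA interpolation rules;
* **Sensitivity** — counts/(time · activity) of a thin Petri-dish source;
* **Count-rate linearity** — the paralyzable model R_obs = R·e^(−Rτ),
  composed into the system curve R_sys(A) = S_peak·A·e^(−S_full·A·τ) and
  the 2 %-loss limit A_linmax = −ln 0.98/(S_full·τ);
* **Photon-class fractions** — every detected photon is tagged primary,
  scatter, or septal penetration from its Monte Carlo history;
* **Contrast recovery** — the NEMA torso phantom with six hot spheres,
  projected with a transport-calibrated PSF, reconstructed with
  ramp-filtered FBP, Chang attenuation-corrected, and scored as
  QH = 100·(C_H/C_B − 1)/(R − 1).

The physics and the numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Photon-class fractions of a 99mTc line source centered in 20 cm of PMMA,
imaged through the low-energy collimator in the 130–151 keV window:

```python
from scintcam import Biasing, EnergyWindow, fractions, make_camera, trace
from scintcam.phantoms import line_source_scene

camera = make_camera("VXGP", EnergyWindow(130, 151))
scene = line_source_scene(20, 11, "Tc99m")   # 20 cm PMMA, 11 cm standoff
events = trace(scene, camera, n_emitted=24_000_000, seed=20260930,
               biasing=Biasing(b1=0.3, b2=0.65, cone1_deg=15, cone2_deg=50))
rep = fractions(events, camera.window)
print(f"PF {rep.pf:.1f}%  SF {rep.sf:.1f}%  CPF {rep.cpf:.1f}%")
```

```
PF 55.4%  SF 36.8%  CPF 7.7%
```

About 55 % of the detected counts never interacted on the way to the
crystal (primary), a third scattered in the phantom or camera, and ~8 %
crossed septal lead — the collimator and window do their job for 99mTc.
Running the same scene for 90Y in its 120–250 keV window instead gives a
penetration-dominated image (CPF far above SF), which is why 90Y
Bremsstrahlung images look the way they do.

The same machinery from the command line:

```sh
scintcam fractions --isotope Tc99m --collimator VXGP --window 130:151 \
    --n-photons 1000000 --seed 1
scintcam countrate            # A_linmax / R_linmax for every configuration
scintcam iq-recon --isotope Ho166 --collimator HEGP --window 74.6:86.6
```

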