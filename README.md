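# tonosim

In-silico non-contact tonometry (NCT) on an idealized 3D human eye.

NCT instruments (Corvis ST-class) fire a calibrated air pulse at the
cornea and film its deformation; the extracted biomarkers mix the
corneal material response with the intraocular pressure (IOP), the
geometry and the surrounding tissues, so interpreting them — or
inverting them for tissue properties — needs a mechanistic model of the
whole test.  `tonosim` is that model at desk scale, for biomechanics
researchers and students: a finite-element eye (anisotropic
hyperelastic cornea and limbus, neo-Hookean sclera, linear-elastic lens
/ zonule / vitreous membrane, humors as closed incompressible
cavities), a zero-pressure prestress recovery, a shape-dependent
air-jet surrogate load coupled two-way to the deforming surface, and
Corvis-style post-processing, plus a factorial sensitivity pipeline on
top.

The corneal stroma follows the Holzapfel–Gasser–Ogden strain energy
with two orthogonal collagen families (tension-only):

    Psi = C10 (I1bar - 3) + k1/(2 k2) * sum_{i=4,6} [e^{k2 (Ibar_i - 1)^2} - 1] + kappa/2 (J - 1)^2

Reference constants: C10 = 0.05 MPa, k1 = 0.010 MPa, k2 = 100 for
cornea/limbus; sclera C10 = 0.8 MPa; all tissues rho = 0.0011 g/mm³.
The humors are pressurized to 15 mmHg by an inflow controller and then
closed, so the IOP is free to rise when the jet indents the cornea —
the closed-globe effect that an open (constant-pressure) model misses.

## Worked example

```python
from tonosim.config import default_config
from tonosim.workbench import run_prestress, run_airpuff

cfg = default_config()                      # reference eye, 15 mmHg, 120 m/s pulse
model, prestress, state = run_prestress(cfg)
model, history, report = run_airpuff(cfg, model=model, state=state)
print(f"A1/HC/A2: {report.t_A1:.1f} / {report.t_HC:.1f} / {report.t_A2:.1f} ms")
print(f"deflection amplitude: {report.deflection_amplitude:.2f} mm")
print(f"peak distance:        {report.peak_distance:.2f} mm")
print(f"max IOP:              {report.max_iop:.1f} mmHg")
```

On the default desk-scale resolution this prints

```
A1/HC/A2: 46.2 / 48.8 / 53.1 ms
deflection amplitude: 1.26 mm
peak distance:        5.63 mm
max IOP:              21.4 mmHg
```

i.e. the cornea flattens ~2.5 ms before the concavity peak, the apex is
pushed in by ≈1.3 mm (clinical band 1.09 ± 0.10 mm), the two bending
peaks sit ≈5.6 mm apart, and the trapped humors drive the IOP from 15
to ≈21 mmHg at the instant of highest concavity.

The same pipeline is scriptable from the shell:

```
tonosim airpuff --out out/          # traces.csv, profiles.csv, biomarkers.json
tonosim doe --fraction 4 --out out/ # 8-run factorial smoke batch + ANOVA
tonosim ablation --out out/         # influence of lens/zonule/membranes
tonosim convergence --out out/      # through-thickness mesh study
tonosim biomarkers --profiles frames.csv   # standalone Corvis-style CSV
```

`tonosim mesh`, `prestress`, `inflate`, `fixtures` and `report` cover
the remaining stages; every command accepts `--config run.yaml` (see
`tonosim.config.save_config` for the schema with all defaults).

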