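# aortaflow

Statistical shape modeling of the thoracic aorta coupled to reduced-order
hemodynamics of veno-arterial ECMO (VA-ECMO) support.

During peripheral VA-ECMO, oxygenated blood returns retrograde through the
descending aorta and meets the antegrade stream ejected by the left
ventricle. The mixing interface — the *watershed zone* — decides which
supra-aortic branches (brachiocephalic, left common carotid, left
subclavian: BCA, LCCA, LSA) receive native versus circuit blood, and its
position depends on both the support level and the aortic morphology.
`aortaflow` provides a desk-scale pipeline to study that interplay over a
whole population of anatomies:

1. **Synthetic population** — point-corresponded swept-tube thoracic aortas
   (ascending segment, arch, descending segment, three branches, optional
   bovine-arch variant) with known ground-truth centerlines.
2. **Statistical shape model** — PCA on the corresponded point sets:
   x(c) = x̄ + Σᵢ cᵢ √λᵢ φᵢ, with modes φᵢ ordered by variance λᵢ and cᵢ in
   population-SD units; dataset augmentation by single-mode SD sweeps
   (47 novel shapes + template on a 19-mode model).
3. **Morphometry** — centerline trees split into the seven characteristic
   tracts (total, ascending, arch, descending, BCA, LCCA, LSA), each with
   length, tortuosity (length/chord), maximal-inscribed-sphere radius,
   Frenet curvature κ and torsion τ; percent deviation from the template
   ranks shapes for simulation.
4. **Hemodynamics** — a lumped network of Poiseuille resistances
   (R = 8μL/πr⁴) with a three-element Windkessel (RCR) at every outlet,
   C dP_d/dt = Q − (P_d − P₀)/R_d, P = P_d + R_p Q (time constant
   τ = R_d C); a constant ECMO flow enters the descending aorta in shock
   mode; the ECMO-blood fraction φ(s, t) is advected along the aortic axis
   by a conservative upwind scheme and the watershed is localized as the
   sign change of the net axial flow. Cycle-mean outlet flows Q̄ are the
   final-cycle integral of Q divided by the period.
5. **Pipeline** — end-to-end orchestration with per-stage seeds and
   hash-recorded artifacts, plus a thin `aortaflow` CLI.

## Worked example

```bash
python examples/04_healthy_hemodynamics.py
```

builds the template anatomy, calibrates the Windkessel outlets to the
default flow split (70% descending, 15% BCA, 7.5% LCCA, 7.5% LSA) and the
120–130 mmHg systolic band, and simulates three 0.8 s cardiac cycles at a
5 L/min inlet flow:

```
peak root pressure (final cycle): 125.1 mmHg
  BCA         0.75 L/min  (15.0% of cardiac output)
  LCCA        0.38 L/min  ( 7.5% of cardiac output)
  LSA         0.38 L/min  ( 7.5% of cardiac output)
  descending  3.50 L/min  (70.0% of cardiac output)
sum of outlet mean flows: 5.000000 L/min (equals the 5 L/min inflow)
```

The peak root pressure sits inside the physiological systolic band, the
cycle-mean flows reproduce the calibration split exactly, and their sum
equals the imposed cardiac output (the resistive network stores no volume).
`examples/05_ecmo_watershed.py` continues into cardiogenic shock (70%
reduction of cardiac output) with ECMO support at 0, 4 and 6 L/min: root
pressure rises with support (37.5 → 105.8 → 139.9 mmHg), supra-aortic
perfusion recovers linearly in EF, and in diastole retrograde ECMO blood
reaches the ascending aorta. The other examples cover population
generation, the shape model, morphometry, and the full pipeline; run any of
them with `python examples/<name>.py`.

## Layout

```
src/aortaflow/     population, ssm, morphometry, hemodynamics, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and study-level checks)
docs/methods.md    model assumptions, parameter conventions, limitations
```
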