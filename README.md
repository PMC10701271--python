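# srsplan

Closed-loop automated treatment planning for stereotactic radiosurgery (SRS)
of solitary brain metastases, exercisable entirely on synthetic head
phantoms.  The package covers the whole chain a clinical auto-planning
system needs:

1. **Phantom generation** — head-like CT volumes in Hounsfield units with a
   spherical target (PGTV), the nine standard intracranial organs at risk,
   and a physically consistent, deliverable reference dose (30 Gy in 5
   fractions).
2. **Preprocessing** — coordinate alignment, CT clipping to [−200, 300] HU
   and affine normalization to [−1, 1], dose normalization, PGTV-centred
   cropping (224 × 224 × 32 at 2.5 mm full scale), and grouping by target
   volume (≤ 20 cc "small", > 20 cc "large").
3. **Dose prediction** — two volumetric networks: a 3D U-Net
   (structures → dose) and an attention variant with separate CT and
   structure encoders fused at the bottleneck by multi-head attention
   (queries from structures, keys/values from CT; 8 heads × 64 dims at full
   scale).  The layer stack (3D convolutions, feature normalization, ReLU,
   max-pooling, attention) is implemented in numpy with analytic gradients
   and an Adam optimizer, so training runs anywhere.
4. **Dose mimicking** — conversion of a predicted dose into a deliverable
   plan: nine auto-configured coplanar beams at 20° spacing, a sparse
   deposition matrix `D` mapping beamlet fluence to voxel dose, non-negative
   weighted least-squares fluence optimization
   `min_f Σ_v w_v (D f − t)_v² , f ≥ 0`, dual-layer orthogonal MLC
   sequencing, and recomputation of the delivered dose.
5. **Evaluation** — DVH, D2%/D98%/D95%/D50%, Dmean/Dmax,
   HI = (D2% − D98%)/Dmean, Paddick CI = |PGTV∩V_rx|²/(|PGTV|·|V_rx|),
   R50% = |V_half-rx|/|PGTV|, D2cm, brainstem V23, point-wise δ/MAE
   statistics, isodose Dice, and 2D/3D gamma analysis (3%/3 mm, global
   normalization, 10% threshold).

## Worked example

```python
from srsplan.phantom import PhantomSpec, generate_case
from srsplan.mimic import mimic_pipeline
from srsplan.evaluate import metrics_panel

case = generate_case(PhantomSpec(pgtv_radius=12.0, seed=3))   # 7.25 cc, "small"
result = mimic_pipeline(case, case.reference_dose)

panel = metrics_panel(result.delivered_dose, case)
print(f"D95%  {panel.d95:.2f} Gy   HI {panel.hi:.2f}   CI {panel.ci:.2f}   "
      f"R50 {panel.r50:.2f}")
print(f"2D gamma {result.verification['gamma_2d'].pass_rate:.1f} %   "
      f"3D gamma {result.verification['gamma_3d'].pass_rate:.1f} %")
```

prints

```
D95%  30.33 Gy   HI 0.34   CI 0.93   R50 3.74
2D gamma 100.0 %   3D gamma 100.0 %
```

The delivered plan covers 95% of the target with at least the 30 Gy
prescription, keeps the hot spot inside the PGTV with a clinically plausible
intermediate-dose spillage (R50 well under 4), and the sequenced plan
reproduces the optimized one: every point of the gantry-0 verification plane
and of the 3D volume passes the 3%/3 mm gamma criterion.

The same stages are scriptable from the shell:

```bash
srsplan generate --n-small 2 --n-large 1 --seed 11 --outdir run/
srsplan mimic    --outdir run/ --source reference
srsplan verify   --outdir run/
srsplan evaluate --outdir run/ --against plans
```

## Layout

```
src/srsplan/
  grid.py        VoxelGrid / PlanCase containers
  phantom.py     synthetic cases + reference-dose planning loop
  preprocess.py  alignment, normalization, cropping, grouping
  engine.py      beam geometry, pencil-beam kernel, deposition matrix
  nn/            numpy NN core (layers, U-Nets, Adam)
  models.py      model/training configuration, train / predict
  mimic.py       fluence optimization, MLC sequencing, verification
  evaluate.py    DVH, dose metrics, gamma analysis
  io.py          NIfTI + sparse-matrix persistence
  dicom_io.py    minimal DICOM-RT export / import
  cli.py         `srsplan` command-line pipeline
docs/methods.md  model assumptions, parameters, design notes
```
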