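# hippodvh

Sub-structure dosimetry of the hippocampus for radiotherapy cohorts.

When nasopharyngeal carcinoma is treated with intensity-modulated
radiotherapy, the hippocampus — an organ critical for memory, typically not
constrained during planning — receives a substantial incidental dose. Because
its anterior-inferior pole lies closest to the nasopharynx, the dose is not
uniform along the organ: the head receives more than the body, which receives
more than the tail. `hippodvh` implements the analysis that quantifies this:
it splits each delineated hippocampus into head (HH), body (HB) and tail (HT)
along the anterior→posterior coronal axis by fixed layer fractions
(35% / 45% / 20%), computes per-sub-region dose–volume-histogram metrics, and
produces cohort comparison tables with one-way ANOVA and pairwise tests.

It is aimed at medical-physics and radiation-oncology researchers who have
planned dose grids (DICOM RTDOSE) and structure delineations (DICOM RTSTRUCT
or a simple JSON contour format), or who want to exercise the analysis
end-to-end on the built-in synthetic phantoms.

## The method

**Sub-segmentation.** Let the structure span N coronal layers from its most
anterior to its most posterior occupied slice (inclusive). With layer
fractions f_H, f_B, f_T (default 0.35, 0.45, 0.20), the head takes layers
1..c₁ and the body layers c₁+1..c₂, where

```
c₁ = round_half_up(f_H · N),   c₂ = round_half_up((f_H + f_B) · N),
```

and the tail takes the rest. Layers are assigned whole, so the three
sub-masks partition the parent exactly.

**DVH metrics.** For a structure with M voxels inside the dose grid,

- *D_x%* — the minimum dose received by the hottest x% of the volume: the
  dose at rank ⌈x·M/100⌉ when voxel doses are sorted descending
  (D_1% ≈ near-maximum, D_99% ≈ near-minimum);
- *D_mean* — the arithmetic mean of voxel doses;
- *V_d* — the percentage of voxels receiving at least d Gy (thresholds
  given in Gy, doses stored in cGy; the boundary voxel counts as irradiated).

**Cohort statistics.** Per metric and side, values are reported as
mean ± sample SD across patients; sub-regions are compared with a classical
one-way ANOVA (F = MSB/MSW) and Fisher-LSD pairwise tests on the pooled
within-group mean square (Bonferroni optional); pre/post cognitive scores use
a paired t test. Two-tailed P < 0.050 is flagged significant; cells whose
group mean is zero are not tested and carry the "—" marker.

## Worked example

```python
from hippodvh import (make_cohort, split_structure, metrics_bundle,
                      mask_volume)

cohort = make_cohort(n_patients=10, seed=17)   # synthetic phantoms
patient = cohort[0]
split = split_structure(patient.left)          # 35/45/20 by coronal layers
print(f"layers: {split.n_layers}")
for name, mask in [("HC", patient.left), ("HH", split.head),
                   ("HB", split.body), ("HT", split.tail)]:
    b = metrics_bundle(patient.dose, mask)
    print(f"{name}: volume={mask_volume(mask):.2f} cc  "
          f"D_1%={b.d1:.0f}  D_mean={b.dmean:.0f}  D_99%={b.d99:.0f} cGy  "
          f"V_5={b.v_at[5.0]:.1f}%")
```

prints

```
layers: 20
HC: volume=3.49 cc  D_1%=1694  D_mean=821  D_99%=342 cGy  V_5=75.0%
HH: volume=1.26 cc  D_1%=1746  D_mean=1249  D_99%=823 cGy  V_5=100.0%
HB: volume=1.74 cc  D_1%=1002  D_mean=632  D_99%=410 cGy  V_5=78.0%
HT: volume=0.49 cc  D_1%=473  D_mean=392  D_99%=333 cGy  V_5=0.0%
```

The hippocampus spans 20 coronal layers, split 7/9/4 into head, body and
tail. Mean dose falls monotonically from head (1249 cGy) to tail (392 cGy)
because the dose source sits anterior-inferior to the structure — the
ordering the cohort analysis tests across patients. V_5 reads the same way:
the entire head but none of the tail receives at least 5 Gy.

The same pipeline is available from the shell:

```bash
hippodvh run --n-patients 10 --seed 17 --out results/
```

which writes `table1_whole_hc.csv` (whole-structure doses per side),
`table2_d_metrics.csv` (D metrics by sub-region with ANOVA and pairwise P),
`table3_v_metrics.csv` (V metrics likewise), the raw per-patient
`metrics_long.csv` and a run log. `hippodvh simulate|segment|dvh|stats`
expose the individual stages.

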