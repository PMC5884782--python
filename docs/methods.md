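# Methods

## Problem and scope

`hippodvh` quantifies how the incidental radiotherapy dose is distributed
along the hippocampus when the organ is not spared during planning. The
pipeline takes a 3D planned dose grid and bilateral hippocampal
delineations, splits each structure into head/body/tail (HH/HB/HT)
sub-regions, computes standard organ-at-risk dose metrics per sub-region,
and summarises a patient cohort with group statistics. It does not perform
delineation, image registration, plan optimisation, or any biological dose
modelling (EUD, NTCP).

## Geometry

All coordinates are patient-space millimetres. A `Grid3D` carries origin,
spacing, dims and anatomical axis labels (`"L-R"`, `"A-P"`, `"I-S"` or their
reversed forms); a voxel's position is its centre, and voxel volume is the
product of spacings, so anisotropic grids (e.g. 3 mm CT slices vs 1.5 mm MRI
slices) are supported directly.

**Rasterization.** A voxel belongs to a structure iff its centre lies
inside an odd number of the nested polygons of its nearest contour plane
(even-odd rule, strictly-inside containment). This matches common
treatment-planning-system behaviour, supports holes delineated as inner
rings, and — because membership is a pure point-in-polygon predicate —
makes a brute-force ray-casting oracle exact, which the tests exploit.
Partial-volume weighting at contour edges is deliberately not modelled; the
convention is declared rather than inferred, since planning systems do not
document theirs. Contour planes map to the nearest grid slice, ties broken
toward the lower index.

**Resampling.** Masks are brought onto the dose grid by nearest-neighbour
assignment at target voxel centres before any metric is computed, keeping
one canonical grid per patient. Volume is conserved to within one source
voxel per boundary voxel; spatially disjoint grids yield an empty mask plus
a warning rather than an error.

## Head/body/tail split

The structure's coronal extent N is the span from the first to the last
occupied slice along the anterior→posterior axis, inclusive. Span (rather
than a count of occupied slices) is used so that single-slice delineation
gaps do not shift the sub-region boundaries. With layer fractions
f_H/f_B/f_T (default 0.35/0.45/0.20, configurable), cumulative boundaries

    c1 = round_half_up(f_H * N),  c2 = round_half_up((f_H + f_B) * N)

assign layers 1..c1 to the head, c1+1..c2 to the body, and the rest to the
tail. Rounding the *cumulative* counts guarantees the three parts always
sum to N with no leftover layer; round-half-up is the declared tie-break.
Layers are assigned whole — no slice is divided between sub-regions. At
least 3 layers are required (`TooFewLayersError` otherwise); degenerate
roundings under extreme user-supplied ratios are clamped so every part
keeps at least one layer. The split is an exact partition: union equals the
parent, intersections are empty, volumes add exactly.

An alternative — splitting by physical length or at anatomical landmarks
such as the uncal apex — is out of scope; layer-count splitting is the
implemented convention, and is equivalent to length-proportional splitting
whenever slice thickness is uniform.

## Dose metrics

Doses are stored in cGy throughout. D_x% is computed from exact order
statistics — the dose at rank ceil(x/100 · M) of the M occupied-voxel doses
sorted descending, i.e. the minimum dose to the hottest x% — not by
interpolating a binned curve, which removes any bin-width sensitivity.
Binned cumulative curves (`compute_dvh`, default 10 cGy bins) exist only
for export and plotting. V thresholds are accepted in Gy (the table-header
convention: V_5 means ≥ 5 Gy = 500 cGy) and compared with ≥, so a voxel
exactly at threshold counts as irradiated. D_mean is the unweighted voxel
mean (all voxels have equal volume on a regular grid).

## Synthetic phantoms

The generator (`hippodvh.phantom`) emulates the study conditions the
analysis assumes, at phantom scale:

- **Structures.** Each hippocampus is a curved tube of length 35 mm and
  radius 5 mm running anterior-inferior → posterior-superior, with a 6 mm
  lateral bow, mirrored across the sagittal midplane; on the default
  80×80×60 grid at 2 mm isotropic spacing it spans 20 coronal layers and
  has a volume of ≈3.5 cc, in the range of adult hippocampi.
- **Dose.** `dose(v) = d0 · j · exp(−‖v − s‖/λ)` with the peak `d0 = 7040
  cGy` (the prescription dose of the primary nasopharyngeal target, 7040
  cGy in 32 fractions), the source `s` at a nasopharynx-like point
  anterior-inferior-medial to the structures, and falloff length `λ = 25
  mm`. These defaults put whole-hippocampus mean doses near 1000 cGy and
  sub-region means in the ~400–1700 cGy range, matching the magnitudes
  reported for unspared hippocampi in this treatment site. Because the
  source is anterior-inferior and the field decays monotonically with
  distance, every phantom satisfies D_mean(HH) > D_mean(HB) > D_mean(HT) —
  the qualitative signature the cohort analysis is designed to detect.
- **Inter-patient variability** is a single multiplicative lognormal jitter
  per patient (σ = 0.2, median 1), emulating anatomy- and plan-driven
  spread between patients. It scales the whole field, so orderings are
  preserved while cohort SDs become realistic fractions of the means.
- **Cognitive scores** (optional) are digit-span-style integers clipped to
  [0, 17]: pre ~ N(8.6, 1.3²), post = pre − 0.6 + N(0, 1), emulating a
  small post-treatment decline around the observed pre-treatment mean.

With a midline source the left and right sides are exact mirrors and their
metrics coincide; displacing the source laterally breaks the tie toward the
displaced side. Per-patient random streams are spawned from a master seed,
so cohorts are byte-reproducible.

What the phantoms do **not** model: realistic IMRT beam arrangements and
optimiser behaviour (real fields are not monotone in distance and can
locally invert the HB/HT ordering, as clinical data occasionally show),
anatomical shape variation between patients, delineation noise, and any
correlation between dose and cognitive scores. Passing tests therefore
demonstrate the correctness of the segmentation, metric and statistics
machinery under the stated dose model — not that clinical cohorts must
reproduce the orderings.

## Statistics

Summaries are mean ± sample SD (n−1 denominator; SD undefined at n=1 and
shown as "—"). The sub-region comparison is a classical one-way ANOVA
(F = MSB/MSW, df k−1 and N−k), delegated to `scipy.stats.f_oneway` with
explicit degenerate handling: all-identical values give F=0, p=1; zero
within-group variance with unequal means raises. Pairwise comparisons are
Fisher-LSD: t = Δmean / √(MSW·(1/nᵢ+1/nⱼ)) on the pooled MSW with N−k df,
unadjusted — chosen because clinical tables of this kind report unadjusted
per-pair P values without naming a post-hoc method; Bonferroni is available
as an option. The paired pre/post comparison is the standard paired t test
(`scipy.stats.ttest_rel` with degenerate handling). Significance is strict:
p < 0.050. Cells whose group mean is zero (e.g. V_40 of an unirradiated
tail) are excluded from testing and marked "—", following the reporting
convention for untestable all-zero cells.

## Pipeline and file formats

Internal exchange formats are plain JSON (grids, masks as voxel-index
lists, contours, dose arrays) and CSV (manifests, metrics, report tables),
so the full pipeline runs without binary fixtures. DICOM RTSTRUCT and
RTDOSE readers (`pydicom`) ingest clinical exports: contours become the
internal representation with names preserved; dose is stored-value ×
DoseGridScaling, Gy converted to cGy, with grid geometry from the image
position, pixel spacing and frame offsets. DICOM writing is out of scope.

`run_study` skips patients whose structures are empty or span fewer than
three layers (logged warning; error only if all patients are skipped), logs
one structured line per patient/side/region with voxel counts and volumes,
and formats report values at fixed precision so repeated seeded runs are
byte-identical.

## Numerical and test choices

- Exactness over tolerance: rasterization, splitting and the D/V metrics
  are integer/order-statistic computations, so their tests assert equality
  against independent brute-force oracles (ray-casting point-in-polygon,
  sort/count); only D_mean uses a 1e-9 relative tolerance.
- The partition-exactness property is exercised on 200 random structures
  (random blob masks across random anisotropic grids plus hippocampus
  phantoms at several radii); the null calibration of the ANOVA uses 1000
  simulated three-group datasets of n=10 and checks the empirical type-I
  error at α=0.05 against its binomial 95% interval. Problem sizes
  (≤ ~10⁵-voxel fields, 10-patient cohorts) were chosen to keep the whole
  suite fast while covering every code path at realistic scale.
- `hypothesis` drives the randomized partition property (derandomised for
  reproducibility).

## Known limitations

- The exponential point-source dose model is analytically convenient but
  cannot produce the locally non-monotone fields of real IMRT plans.
- Center-inside voxel membership makes volumes slightly
  delineation-dependent at coarse spacings; no partial-volume correction.
- The layer split assumes the structure's anterior-posterior extent is
  meaningful after any delineation gaps (span convention); structures with
  large gaps may place boundaries inside a gap.
- Left/right structures of the same patient are analysed separately, as in
  the standard table layout, not as repeated measures.
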