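"""Study orchestration, DICOM-RT / internal file I/O, and report tables.

``run_study`` drives the full analysis: for every patient and side it
rasterizes or loads the structure, resamples it onto the dose grid, splits
it head/body/tail, and computes the dose metrics; across patients it then
builds the three report tables — whole-structure doses, D metrics by
sub-region with ANOVA and pairwise P values, and V metrics likewise — and
writes them as CSV together with a per-patient metrics file and a run log.
Cells whose group mean is zero are not tested and carry the "—" marker.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pydicom

from .dvh import DEFAULT_V_THRESHOLDS_GY, DoseGrid, metrics_bundle
from .errors import EmptyStructureError, FormatError, TooFewLayersError
from .phantom import PatientPhantom, PhantomConfig, make_cohort
from .stats import (
    SKIP_MARKER,
    GroupSamples,
    PairedScores,
    PosthocMethod,
    one_way_anova,
    paired_t,
    pairwise_tests,
    summarize,
)
from .structures import ContourPlane, ContourSet, Grid3D, StructureMask, \
    mask_volume, rasterize_contours, resample_mask
from .subsegment import SubregionRatios, split_structure

logger = logging.getLogger("hippodvh")

REGIONS = ("whole", "head", "body", "tail")
SUBREGIONS = ("head", "body", "tail")
REGION_DISPLAY = {"whole": "HC", "head": "HH", "body": "HB", "tail": "HT"}
SIDES = ("HC-L", "HC-R")
D_METRICS = ("D_1%", "D_50%", "D_mean", "D_99%")


@dataclass
class StudyConfig:
    """Configuration of one cohort analysis run."""

    mode: Literal["simulate", "files"] = "simulate"
    n_patients: int = 10
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    manifest: str | None = None  # CSV for mode="files"
    ratios: SubregionRatios = field(default_factory=SubregionRatios)
    v_thresholds_gy: tuple[float, ...] = DEFAULT_V_THRESHOLDS_GY
    posthoc: PosthocMethod = "lsd"
    scores_csv: str | None = None  # optional pre/post cognitive scores
    with_scores: bool = False  # simulate paired scores
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(v) for v in self.v_thresholds_gy)
        if any(v <= 0 for v in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("v_thresholds_gy must be positive and strictly increasing")
        self.v_thresholds_gy = t


@dataclass
class CohortTable:
    """Cohort results: raw per-patient metrics and the summary table.

    ``metrics`` is long-form (patient, side, region, metric, value);
    ``summary`` has one row per (side, region, metric) with mean, sd,
    overall_p and the three pairwise p values (either floats as strings or
    the "—" skip marker).
    """

    metrics: pd.DataFrame
    summary: pd.DataFrame
    scores: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# DICOM-RT readers

def read_rtstruct(path: str | Path) -> list[ContourSet]:
    """Read a DICOM RT Structure Set into internal contour sets.

    One ContourSet per ROI, names preserved, coordinates in patient mm.
    Only CLOSED_PLANAR contours are imported; planes are grouped by their
    z coordinate.
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise to FormatError
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTSTRUCT" or "ROIContourSequence" not in ds:
        raise FormatError(f"{path} is not an RT Structure Set with contours")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: list[ContourSet] = []
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        planes: dict[float, list] = {}
        for c in getattr(roi, "ContourSequence", []):
            if getattr(c, "ContourGeometricType", "CLOSED_PLANAR") != "CLOSED_PLANAR":
                continue
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            z = round(float(pts[0, 2]), 6)
            planes.setdefault(z, []).append(pts[:, :2])
        out.append(ContourSet(
            structure_name=name,
            planes=[ContourPlane(z, polys) for z, polys in sorted(planes.items())],
        ))
    return out


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT Dose into a DoseGrid with dose in cGy.

    Dose = stored pixel values x DoseGridScaling; Gy units are converted to
    cGy. Grid geometry comes from ImagePositionPatient, PixelSpacing and
    GridFrameOffsetVector; the frame axis is inferior-superior, rows run
    anterior-posterior and columns left-right (standard head-first-supine
    orientation).
    """
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path} is not an RT Dose object")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path} has no DoseGridScaling attribute")
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if str(getattr(ds, "DoseUnits", "GY")).upper() == "GY":
        arr *= 100.0
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    # pixel_array is (frame, row, col) = (z, y, x); store as (x, y, z)
    dose = np.ascontiguousarray(arr.transpose(2, 1, 0))
    grid = Grid3D(origin=origin, spacing=(col_sp, row_sp, abs(dz)),
                  dims=dose.shape, axes=("L-R", "A-P", "I-S"))
    return DoseGrid(grid=grid, dose=dose)


# ---------------------------------------------------------------------------
# internal dose JSON

def save_dose_json(dose: DoseGrid, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "grid": dose.grid.to_dict(),
        "dose_cgy": np.round(dose.dose, 4).ravel().tolist(),
    }))


def load_dose_json(path: str | Path) -> DoseGrid:
    d = json.loads(Path(path).read_text())
    grid = Grid3D.from_dict(d["grid"])
    return DoseGrid(grid=grid, dose=np.asarray(d["dose_cgy"], dtype=float).reshape(grid.dims))


# ---------------------------------------------------------------------------
# study driver

def _patient_metrics(
    patient: PatientPhantom, config: StudyConfig
) -> list[dict]:
    """Metric rows for one patient, or raises on unusable structures."""
    rows = []
    for side_label, mask in (("HC-L", patient.left), ("HC-R", patient.right)):
        if mask.grid != patient.dose.grid:
            mask = resample_mask(mask, patient.dose.grid)
        split = split_structure(mask, config.ratios)
        region_masks = {"whole": mask, "head": split.head, "body": split.body, "tail": split.tail}
        for region, m in region_masks.items():
            b = metrics_bundle(patient.dose, m, config.v_thresholds_gy)
            vals = {"D_1%": b.d1, "D_50%": b.d50, "D_mean": b.dmean, "D_99%": b.d99}
            vals.update({f"V_{t:g}%": v for t, v in b.v_at.items()})
            for metric, value in vals.items():
                rows.append({"patient": patient.patient_id, "side": side_label,
                             "region": region, "metric": metric, "value": value})
            logger.info("patient=%s side=%s region=%s n_voxels=%d volume_cc=%.3f dmean=%.1f",
                        patient.patient_id, side_label, region, m.n_voxels,
                        mask_volume(m), b.dmean)
    return rows


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def _summarise(metrics: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Mean/SD per cell plus ANOVA and pairwise p across head/body/tail."""
    rows = []
    pair_keys = {
        "p_head_body": frozenset(("head", "body")),
        "p_head_tail": frozenset(("head", "tail")),
        "p_body_tail": frozenset(("body", "tail")),
    }
    for (side, metric), df in metrics.groupby(["side", "metric"], sort=False):
        by_region = {r: df.loc[df.region == r, "value"].to_numpy() for r in REGIONS}
        # group tests across the three sub-regions
        sub = {r: by_region[r] for r in SUBREGIONS}
        n = min(len(v) for v in sub.values())
        testable = {r: v.mean() != 0.0 for r, v in sub.items()}
        overall_p: float | str = SKIP_MARKER
        pair_p: dict[str, float | str] = {k: SKIP_MARKER for k in pair_keys}
        if n >= 2:
            if all(testable.values()):
                try:
                    _, overall_p = one_way_anova(GroupSamples(SUBREGIONS, [sub[r] for r in SUBREGIONS]))
                except Exception:  # degenerate variance
                    overall_p = SKIP_MARKER
            for col, pair in pair_keys.items():
                if all(testable[r] for r in pair):
                    try:
                        pp = pairwise_tests(
                            GroupSamples(SUBREGIONS, [sub[r] for r in SUBREGIONS]),
                            method=config.posthoc,
                        )
                        pair_p[col] = pp[pair]
                    except Exception:
                        pair_p[col] = SKIP_MARKER
        for region in REGIONS:
            mean, sd = summarize(by_region[region])
            row = {
                "side": side, "region": REGION_DISPLAY[region], "metric": metric,
                "mean": _fmt(mean), "sd": _fmt(sd) if np.isfinite(sd) else SKIP_MARKER,
            }
            if region == "whole":
                row.update({"overall_p": "", "p_head_body": "", "p_head_tail": "", "p_body_tail": ""})
            else:
                row["overall_p"] = _fmt(overall_p, 4) if isinstance(overall_p, float) else overall_p
                for col in pair_keys:
                    v = pair_p[col]
                    row[col] = _fmt(v, 4) if isinstance(v, float) else v
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> CohortTable:
    """Run the full cohort analysis and write report CSVs.

    Patients whose structures are empty or span fewer than three coronal
    layers are skipped with a logged warning; if every patient is skipped
    the run fails. Output is deterministic for a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    try:
        if config.mode == "simulate":
            cohort = make_cohort(config.n_patients, config.phantom, config.seed,
                                 with_scores=config.with_scores)
        else:
            cohort = _load_cohort_from_manifest(config)
        all_rows: list[dict] = []
        for patient in cohort:
            try:
                all_rows.extend(_patient_metrics(patient, config))
            except (EmptyStructureError, TooFewLayersError) as exc:
                logger.warning("patient=%s skipped: %s", patient.patient_id, exc)
        if not all_rows:
            raise RuntimeError("all patients were skipped; nothing to report")
        metrics = pd.DataFrame(all_rows)
        summary = _summarise(metrics, config)
        scores_df = _score_analysis(cohort, config)
        _write_reports(metrics, summary, scores_df, out, config)
        return CohortTable(metrics=metrics, summary=summary, scores=scores_df)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _load_cohort_from_manifest(config: StudyConfig) -> list[PatientPhantom]:
    if not config.manifest:
        raise ValueError("mode='files' requires a manifest CSV")
    man = pd.read_csv(config.manifest)
    cohort = []
    for _, row in man.iterrows():
        dose = load_dose_json(row["dose_path"])
        left = _load_structure(row["left_path"], dose.grid)
        right = _load_structure(row["right_path"], dose.grid)
        cohort.append(PatientPhantom(patient_id=str(row["patient_id"]),
                                     left=left, right=right, dose=dose))
    return cohort


def _load_structure(path: str, grid: Grid3D) -> StructureMask:
    d = json.loads(Path(path).read_text())
    if "voxels" in d:
        return StructureMask.from_dict(d)
    return rasterize_contours(ContourSet.from_dict(d), grid)


def _score_analysis(cohort: Sequence[PatientPhantom], config: StudyConfig) -> pd.DataFrame | None:
    if config.scores_csv:
        df = pd.read_csv(config.scores_csv)
        pairs = {c: (df[f"{c}_pre"].to_numpy(), df[f"{c}_post"].to_numpy())
                 for c in ("regular", "reverse")
                 if f"{c}_pre" in df.columns and f"{c}_post" in df.columns}
    elif cohort and cohort[0].score_pre is not None:
        pre = [p.score_pre for p in cohort]
        post = [p.score_post for p in cohort]
        pairs = {"regular": (np.asarray(pre, float), np.asarray(post, float))}
    else:
        return None
    rows = []
    for name, (pre, post) in pairs.items():
        mean_pre, sd_pre = summarize(pre)
        mean_post, sd_post = summarize(post)
        if len(pre) >= 2 and np.std(pre - post, ddof=1) > 0:
            t, p = paired_t(PairedScores(pre, post))
            t_s, p_s = _fmt(t, 4), _fmt(p, 4)
        elif len(pre) >= 2 and np.all(pre == post):
            t_s, p_s = "0.0000", "1.0000"
        else:
            t_s = p_s = SKIP_MARKER
        rows.append({"score": name, "n": len(pre),
                     "pre_mean": _fmt(mean_pre), "pre_sd": _fmt(sd_pre),
                     "post_mean": _fmt(mean_post), "post_sd": _fmt(sd_post),
                     "t": t_s, "p": p_s})
    return pd.DataFrame(rows)


def _write_reports(metrics: pd.DataFrame, summary: pd.DataFrame,
                   scores: pd.DataFrame | None, out: Path, config: StudyConfig) -> None:
    metrics_out = metrics.copy()
    metrics_out["value"] = metrics_out["value"].map(lambda v: f"{v:.4f}")
    metrics_out.to_csv(out / "metrics_long.csv", index=False)

    # Table 1: whole-structure D metrics, one row per side
    t1 = summary[(summary.region == "HC") & summary.metric.isin(D_METRICS)]
    tab1 = t1.pivot(index="side", columns="metric", values=["mean", "sd"])
    rows1 = []
    for side in SIDES:
        if side not in tab1.index:
            continue
        row = {"Position": side}
        for m in D_METRICS:
            row[m] = f"{tab1.loc[side, ('mean', m)]} ± {tab1.loc[side, ('sd', m)]}"
        rows1.append(row)
    pd.DataFrame(rows1).to_csv(out / "table1_whole_hc.csv", index=False)

    sub = summary[summary.region.isin(("HH", "HB", "HT"))]
    sub[~sub.metric.str.startswith("V_")].to_csv(out / "table2_d_metrics.csv", index=False)
    sub[sub.metric.str.startswith("V_")].to_csv(out / "table3_v_metrics.csv", index=False)
    if scores is not None:
        scores.to_csv(out / "scores_paired.csv", index=False)
    logger.info("reports written to %s", out)
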