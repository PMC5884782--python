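"""Synthetic cohort generator: hippocampus-like structures and dose fields.

The phantom emulates the dosimetric situation of nasopharyngeal-carcinoma
radiotherapy without hippocampal sparing: each patient carries bilateral
hippocampus-like curved tubes running anterior-inferior to
posterior-superior, mirrored across the sagittal midplane, and a dose field
peaked at a nasopharynx-like point anterior-inferior-medial to them that
decays exponentially with distance. Because the source sits anterior to the
structures, mean dose decreases monotonically from head to body to tail —
the ordering the analysis is designed to detect. Patient-to-patient
variation enters as a multiplicative lognormal jitter on the whole field,
emulating anatomy- and plan-driven spread.

Optional paired memory scores (digit-span style, integers clipped to
[0, 17]) model a small pre/post cognitive decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .dvh import DoseGrid
from .structures import DEFAULT_AXES, Grid3D, StructureMask

Side = Literal["left", "right"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and dose parameters of the synthetic cohort.

    Defaults place the structures and source so that hippocampal mean doses
    land in the ~500-3000 cGy range reported for this treatment site, with
    head > body > tail for every patient.

    Parameters
    ----------
    grid_dims, grid_spacing_mm : lattice of the dose grid (default 80x80x60
        voxels at 2 mm isotropic -> a 160x160x120 mm head-and-neck volume).
    hc_length_mm : arc length of each hippocampus-like tube (default 35 mm,
        a typical adult hippocampal extent).
    hc_radius_mm : tube radius (default 5 mm).
    curvature_mm : sagittal bowing of the tube's central curve (default 6 mm).
    lateral_offset_mm : distance of each tube from the midline (default 14 mm).
    source_point_mm : nasopharynx-like dose peak, anterior-inferior-medial to
        the structures (default midline, 22 mm anterior and 24 mm inferior to
        the hippocampal head).
    d0_cgy : peak dose at the source (default 7040, the prescription dose of
        the primary target, 7040 cGy / 32 fractions).
    falloff_mm : exponential dose falloff length lambda (default 25 mm).
    jitter_sd : SD of the per-patient lognormal dose multiplier (default 0.2).
    score_mu_pre, score_delta, score_noise_sd : paired-score model
        (pre ~ N(mu, sd^2), post = pre - delta + noise), defaults emulating a
        regular-order digit-span decline of 0.6 points.
    """

    grid_dims: tuple[int, int, int] = (80, 80, 60)
    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hc_length_mm: float = 35.0
    hc_radius_mm: float = 5.0
    curvature_mm: float = 6.0
    lateral_offset_mm: float = 14.0
    source_point_mm: tuple[float, float, float] = (80.0, 38.0, 26.0)
    d0_cgy: float = 7040.0
    falloff_mm: float = 25.0
    jitter_sd: float = 0.2
    score_mu_pre: float = 8.6
    score_pre_sd: float = 1.3
    score_delta: float = 0.6
    score_noise_sd: float = 1.0

    def __post_init__(self):
        if any(d < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        for name in ("hc_length_mm", "hc_radius_mm", "d0_cgy", "falloff_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def grid(self) -> Grid3D:
        return Grid3D(origin=(1.0, 1.0, 1.0), spacing=self.grid_spacing_mm,
                      dims=self.grid_dims, axes=DEFAULT_AXES)

    @property
    def midline_x_mm(self) -> float:
        g = self.grid()
        return g.origin[0] + g.spacing[0] * (g.dims[0] - 1) / 2.0


@dataclass
class PatientPhantom:
    """One synthetic patient: bilateral structures, dose, optional scores."""

    patient_id: str
    left: StructureMask
    right: StructureMask
    dose: DoseGrid
    score_pre: int | None = None
    score_post: int | None = None


def _central_curve(config: PhantomConfig, side: Side, n_samples: int = 80) -> np.ndarray:
    """Sampled centreline of one hippocampus-like tube (patient mm).

    Runs anterior-inferior -> posterior-superior with a lateral bow of
    ``curvature_mm``; the two sides are exact mirrors across the midline.
    """
    g = config.grid()
    extent = [g.origin[a] + g.spacing[a] * (g.dims[a] - 1) for a in range(3)]
    # anterior (low y) / inferior (low z) start, centred in the volume
    y0 = 0.38 * extent[1]
    z0 = 0.42 * extent[2]
    # direction in the y-z plane: posterior and superior components
    dy, dz = 0.85, 0.527  # unit vector, atan2(dz, dy) ~ 31.8 deg climb
    t = np.linspace(0.0, config.hc_length_mm, n_samples)
    y = y0 + dy * t
    z = z0 + dz * t
    sign = -1.0 if side == "left" else 1.0
    x_off = config.lateral_offset_mm + config.curvature_mm * np.sin(np.pi * t / t[-1])
    x = config.midline_x_mm + sign * x_off
    return np.column_stack([x, y, z])


def make_hippocampus(config: PhantomConfig, side: Side) -> StructureMask:
    """Voxelize one hippocampus-like curved tube.

    A voxel is occupied when its centre lies within ``hc_radius_mm`` of the
    sampled centreline. Construction is deterministic; the left and right
    masks are mirror images (equal volumes) on the midline-symmetric grid.
    """
    g = config.grid()
    curve = _central_curve(config, side)
    lo = curve.min(axis=0) - config.hc_radius_mm
    hi = curve.max(axis=0) + config.hc_radius_mm
    for a in range(3):
        if lo[a] < g.origin[a] - g.spacing[a] / 2 or \
           hi[a] > g.origin[a] + g.spacing[a] * (g.dims[a] - 1) + g.spacing[a] / 2:
            raise ValueError("hippocampus phantom exceeds the grid; enlarge grid_dims")
    xs, ys, zs = (g.axis_centers(a) for a in range(3))
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(curve).query(pts, workers=-1)
    occ = (dist <= config.hc_radius_mm).reshape(g.dims)
    name = "HC-L" if side == "left" else "HC-R"
    return StructureMask(grid=g, occupancy=occ, structure_name=name)


def make_dose_field(config: PhantomConfig, rng: np.random.Generator | int | None = None) -> DoseGrid:
    """Exponentially decaying dose field peaked at the nasopharynx-like point.

    ``dose(v) = d0 * j * exp(-||v - source|| / lambda)`` with one lognormal
    patient-level multiplier ``j`` (median 1) drawn from ``rng``; pass
    ``rng=None`` for j = 1.
    """
    g = config.grid()
    xs, ys, zs = (g.axis_centers(a) for a in range(3))
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    sx, sy, sz = config.source_point_mm
    r = np.sqrt((xx - sx) ** 2 + (yy - sy) ** 2 + (zz - sz) ** 2)
    if rng is None:
        j = 1.0
    else:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        j = float(rng.lognormal(mean=0.0, sigma=config.jitter_sd))
    return DoseGrid(grid=g, dose=config.d0_cgy * j * np.exp(-r / config.falloff_mm))


def make_cohort(
    n_patients: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
    with_scores: bool = False,
) -> list[PatientPhantom]:
    """Generate a reproducible synthetic cohort.

    Per-patient random streams are spawned from the master ``seed``, so the
    cohort is byte-identical across runs with the same arguments. When
    ``with_scores`` is set, paired digit-span-style scores are drawn
    (integers clipped to [0, 17]) with a mean post-treatment decline of
    ``config.score_delta``.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if config is None:
        config = PhantomConfig()
    left = make_hippocampus(config, "left")
    right = make_hippocampus(config, "right")
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        dose = make_dose_field(config, rng)
        pre = post = None
        if with_scores:
            raw_pre = rng.normal(config.score_mu_pre, config.score_pre_sd)
            raw_post = raw_pre - config.score_delta + rng.normal(0.0, config.score_noise_sd)
            pre = int(np.clip(round(raw_pre), 0, 17))
            post = int(np.clip(round(raw_post), 0, 17))
        cohort.append(PatientPhantom(
            patient_id=f"P{i + 1:02d}", left=left, right=right, dose=dose,
            score_pre=pre, score_post=post,
        ))
    return cohort
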