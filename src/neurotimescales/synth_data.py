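"""Synthetic resting-state cohorts with known AR(1) timescale ground truth.

Each voxel's BOLD series is a stationary, unit-variance Gaussian AR(1)
process with lag-1 coefficient ``phi``; its theoretical ACF is ``phi**k``,
so the population INT is available in closed form,

    INT(phi) = tr * phi * (1 - phi**K) / (1 - phi),

where K is the number of lags in the estimation window.  This is exactly
the structure the positive-ACF-sum estimator assumes, which makes the
generator a ground-truth oracle for parameter-recovery tests: the
``phi`` field is known per voxel, per-subject heterogeneity is a scalar
``phi`` offset, and group effects are ``phi`` decrements confined to
designated ROI spheres.

Phenotypes (age, sex, IQ, FD targets, ADOS, PANSS) are drawn from group
marginal distributions matching a three-group (TD / ASD / SZ) case-control
design, and 6-parameter motion traces are random walks tuned to a target
mean framewise displacement.  Only marginal structure is emulated: no
physiological noise, scanner drift, spatial smoothness, or covariance
between phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .int_core import TimeSeries, Volume4D
from .qc_motion import MotionTrace, framewise_displacement
from .roi_spheres import RoiSpec, load_roi_table, sphere_mask

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "closed_form_int",
    "phi_from_int",
    "simulate_cohort",
    "simulate_voxel_series",
]

#: Group marginal phenotype distributions: mean/sd for continuous scores,
#: female fraction for sex.  PANSS subscales apply to the clinical groups.
DEFAULT_COVARIATE_PARAMS: Dict[str, dict] = {
    "TD": {
        "age": (24.0, 3.73), "iq": (112.26, 14.62), "fd": (0.08, 0.03),
        "ados_total": (1.87, 1.45), "female_fraction": 29 / 55,
    },
    "ASD": {
        "age": (22.0, 3.74), "iq": (109.1, 15.21), "fd": (0.09, 0.04),
        "ados_total": (10.1, 2.61), "female_fraction": 5 / 30,
        "panss_pos": (12.1, 2.86), "panss_neg": (15.57, 4.7),
        "panss_gen": (26.7, 5.62),
    },
    "SZ": {
        "age": (26.0, 3.58), "iq": (99.41, 13.34), "fd": (0.11, 0.1),
        "ados_total": (8.41, 5.26), "female_fraction": 8 / 39,
        "panss_pos": (15.36, 4.86), "panss_neg": (19.26, 6.2),
        "panss_gen": (31.59, 6.98),
    },
}

GROUPS = ("TD", "ASD", "SZ")

# per-ROI phi decrement applied to SZ subjects inside two designated
# spheres; the value is calibrated by simulation to yield a Hedges g of
# roughly 0.6 on estimated ROI INT at the default sample sizes
DEFAULT_GROUP_EFFECT: Dict[str, Dict[str, float]] = {
    "SZ": {"U_lLatOccC": 0.035, "U_rPostCenG": 0.035},
}


def closed_form_int(phi: float, tr: float, max_lag_samples: int) -> float:
    """Population INT of a stationary AR(1) process under the
    positive-ACF-sum estimator window: tr * phi * (1 - phi**K) / (1 - phi).
    """
    phi = float(phi)
    if phi == 0.0:
        return 0.0
    if phi == 1.0:
        return tr * max_lag_samples
    return tr * phi * (1.0 - phi**max_lag_samples) / (1.0 - phi)


def phi_from_int(target_int: float, tr: float, max_lag_samples: int) -> float:
    """Invert :func:`closed_form_int` for phi in [0, 1) by monotone
    root-finding (tolerance 1e-10)."""
    upper = closed_form_int(1.0 - 1e-12, tr, max_lag_samples)
    if not (0.0 <= target_int < tr * max_lag_samples):
        raise ValueError(
            f"target INT {target_int} outside achievable range "
            f"[0, {tr * max_lag_samples})"
        )
    if target_int == 0.0:
        return 0.0
    if target_int >= upper:
        return 1.0 - 1e-12
    return float(
        brentq(
            lambda p: closed_form_int(p, tr, max_lag_samples) - target_int,
            0.0, 1.0 - 1e-12, xtol=1e-10,
        )
    )


def _ar1_matrix(phi: np.ndarray, n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) draws: returns (n_volumes, V)."""
    phi = np.asarray(phi, dtype=float)
    V = phi.size
    x = np.empty((n_volumes, V))
    innov_sd = np.sqrt(1.0 - phi**2)
    x[0] = rng.standard_normal(V)
    eps = rng.standard_normal((n_volumes - 1, V))
    for t in range(1, n_volumes):
        x[t] = phi * x[t - 1] + innov_sd * eps[t - 1]
    return x


def simulate_voxel_series(
    phi: float, n_volumes: int, seed, tr: float = 0.475
) -> TimeSeries:
    """One stationary AR(1) voxel series with unit marginal variance.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical
    seeds give identical series.
    """
    if not (0.0 <= phi < 1.0):
        raise ValueError(f"phi must lie in [0, 1), got {phi}")
    if n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    rng = np.random.default_rng(seed)
    values = _ar1_matrix(np.array([phi]), n_volumes, rng)[:, 0]
    return TimeSeries(values=values, tr=tr)


def _grid_covering_rois(
    rois: Sequence[RoiSpec], voxel_mm: float = 3.0, pad_mm: float = 9.0
) -> tuple:
    """Axis-aligned voxel grid (shape, affine) containing every sphere."""
    centers = np.array([r.center for r in rois])
    radii = np.array([r.radius for r in rois])
    lo = (centers - radii[:, None]).min(axis=0) - pad_mm
    hi = (centers + radii[:, None]).max(axis=0) + pad_mm
    shape = tuple(int(np.ceil((h - l) / voxel_mm)) + 1 for l, h in zip(lo, hi))
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    affine[:3, 3] = lo
    return shape, affine


@dataclass
class CohortConfig:
    """Everything needed to draw one synthetic cohort.

    Defaults mirror the target study design: group sizes (55, 30, 39),
    TR 0.475 s, 947 volumes (7.5 min of scanning), a posterior-to-anterior
    increasing ``phi`` gradient, and an SZ-specific ``phi`` decrement inside
    the two designated ROI spheres.  ``phi_gradient`` maps world y (mm)
    linearly onto [phi_low, phi_high]; an explicit ``phi_field`` array
    overrides it.  ``mask_mode`` chooses which voxels carry simulated
    signal: ``"rois"`` (union of the spheres; compact and fast) or
    ``"full"`` (every voxel of the grid).
    """

    n_per_group: Tuple[int, int, int] = (55, 30, 39)
    tr: float = 0.475
    n_volumes: int = 947
    max_lag_seconds: float = 20.0
    grid_shape: Optional[Tuple[int, int, int]] = None
    affine: Optional[np.ndarray] = None
    phi_gradient: Tuple[float, float] = (0.55, 0.85)  # posterior -> anterior
    phi_field: Optional[np.ndarray] = None
    phi_subject_sd: float = 0.05
    phi_max: float = 0.95
    group_effect: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_GROUP_EFFECT.items()}
    )
    covariate_params: Dict[str, dict] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_COVARIATE_PARAMS.items()}
    )
    rois: Optional[Sequence[RoiSpec]] = None
    mask_mode: str = "rois"
    n_high_motion_per_group: Tuple[int, int, int] = (0, 0, 0)
    high_motion_translation_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rois is None:
            self.rois = load_roi_table()
        if self.grid_shape is None or self.affine is None:
            shape, affine = _grid_covering_rois(self.rois)
            self.grid_shape = shape if self.grid_shape is None else self.grid_shape
            self.affine = affine if self.affine is None else self.affine
        self.affine = np.asarray(self.affine, dtype=float)
        if self.n_volumes < 3:
            raise ValueError("n_volumes must be >= 3")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mask_mode not in ("rois", "full"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")
        lo, hi = self.phi_gradient
        if not (0.0 <= lo < 1.0 and 0.0 <= hi < 1.0):
            raise ValueError("phi_gradient endpoints must lie in [0, 1)")
        if self.phi_field is not None:
            f = np.asarray(self.phi_field, dtype=float)
            if f.shape != tuple(self.grid_shape):
                raise ValueError("phi_field shape must match grid_shape")
            if np.any(f < 0) or np.any(f >= 1):
                raise ValueError("phi_field values must lie in [0, 1)")
            self.phi_field = f
        if not (0.0 < self.phi_max < 1.0):
            raise ValueError("phi_max must lie in (0, 1)")
        if len(self.n_per_group) != 3 or any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group must be three positive counts")

    @property
    def max_lag_samples(self) -> int:
        return int(np.floor(self.max_lag_seconds / self.tr))


@dataclass
class GroundTruth:
    """Per-voxel and per-subject ground truth of a synthetic cohort."""

    phi_base: np.ndarray            # group-independent phi field
    group_phi: Dict[str, np.ndarray]  # phi field after group decrements
    subject_delta: np.ndarray       # per-subject scalar phi offset
    mask: np.ndarray
    affine: np.ndarray
    tr: float
    max_lag_samples: int

    def subject_phi_field(self, groups: Sequence[str], i: int) -> np.ndarray:
        base = self.group_phi[groups[i]]
        return np.clip(base + self.subject_delta[i], 0.0, None)

    def int_field(self, group: str) -> np.ndarray:
        """Population INT field for a group (NaN outside the mask)."""
        phi = self.group_phi[group]
        out = np.full(phi.shape, np.nan)
        p = phi[self.mask]
        out[self.mask] = self.tr * p * (1 - p**self.max_lag_samples) / (1 - p)
        return out

    def roi_int(self, roi_masks, group: str) -> pd.Series:
        f = self.int_field(group)
        return pd.Series(
            {rm.roi.name: float(np.nanmean(f[rm.mask])) for rm in roi_masks}
        )


def _seed_for(master: int, stream: int, index: int = 0) -> np.random.SeedSequence:
    # counter-based splitting: subject i reproducible independently of
    # cohort size or generation order
    return np.random.SeedSequence(entropy=int(master), spawn_key=(stream, index))


_STREAM_PHENO, _STREAM_MOTION, _STREAM_BOLD, _STREAM_DELTA = 0, 1, 2, 3


@dataclass
class SyntheticCohort:
    """A drawn cohort: phenotypes, motion, lazy BOLD volumes, ground truth.

    BOLD volumes are generated on demand through :meth:`volume` so large
    cohorts never hold more than one subject's 4D array in memory.
    """

    config: CohortConfig
    records: pd.DataFrame
    motion: list
    truth: GroundTruth
    roi_masks: list

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    @property
    def mask(self) -> np.ndarray:
        return self.truth.mask

    def subject_phi(self, i: int) -> np.ndarray:
        groups = self.records["group"].tolist()
        return self.truth.subject_phi_field(groups, i)

    def masked_series(self, i: int) -> np.ndarray:
        """Subject ``i``'s BOLD series for in-mask voxels only: (T, V) with
        one column per mask voxel in C-order (deterministic per seed)."""
        cfg = self.config
        phi = self.subject_phi(i)[self.truth.mask]
        phi = np.clip(phi, 0.0, cfg.phi_max)
        rng = np.random.default_rng(_seed_for(cfg.seed, _STREAM_BOLD, i))
        return _ar1_matrix(phi, cfg.n_volumes, rng)

    def volume(self, i: int) -> Volume4D:
        """Subject ``i``'s full 4D BOLD volume (deterministic per seed).

        Voxels outside the simulation mask carry no defined signal; this
        materializes the whole grid, so prefer :meth:`masked_series` for
        large in-memory cohorts.
        """
        cfg = self.config
        series = self.masked_series(i)
        data = np.zeros((*cfg.grid_shape, cfg.n_volumes), dtype=np.float32)
        data[self.truth.mask] = series.T.astype(np.float32)
        return Volume4D(data=data, affine=cfg.affine, tr=cfg.tr)

    def volumes(self) -> list:
        return [self.volume(i) for i in range(self.n_subjects)]


def _draw_phenotypes(cfg: CohortConfig) -> pd.DataFrame:
    # one rng per subject (counter-based split) so subject i's phenotypes
    # do not depend on cohort size; sex hits the configured female count
    # exactly via a deterministic even-spread rule
    rows = []
    idx = 0
    for group, n in zip(GROUPS, cfg.n_per_group):
        params = cfg.covariate_params[group]
        n_f = int(round(params["female_fraction"] * n))
        for j in range(n):
            rng = np.random.default_rng(_seed_for(cfg.seed, _STREAM_PHENO, idx))
            female = (j + 1) * n_f // n > j * n_f // n
            row = {
                "subject_id": f"sub-{idx:03d}",
                "group": group,
                "age": rng.normal(*params["age"]),
                "sex": "F" if female else "M",
                "iq": rng.normal(*params["iq"]),
                "ados_total": max(rng.normal(*params["ados_total"]), 0.0),
                "fd_target": max(rng.normal(*params["fd"]), 0.005),
            }
            for key in ("panss_pos", "panss_neg", "panss_gen"):
                row[key] = (
                    max(rng.normal(*params[key]), 0.0) if key in params else np.nan
                )
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def _simulate_motion(
    cfg: CohortConfig, i: int, fd_target: float, high_motion: bool
) -> MotionTrace:
    """Random-walk motion trace whose expected mean FD matches the target.

    Translation steps contribute ~70% of FD and rotations ~30%; a
    high-motion subject additionally gets one translation excursion past
    the exclusion threshold.
    """
    rng = np.random.default_rng(_seed_for(cfg.seed, _STREAM_MOTION, i))
    T = cfg.n_volumes
    c = np.sqrt(2.0 / np.pi)  # E|N(0, s^2)| = c * s
    sd_t = 0.7 * fd_target / (3.0 * c)
    sd_r = 0.3 * fd_target / (3.0 * c * 50.0)
    translations = np.cumsum(
        np.vstack([np.zeros(3), rng.normal(0, sd_t, (T - 1, 3))]), axis=0
    )
    rotations = np.cumsum(
        np.vstack([np.zeros(3), rng.normal(0, sd_r, (T - 1, 3))]), axis=0
    )
    if high_motion:
        t0 = int(rng.integers(T // 4, 3 * T // 4))
        translations[t0:, 0] += cfg.high_motion_translation_mm
    return MotionTrace(translations=translations, rotations=rotations)


def _phi_base_field(cfg: CohortConfig) -> np.ndarray:
    if cfg.phi_field is not None:
        return cfg.phi_field
    # linear in world y: posterior (low y) -> anterior (high y)
    jj = np.arange(cfg.grid_shape[1])
    y_mm = cfg.affine[1, 1] * jj + cfg.affine[1, 3]
    lo, hi = cfg.phi_gradient
    span = y_mm.max() - y_mm.min()
    frac = (y_mm - y_mm.min()) / span if span > 0 else np.zeros_like(y_mm)
    phi_y = lo + (hi - lo) * frac
    return np.broadcast_to(
        phi_y[None, :, None], cfg.grid_shape
    ).copy()


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config``.

    Returns phenotype records (including realized mean FD), motion traces,
    the ground-truth phi fields (base, per group, per subject), ROI masks
    on the cohort grid, and lazy access to each subject's 4D BOLD volume.
    Identical configs (including seed) give bit-identical cohorts.
    """
    cfg = config
    roi_masks = [sphere_mask(r, cfg.affine, cfg.grid_shape) for r in cfg.rois]
    for rm in roi_masks:
        if rm.empty:
            raise ValueError(f"ROI sphere {rm.roi.name} lies outside the grid")
    if cfg.mask_mode == "rois":
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        for rm in roi_masks:
            mask |= rm.mask
    else:
        mask = np.ones(cfg.grid_shape, dtype=bool)

    phi_base = _phi_base_field(cfg)
    group_phi = {}
    roi_mask_by_name = {rm.roi.name: rm.mask for rm in roi_masks}
    for group in GROUPS:
        f = phi_base.copy()
        for roi_name, dec in cfg.group_effect.get(group, {}).items():
            if roi_name not in roi_mask_by_name:
                raise ValueError(f"group_effect names unknown ROI {roi_name!r}")
            f[roi_mask_by_name[roi_name]] -= dec
        group_phi[group] = np.clip(f, 0.0, cfg.phi_max)

    records = _draw_phenotypes(cfg)
    n_total = len(records)
    delta_rng = np.random.default_rng(_seed_for(cfg.seed, _STREAM_DELTA))
    subject_delta = delta_rng.normal(0.0, cfg.phi_subject_sd, n_total)

    high = np.zeros(n_total, dtype=bool)
    offset = 0
    for (g, n), nh in zip(zip(GROUPS, cfg.n_per_group), cfg.n_high_motion_per_group):
        high[offset:offset + nh] = True
        offset += n
    motion = [
        _simulate_motion(cfg, i, records.loc[i, "fd_target"], bool(high[i]))
        for i in range(n_total)
    ]
    records["fd_mean"] = [
        float(framewise_displacement(m).mean()) for m in motion
    ]
    records = records.drop(columns=["fd_target"])

    truth = GroundTruth(
        phi_base=phi_base,
        group_phi=group_phi,
        subject_delta=subject_delta,
        mask=mask,
        affine=cfg.affine,
        tr=cfg.tr,
        max_lag_samples=cfg.max_lag_samples,
    )
    return SyntheticCohort(
        config=cfg, records=records, motion=motion, truth=truth, roi_masks=roi_masks
    )
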