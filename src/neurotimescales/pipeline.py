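"""End-to-end orchestration: estimate INT maps, extract sphere ROIs, run
the group statistics, and write a stable output bundle.

The bundle layout is::

    outdir/
      maps/      per-subject INT maps and optional voxelwise stat maps (NIfTI)
      tables/    ROI INT table, ANCOVA table, pairwise tables,
                 correlation grids, cluster table (TSV)
      qc/        exclusion decisions and per-subject QC (JSON + TSV)
      manifest.json   versions, config hash, QC counts

``make_fixture`` materializes a synthetic cohort to disk in exactly the
formats the pipeline reads, together with a ready-to-run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __name__ as _pkg_name
from .int_core import IntMap, Volume4D, int_map, load_volume, save_int_map
from .qc_motion import MotionTrace, exclusion_flags, read_motion_file
from .roi_spheres import RoiMask, extract_roi_values, load_roi_table, sphere_mask
from .stats_suite import (
    bh_fdr,
    ancova_group_effect,
    hedges_g_from_samples,
    spearman_grid,
    voxelwise_group_maps,
    welch_t_from_samples,
)
from .synth_data import CohortConfig, SyntheticCohort, simulate_cohort

__all__ = [
    "RunConfig",
    "analyze_cohort",
    "analyze_subjects",
    "ancova_table",
    "correlation_grids",
    "make_fixture",
    "pairwise_tables",
    "run_replication",
]

logger = logging.getLogger(__name__)

GROUP_PAIRS = (("TD", "ASD"), ("TD", "SZ"), ("ASD", "SZ"))
CLINICAL_MEASURES = ("ados_total", "panss_pos", "panss_neg", "panss_gen")
COVARIATES = ("age", "sex", "iq", "fd_mean")


@dataclass
class RunConfig:
    """Configuration of one full replication run.

    ``manifest`` maps subject_id to ``{"bold": path, "motion": path}``;
    ``phenotypes`` is a TSV with one row per subject.  ``roi_table`` is
    ``"packaged"`` for the built-in 13-sphere table or a TSV path.
    """

    manifest: Dict[str, dict]
    phenotypes: Union[str, Path]
    outdir: Union[str, Path]
    roi_table: str = "packaged"
    tr_override: Optional[float] = None
    max_lag_seconds: float = 20.0
    include_lag_zero: bool = False
    one_tailed_convention: str = "one_sided_first_larger"
    motion_threshold_mm: float = 10.0
    brain_mask: Optional[Union[str, Path]] = None
    write_maps: bool = True
    voxelwise: bool = False
    voxelwise_threshold_p: float = 0.001
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phenotypes"] = str(d["phenotypes"])
        d["outdir"] = str(d["outdir"])
        if d["brain_mask"] is not None:
            d["brain_mask"] = str(d["brain_mask"])
        return d


def _config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_roi_masks(rois, affine, shape) -> list:
    return [sphere_mask(r, affine, shape) for r in rois]


def analyze_subjects(
    subjects: Iterable[Tuple[str, Volume4D, Optional[MotionTrace]]],
    roi_masks: Sequence[RoiMask],
    max_lag_seconds: float = 20.0,
    include_lag_zero: bool = False,
    motion_threshold_mm: float = 10.0,
    brain_mask: Optional[np.ndarray] = None,
    keep_maps: bool = False,
    map_sink=None,
) -> tuple:
    """Per-subject stage: QC, INT estimation, ROI extraction.

    ``subjects`` yields ``(subject_id, Volume4D, MotionTrace or None)``
    one at a time, so arbitrarily large cohorts run in bounded memory.
    When ``brain_mask`` is None the union of the ROI masks is analyzed.
    Returns ``(roi_table, qc_table, int_maps)``: the subjects x ROIs INT
    table, a per-subject QC frame (mean FD, exclusion flag, degenerate and
    window-capped voxel counts), and the per-subject maps if ``keep_maps``
    (``map_sink(subject_id, IntMap)`` may stream them out instead).
    """
    if brain_mask is None:
        brain_mask = np.zeros(roi_masks[0].mask.shape, dtype=bool)
        for rm in roi_masks:
            brain_mask |= rm.mask
    rows, qc_rows, maps = {}, [], {}
    for subject_id, volume, motion in subjects:
        excluded, fd_mean = (False, np.nan)
        if motion is not None:
            excluded, fd_mean = exclusion_flags(motion, motion_threshold_mm)
        if excluded:
            logger.info("subject %s excluded for head motion", subject_id)
            qc_rows.append(
                {"subject_id": subject_id, "fd_mean": fd_mean, "excluded": True,
                 "n_degenerate": np.nan, "n_window_capped": np.nan}
            )
            continue
        imap = int_map(
            volume, brain_mask, max_lag_seconds=max_lag_seconds,
            include_lag_zero=include_lag_zero,
        )
        rows[subject_id] = extract_roi_values(imap, roi_masks)
        qc_rows.append(
            {"subject_id": subject_id, "fd_mean": fd_mean, "excluded": False,
             "n_degenerate": imap.qc["n_degenerate"],
             "n_window_capped": imap.qc["n_window_capped"]}
        )
        if keep_maps:
            maps[subject_id] = imap
        if map_sink is not None:
            map_sink(subject_id, imap)
        logger.info("subject %s: INT estimated over %d voxels",
                    subject_id, imap.qc["n_in_mask"])
    roi_table = pd.DataFrame(rows).T
    roi_table.index.name = "subject_id"
    qc_table = pd.DataFrame(qc_rows)
    return roi_table, qc_table, maps


def analyze_cohort(
    cohort: SyntheticCohort,
    max_lag_seconds: Optional[float] = None,
    include_lag_zero: bool = False,
    keep_maps: bool = False,
) -> tuple:
    """In-memory analogue of :func:`analyze_subjects` for a synthetic
    cohort: estimates each subject's INT over the cohort's simulation mask
    without materializing 4-D arrays.  Returns ``(roi_table, qc_table,
    int_maps)`` identical to streaming the full volumes through
    :func:`analyze_subjects`."""
    from .int_core import int_map_from_series

    cfg = cohort.config
    if max_lag_seconds is None:
        max_lag_seconds = cfg.max_lag_seconds
    rows, qc_rows, maps = {}, [], {}
    for i in range(cohort.n_subjects):
        sid = cohort.records.loc[i, "subject_id"]
        excluded, fd_mean = exclusion_flags(cohort.motion[i])
        if excluded:
            qc_rows.append(
                {"subject_id": sid, "fd_mean": fd_mean, "excluded": True,
                 "n_degenerate": np.nan, "n_window_capped": np.nan}
            )
            continue
        imap = int_map_from_series(
            cohort.masked_series(i), cohort.mask, cfg.affine, cfg.tr,
            max_lag_seconds=max_lag_seconds, include_lag_zero=include_lag_zero,
        )
        rows[sid] = extract_roi_values(imap, cohort.roi_masks)
        qc_rows.append(
            {"subject_id": sid, "fd_mean": fd_mean, "excluded": False,
             "n_degenerate": imap.qc["n_degenerate"],
             "n_window_capped": imap.qc["n_window_capped"]}
        )
        if keep_maps:
            maps[sid] = imap
    roi_table = pd.DataFrame(rows).T
    roi_table.index.name = "subject_id"
    return roi_table, pd.DataFrame(qc_rows), maps


def ancova_table(
    roi_table: pd.DataFrame,
    records: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
) -> pd.DataFrame:
    """Group-effect ANCOVA per ROI with a single BH-FDR family across ROIs.

    Output mirrors the published layout: per-group mean (sd) of ROI INT,
    the group F with its dfs, uncorrected and FDR p, partial eta squared.
    """
    recs = records.set_index("subject_id").loc[roi_table.index]
    rows = []
    for roi in roi_table.columns:
        res = ancova_group_effect(
            roi_table[roi].to_numpy(), recs, covariates=covariates, label=roi
        )
        row = {"roi": roi}
        for g in ("TD", "ASD", "SZ"):
            vals = roi_table[roi][(recs["group"] == g).to_numpy()]
            row[f"mean_{g}"] = vals.mean()
            row[f"sd_{g}"] = vals.std(ddof=1)
        row.update(
            F=res.statistic, df1=res.df[0], df2=res.df[1],
            p_unc=res.p_unc, eta_p2=res.effect,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_unc"].to_numpy())
    return out


def pairwise_tables(
    roi_table: pd.DataFrame,
    records: pd.DataFrame,
    tail: str = "one_sided_first_larger",
    pairs: Sequence[Tuple[str, str]] = GROUP_PAIRS,
) -> Dict[str, pd.DataFrame]:
    """One-tailed Welch tests with Hedges g per ROI for each group pair.

    The first-listed group of each pair is hypothesized larger (default
    convention); FDR is applied per pair across the ROI family.
    """
    recs = records.set_index("subject_id").loc[roi_table.index]
    out = {}
    for g1, g2 in pairs:
        rows = []
        for roi in roi_table.columns:
            x1 = roi_table[roi][(recs["group"] == g1).to_numpy()].to_numpy()
            x2 = roi_table[roi][(recs["group"] == g2).to_numpy()].to_numpy()
            t, df, p = welch_t_from_samples(x1, x2, tail=tail)
            rows.append(
                {"roi": roi, "t": t, "df": df, "p_unc": p,
                 "g": hedges_g_from_samples(x1, x2)}
            )
        table = pd.DataFrame(rows)
        table["p_fdr"] = bh_fdr(table["p_unc"].to_numpy())
        out[f"{g1}_v_{g2}"] = table[["roi", "t", "df", "p_unc", "p_fdr", "g"]]
    return out


def correlation_grids(
    roi_table: pd.DataFrame,
    records: pd.DataFrame,
    measures: Sequence[str] = CLINICAL_MEASURES,
    groups: Sequence[str] = ("ASD", "SZ"),
) -> pd.DataFrame:
    """Spearman ROI-by-clinical-measure grids for the clinical groups,
    FDR-corrected within each group's grid."""
    recs = records.set_index("subject_id").loc[roi_table.index]
    sel = recs["group"].isin(groups).to_numpy()
    clinical = recs.loc[sel, [m for m in measures if m in recs.columns]]
    return spearman_grid(
        roi_table[sel], clinical, groups=recs.loc[sel, "group"]
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_replication(config: RunConfig) -> dict:
    """Run the full pipeline from files on disk and write the bundle.

    Subjects missing any covariate value are dropped with a logged reason.
    Returns a summary dict with the output paths and QC counts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    for sub in ("maps", "tables", "qc"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    records = pd.read_csv(config.phenotypes, sep="\t")
    missing_subjects = [s for s in config.manifest if s not in set(records["subject_id"])]
    if missing_subjects:
        raise ValueError(f"subjects absent from phenotype table: {missing_subjects}")

    rois = (
        load_roi_table()
        if config.roi_table == "packaged"
        else load_roi_table(config.roi_table)
    )

    first = next(iter(config.manifest.values()))
    probe = load_volume(first["bold"], tr_override=config.tr_override)
    roi_masks = build_roi_masks(rois, probe.affine, probe.spatial_shape)
    brain_mask = None
    if config.brain_mask is not None:
        brain_mask = np.asarray(
            nib.load(str(config.brain_mask)).get_fdata() > 0, dtype=bool
        )

    def subject_stream():
        for sid, paths in config.manifest.items():
            vol = load_volume(paths["bold"], tr_override=config.tr_override)
            motion = (
                read_motion_file(paths["motion"]) if paths.get("motion") else None
            )
            yield sid, vol, motion

    def map_sink(sid: str, imap: IntMap) -> None:
        if config.write_maps:
            save_int_map(imap, outdir / "maps" / f"{sid}_int.nii.gz")

    roi_table, qc_table, _ = analyze_subjects(
        subject_stream(), roi_masks,
        max_lag_seconds=config.max_lag_seconds,
        include_lag_zero=config.include_lag_zero,
        motion_threshold_mm=config.motion_threshold_mm,
        brain_mask=brain_mask,
        map_sink=map_sink,
    )

    # drop subjects with incomplete covariates, mirroring exclusion of
    # incomplete phenotypic assessment
    recs = records.set_index("subject_id").loc[roi_table.index].reset_index()
    complete = recs[list(COVARIATES) + ["group"]].notna().all(axis=1)
    for sid in recs.loc[~complete, "subject_id"]:
        logger.info("subject %s dropped: incomplete covariates", sid)
    recs = recs[complete.to_numpy()]
    roi_table = roi_table.loc[recs["subject_id"]]

    anc = ancova_table(roi_table, recs)
    pair = pairwise_tables(roi_table, recs, tail=config.one_tailed_convention)
    corr = correlation_grids(roi_table, recs)

    _write_tsv(roi_table.reset_index(), outdir / "tables" / "roi_int.tsv")
    _write_tsv(anc, outdir / "tables" / "ancova.tsv")
    for name, table in pair.items():
        _write_tsv(table, outdir / "tables" / f"pairwise_{name}.tsv")
    _write_tsv(corr, outdir / "tables" / "correlations.tsv")
    _write_tsv(qc_table, outdir / "qc" / "subjects.tsv")

    if config.voxelwise:
        maps, groups = [], []
        grp = recs.set_index("subject_id")["group"]
        for sid, paths in config.manifest.items():
            if sid not in grp.index:
                continue
            vol = load_volume(paths["bold"], tr_override=config.tr_override)
            m = brain_mask
            if m is None:
                m = np.zeros(vol.spatial_shape, dtype=bool)
                for rm in roi_masks:
                    m |= rm.mask
            maps.append(int_map(vol, m, config.max_lag_seconds, config.include_lag_zero))
            groups.append(grp.loc[sid])
        vw = voxelwise_group_maps(maps, groups, config.voxelwise_threshold_p)
        nib.save(
            nib.Nifti1Image(vw.f_map.astype(np.float32), vw.affine),
            outdir / "maps" / "voxelwise_F.nii.gz",
        )
        for label, tm in vw.t_maps.items():
            safe = label.replace(">", "_gt_")
            nib.save(
                nib.Nifti1Image(tm.astype(np.float32), vw.affine),
                outdir / "maps" / f"voxelwise_t_{safe}.nii.gz",
            )
        _write_tsv(vw.clusters, outdir / "tables" / "clusters.tsv")

    import neurotimescales

    qc_counts = {
        "n_subjects_in": len(config.manifest),
        "n_excluded_motion": int(qc_table["excluded"].sum()),
        "n_dropped_covariates": int((~complete).sum()),
        "n_analyzed": len(roi_table),
        "n_window_capped_total": int(np.nansum(qc_table["n_window_capped"])),
        "n_degenerate_total": int(np.nansum(qc_table["n_degenerate"])),
    }
    manifest = {
        "package": _pkg_name,
        "version": neurotimescales.__version__,
        "numpy": np.__version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config.to_dict()),
        "qc": qc_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "qc" / "qc.json").write_text(json.dumps(qc_counts, indent=2))
    return {"outdir": str(outdir), "qc": qc_counts, "tables": {
        "roi_int": str(outdir / "tables" / "roi_int.tsv"),
        "ancova": str(outdir / "tables" / "ancova.tsv"),
    }}


def make_fixture(config: CohortConfig, outdir: Union[str, Path]) -> dict:
    """Materialize a synthetic cohort to disk as a ready-to-run bundle.

    Writes gzipped 4D NIfTI per subject, a participants TSV, 6-column
    motion text files, ground-truth phi/INT NIfTI fields, a config echo as
    YAML, and a run-config YAML pointing at the generated files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    (outdir / "bold").mkdir(exist_ok=True)
    (outdir / "motion").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    manifest = {}
    for i in range(cohort.n_subjects):
        sid = cohort.records.loc[i, "subject_id"]
        vol = cohort.volume(i)
        img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
        img.header.set_zooms((*np.abs(np.diag(vol.affine)[:3]), vol.tr))
        bold_path = outdir / "bold" / f"{sid}_bold.nii.gz"
        nib.save(img, bold_path)
        motion_path = outdir / "motion" / f"{sid}_motion.txt"
        m = cohort.motion[i]
        np.savetxt(motion_path, np.hstack([m.translations, m.rotations]), fmt="%.8f")
        manifest[str(sid)] = {"bold": str(bold_path), "motion": str(motion_path)}

    pheno_path = outdir / "participants.tsv"
    cohort.records.to_csv(pheno_path, sep="\t", index=False)

    roi_path = outdir / "rois.tsv"
    pd.DataFrame(
        [
            {"name": r.name, "description": r.description, "source": r.source,
             "x": r.center[0], "y": r.center[1], "z": r.center[2],
             "radius_mm": r.radius}
            for r in config.rois
        ]
    ).to_csv(roi_path, sep="\t", index=False)

    truth = cohort.truth
    nib.save(
        nib.Nifti1Image(truth.phi_base.astype(np.float32), truth.affine),
        outdir / "truth" / "phi_base.nii.gz",
    )
    for g, f in truth.group_phi.items():
        nib.save(
            nib.Nifti1Image(f.astype(np.float32), truth.affine),
            outdir / "truth" / f"phi_{g}.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(truth.int_field(g).astype(np.float32), truth.affine),
            outdir / "truth" / f"int_{g}.nii.gz",
        )

    cfg_echo = {
        "n_per_group": list(config.n_per_group),
        "tr": config.tr,
        "n_volumes": config.n_volumes,
        "max_lag_seconds": config.max_lag_seconds,
        "grid_shape": list(config.grid_shape),
        "phi_gradient": list(config.phi_gradient),
        "phi_subject_sd": config.phi_subject_sd,
        "group_effect": config.group_effect,
        "mask_mode": config.mask_mode,
        "seed": config.seed,
    }
    (outdir / "cohort_config.yaml").write_text(yaml.safe_dump(cfg_echo))

    run_cfg = {
        "manifest": manifest,
        "phenotypes": str(pheno_path),
        "outdir": str(outdir / "results"),
        "roi_table": str(roi_path),
        "tr_override": config.tr,
        "max_lag_seconds": config.max_lag_seconds,
        "seed": config.seed,
    }
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(run_cfg))
    return {"outdir": str(outdir), "manifest": manifest,
            "run_config": str(outdir / "run_config.yaml")}
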