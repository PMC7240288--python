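"""Readers, writers, run configuration and the end-to-end pipeline driver.

Formats: NIfTI-1 for images (RAS affines), comma-separated UTF-8 CSV with
a header row for tables, tab-separated TSV for motion traces, JSON for
scalar results and the run manifest.  Every output written here is
re-readable by the package's own readers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import pipeline as pipe
from .factors import factor_pipeline
from .variability import motion_qc, sdbold_pipeline

logger = logging.getLogger("boldvar")


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# images


def read_nifti(path: str | Path):
    """Load a NIfTI-1 volume or series; returns (data, affine, header)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such image: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # malformed header, wrong format, ...
        raise DataError(f"cannot read NIfTI at {path}: {exc}") from exc
    return data, img.affine, img.header


def write_nifti(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine),
             path)
    return path


# ---------------------------------------------------------------------------
# tables


def load_tables(behavior_csv: str | Path, battery_csv: str | Path,
                volumes_csv: str | Path, motion_dir: str | Path | None = None):
    """Join cohort tables on subject_id; report and drop incomplete subjects.

    Returns (behavior, battery, volumes, motion dict) with a common,
    normalized subject order.  Duplicate subject ids are an error.
    """
    frames = {}
    for name, p in (("behavior", behavior_csv), ("battery", battery_csv),
                    ("volumes", volumes_csv)):
        df = pd.read_csv(p)
        if "subject_id" not in df.columns:
            raise DataError(f"{name} table lacks a subject_id column")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise DataError(f"duplicate subject_id in {name} table: {dup}")
        frames[name] = df
    if "group" not in frames["behavior"].columns:
        raise DataError("behavior table lacks a group column")
    common = set(frames["behavior"]["subject_id"])
    for name in ("battery", "volumes"):
        common &= set(frames[name]["subject_id"])
    order = [s for s in frames["behavior"]["subject_id"] if s in common]
    dropped = sorted(set().union(*[set(f["subject_id"]) for f in frames.values()])
                     - common)
    if dropped:
        logger.warning("subjects missing from some table, excluded: %s", dropped)
    out = {name: df[df["subject_id"].isin(common)]
           .set_index("subject_id").loc[order].reset_index()
           for name, df in frames.items()}
    motion = {}
    if motion_dir is not None:
        for sid in order:
            p = Path(motion_dir) / f"{sid}_motion.tsv"
            if p.exists():
                motion[sid] = pd.read_csv(p, sep="\t")
    return out["behavior"], out["battery"], out["volumes"], motion


# ---------------------------------------------------------------------------
# run configuration


_COHORT_KEYS = {"n_per_group", "grid_dims", "n_timepoints", "tr_seconds",
                "effect_size", "noise_sd", "baseline_mean", "seed", "ar_coef",
                "volume_coupling", "volume_coupling_at_risk_only",
                "group_flip", "battery_noise_sd"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "boldvar_out"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    gm_threshold: float = 0.43
    low_hz: float = 0.01
    high_hz: float = 0.1
    detrend_order: int = 2
    abs_motion_mm: float = 2.0
    rel_motion_mm: float = 2.5
    n_permutations: int = 1000
    n_bootstraps: int = 1000
    ci_level: float = 0.95
    procrustes: bool = True
    bsr_threshold_whole_brain: float = 4.0
    bsr_threshold_mtl: float = 2.5
    cluster_min_size: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.cohort) - _COHORT_KEYS
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        if not 0.0 <= self.gm_threshold < 1.0:
            raise ConfigError("gm_threshold must lie in [0, 1)")
        if not 0.0 < self.low_hz < self.high_hz:
            raise ConfigError("need 0 < low_hz < high_hz")
        if self.detrend_order not in (1, 2):
            raise ConfigError("detrend_order must be 1 or 2")
        if self.n_permutations < 1 or self.n_bootstraps < 2:
            raise ConfigError("n_permutations >= 1 and n_bootstraps >= 2 required")
        if not 0.5 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0.5, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    out_dir: Path
    manifest: dict
    results: dict = field(default_factory=dict)
    partial: bool = False
    failed_stage: str | None = None


def _pls_summary(res) -> dict:
    r = res.resampling
    return {
        "singular_values": res.decomposition.S.tolist(),
        "covariance_fraction": res.decomposition.covariance_fraction.tolist(),
        "permutation_p": r.permutation_p.tolist(),
        "row_labels": res.decomposition.row_labels,
        "behavior_salience_lv1": res.decomposition.V[:, 0].tolist(),
        "ci_low_lv1": r.ci_low[:, 0].tolist(),
        "ci_high_lv1": r.ci_high[:, 0].tolist(),
        "n_permutations": r.n_permutations,
        "n_bootstraps": r.n_bootstraps,
    }


def run_all(config: RunConfig) -> ResultBundle:
    """Simulate -> SD_BOLD -> factors -> PLS analyses -> report.

    Every stage is logged with its parameters; a stage failure marks the
    bundle partial and names the failing stage.  All randomness flows from
    ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.hash(),
                "seed": config.seed}
    bundle = ResultBundle(out, manifest)
    stage = "simulate"
    try:
        logger.info("stage simulate: %s", config.cohort)
        spec = cohort_mod.CohortSpec(seed=config.seed, **config.cohort)
        ch = cohort_mod.generate_cohort(spec)

        stage = "motion_qc"
        qc = {sid: motion_qc(df["abs_mm"].to_numpy(), df["rel_mm"].to_numpy(),
                             config.abs_motion_mm, config.rel_motion_mm)
              for sid, df in ch.motion.items()}
        keep = [sid for sid in ch.subject_ids if qc[sid].passed]
        excluded = sorted(set(ch.subject_ids) - set(keep))
        if excluded:
            logger.warning("motion QC excluded: %s", excluded)

        stage = "sdbold"
        logger.info("stage sdbold: band %.3f-%.3f Hz, detrend %d, GM > %.2f",
                    config.low_hz, config.high_hz, config.detrend_order,
                    config.gm_threshold)
        sd_maps = {sid: sdbold_pipeline(ch.series[sid], ch.gm_prob,
                                        config.gm_threshold, config.low_hz,
                                        config.high_hz, config.detrend_order)
                   for sid in keep}
        group = ch.behavior.set_index("subject_id").loc[keep, "group"].to_numpy()

        stage = "factors"
        battery = ch.battery.set_index("subject_id").loc[keep]
        solution, record, eig = factor_pipeline(
            battery.drop(columns=["group"]), ch.battery_direction)
        logger.info("stage factors: %d factors, rotation %s",
                    solution.n_factors, solution.rotation)
        fs = pd.DataFrame(solution.factor_scores,
                          columns=solution.factor_names, index=keep)
        fs.to_csv(out / "factor_scores.csv", index_label="subject_id",
                  float_format="%.10g")
        load_df = pd.DataFrame(solution.loadings, index=solution.test_names,
                               columns=solution.factor_names)
        load_df["strong"] = (np.abs(solution.loadings) > 0.40).any(axis=1)
        load_df.to_csv(out / "factor_loadings.csv", float_format="%.4f")

        stage = "pls_group_factors"
        seed_seq = np.random.SeedSequence([config.seed, 77])
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(4)]
        res_gf = pipe.run_group_comparison_pls(
            solution.factor_scores, group, solution.factor_names,
            config.n_permutations, config.n_bootstraps, seeds[0])

        stage = "pls_behavior"
        behavior = ch.behavior.set_index("subject_id").loc[keep].copy()
        for name, col in zip(solution.factor_names, solution.factor_scores.T):
            behavior[name] = col
        res_wb = pipe.run_whole_brain_behavior_pls(
            sd_maps, behavior, keep, group,
            config.n_permutations, config.n_bootstraps, seeds[1])
        mask = res_wb.meta["mask"]
        bsr = pipe.bsr_volume(res_wb, mask)
        write_nifti(bsr, out / "whole_brain_bsr.nii.gz")
        ct = pipe.cluster_table(bsr, config.bsr_threshold_whole_brain,
                                config.cluster_min_size)
        ct.table.to_csv(out / "clusters_whole_brain.csv", index=False)

        stage = "pls_mtl"
        mtl = pipe.extract_mtl_block(sd_maps, keep, group,
                                     ch.region_labels == cohort_mod.MTL_LABEL)
        volumes = ch.volumes.set_index("subject_id").loc[keep]
        res_mtl = pipe.run_mtl_volume_pls(mtl, volumes,
                                          config.n_permutations,
                                          config.n_bootstraps, seeds[2])

        stage = "report"
        cross = pipe.correlate_brain_scores(res_wb.brain_scores.scores[:, 0],
                                            res_mtl.brain_scores.scores[:, 0],
                                            group)
        pd.DataFrame({"subject_id": keep, "group": group,
                      "whole_brain_lv1": res_wb.brain_scores.scores[:, 0],
                      "mtl_volume_lv1": res_mtl.brain_scores.scores[:, 0]}
                     ).to_csv(out / "brain_scores.csv", index=False,
                              float_format="%.10g")
        bundle.results = {
            "motion_excluded": excluded,
            "n_factors": solution.n_factors,
            "scree_eigenvalues": eig.tolist(),
            "group_pls_factors": _pls_summary(res_gf),
            "whole_brain_behavior_pls": _pls_summary(res_wb),
            "mtl_volume_pls": _pls_summary(res_mtl),
            "brain_score_correlations": cross,
            "n_clusters_whole_brain": int(len(ct.table)),
        }
        (out / "results.json").write_text(json.dumps(bundle.results, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        bundle.partial = True
        bundle.failed_stage = stage
        bundle.results["error"] = f"{stage}: {exc}"
        logger.error("run_all failed at stage %s: %s", stage, exc)
    return bundle
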