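"""Cohort table handling, clinical scores, run configuration and pipeline.

The cohort table is a TSV with one row per subject: group membership,
demographic covariates (age, gender coded 0/1, education years), pre- and
post-operative JOA myelopathy scores for patients, the surgical recovery
rate, and file paths to each subject's image and motion trace.

The JOA recovery rate is the fraction of the attainable improvement that
was realised:  (post - pre) / (17 - pre), with 17 the scale ceiling.  It
can be negative if a patient worsened and is capped at 1 by construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("ampdyn")

JOA_CEILING = 17

REQUIRED_COLUMNS = ("subject_id", "group", "age", "gender", "education")


def joa_recovery_rate(joa_pre, joa_post) -> float:
    """Surgical recovery fraction: (post - pre) / (17 - pre).

    Requires 0 <= pre < 17 (a pre score of 17 leaves no room to recover and
    makes the rate undefined) and 0 <= post <= 17.  The result is at most 1
    (full recovery) and may be negative.
    """
    pre = float(joa_pre)
    post = float(joa_post)
    if not (0 <= pre <= JOA_CEILING) or not (0 <= post <= JOA_CEILING):
        raise ValueError(f"JOA scores must lie in [0, {JOA_CEILING}]")
    if pre == JOA_CEILING:
        raise ValueError("preoperative JOA of 17 gives a zero denominator")
    return (post - pre) / (JOA_CEILING - pre)


def load_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort TSV.

    Recomputes the recovery rate from the JOA columns where both are
    present, filling a missing `recovery_rate` column and checking a
    provided one for consistency (tolerance 1e-9).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    for col in ("age", "gender", "education"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "subject_id"].tolist()
            raise ValueError(f"missing {col} for subjects {bad}")
    bad_group = ~df["group"].isin(["patient", "control"])
    if bad_group.any():
        raise ValueError(
            f"unknown group labels for {df.loc[bad_group, 'subject_id'].tolist()}"
        )
    if {"joa_pre", "joa_post"}.issubset(df.columns):
        rates = np.full(len(df), np.nan)
        for i, row in df.iterrows():
            if pd.notna(row["joa_pre"]) and pd.notna(row["joa_post"]):
                try:
                    rates[i] = joa_recovery_rate(row["joa_pre"], row["joa_post"])
                except ValueError as exc:
                    raise ValueError(f"subject {row['subject_id']}: {exc}") from exc
        if "recovery_rate" in df.columns:
            have = df["recovery_rate"].to_numpy(dtype=float)
            both = np.isfinite(have) & np.isfinite(rates)
            if not np.allclose(have[both], rates[both], atol=1e-9):
                off = df.loc[both, "subject_id"][
                    ~np.isclose(have[both], rates[both], atol=1e-9)
                ].tolist()
                raise ValueError(f"recovery_rate inconsistent with JOA for {off}")
        df["recovery_rate"] = rates
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and end-to-end pipeline


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; loadable from YAML."""

    out_dir: str = "ampdyn-out"
    seed: int = 0
    # simulation
    n_per_group: int = 8
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    n_timepoints: int = 180
    tr_s: float = 2.0
    # prep
    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    fd_threshold_mm: float = 0.5
    scrub_before: int = 2
    scrub_after: int = 1
    fwhm_mm: float = 6.0
    # metrics
    window_lens_tr: tuple[int, ...] = (22,)
    step_tr: int = 1
    # statistics
    p_voxel: float = 0.001
    cluster_alpha: float = 0.05
    n_perm_cluster: int = 200
    n_perm_mvpa: int = 200
    svm_c: float = 1.0
    svr_epsilon: float = 0.1
    # optional region-wise analysis
    n_atlas_regions: int | None = 8
    metric: str = "zalff"  # which map feeds the multivariate stages

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("grid_shape", "band_hz", "window_lens_tr"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate a cohort and run every analysis stage on it.

    Stages: simulate -> preprocess -> static/dynamic maps -> covariate-
    adjusted cluster test -> ROI pattern classification (with permutation
    null and AUC) -> prognosis regression.  All outputs plus a provenance
    sidecar are written under `cfg.out_dir`; the result bundle is returned
    and is bit-reproducible for a fixed config.
    """
    from . import metrics, mvpa, synth, univariate
    from .prep import PrepConfig

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg.seed)

    block = synth.EffectBlock(
        lo=tuple(g // 4 for g in cfg.grid_shape),
        hi=tuple(g // 4 + max(2, g // 6) for g in cfg.grid_shape),
        patient_ratio=2.0,
    )
    weight_map = np.zeros(cfg.grid_shape)
    weight_map[block.slices()] = 1.0
    spec = synth.SynthSpec(
        n_per_group=cfg.n_per_group,
        grid_shape=cfg.grid_shape,
        tr_s=cfg.tr_s,
        n_timepoints=cfg.n_timepoints,
        band_hz=cfg.band_hz,
        static_effect_regions=(block,),
        prognosis_weight_map=weight_map,
        seed=rng_seed,
    )
    subjects, table, truth = synth.generate_cohort(spec)
    write_cohort_table(table, out / "cohort.tsv")

    prep_cfg = PrepConfig(
        n_discard=cfg.n_discard,
        band_hz=cfg.band_hz,
        fd_threshold_mm=cfg.fd_threshold_mm,
        scrub_before=cfg.scrub_before,
        scrub_after=cfg.scrub_after,
        fwhm_mm=cfg.fwhm_mm,
    )
    wspecs = [metrics.WindowSpec(w, cfg.step_tr) for w in cfg.window_lens_tr]
    maps = metrics.metric_pipeline(subjects, prep_cfg, wspecs, cfg.band_hz)
    zalff = metrics.stack_maps(maps["zalff"])
    design = univariate.DesignInfo.from_cohort(table)

    tmap = univariate.voxelwise_group_t(zalff, design)
    clusters = univariate.cluster_correct(
        tmap, design, zalff,
        p_voxel=cfg.p_voxel, alpha=cfg.cluster_alpha,
        n_perm=cfg.n_perm_cluster, seed=rng_seed + 1,
    )
    cluster_rows = []
    patients = table["group"].to_numpy() == "patient"
    for c in clusters.clusters:
        row = {
            "peak_t": c.peak_t, "extent": c.extent,
            "peak_coord": list(map(int, c.peak_coord)), "p_fwe": c.p_corrected,
        }
        means = univariate.extract_cluster_means(zalff, c)
        pre = table.loc[patients, "joa_pre"].to_numpy(dtype=float)
        r, p = univariate.correlate_clinical(means[patients], pre)
        row["r_joa_pre"], row["p_joa_pre"] = r, p
        cluster_rows.append(row)

    y = patients.astype(int)
    roi = truth.static_effect_mask
    X = mvpa.extract_features(zalff, roi)
    cv, sens = mvpa.loocv_classify(X, y, C=cfg.svm_c)
    null = mvpa.permutation_test(
        X, y, n_perm=cfg.n_perm_mvpa, seed=rng_seed + 2, statistic="accuracy", C=cfg.svm_c
    )

    rec = table.loc[patients, "recovery_rate"].to_numpy(dtype=float)
    Xp = mvpa.extract_features(zalff[patients], roi)
    svr = mvpa.loocv_svr(Xp, rec, C=cfg.svm_c, epsilon=cfg.svr_epsilon)

    region_results = None
    if cfg.n_atlas_regions:
        atlas = synth.generate_atlas(cfg.grid_shape, cfg.n_atlas_regions, seed=rng_seed)
        rt = mvpa.regionwise_classify(
            zalff, y, atlas, n_perm=cfg.n_perm_mvpa, seed=rng_seed + 3, C=cfg.svm_c
        )
        region_results = rt.to_dict(orient="records")
    else:
        log.info("no atlas requested; skipping region-wise stages")

    bundle = {
        "config_hash": cfg.config_hash(),
        "n_subjects": int(len(table)),
        "clusters": cluster_rows,
        "roi_classification": {
            "accuracy_pct": cv.mean_accuracy_pct,
            "auc": cv.auc,
            "perm_p": null.p_value,
            "null_mean_accuracy_pct": float(np.mean(null.null_values) * 100.0),
            "n_consistent_voxels": int(sens.consistency_mask.sum()),
        },
        "prognosis": {"r": svr.pearson_r, "rmse": svr.rmse},
        "regionwise_classification": region_results,
    }
    (out / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    prov = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "prep": maps["provenance"][0],
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return bundle
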