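"""Synthetic two-group resting-state cohorts with known ground truth.

The generator emulates the structure of a patients-vs-controls resting-state
study: band-limited oscillatory voxel signals whose amplitude is raised for
patients inside designated "static effect" blocks (a static-ALFF group
difference), whose slow amplitude modulation is deepened inside "dynamic
effect" blocks (a dALFF-variance difference), bounded random-walk head
motion, demographic covariates, and clinical recovery scores tied to a
planted regional amplitude pattern so that prognosis regression is testable.

Per-voxel signal model (time in seconds, t = 0, TR, 2 TR, ...):

    x_v(t) = baseline + A_v * (1 + m_v * s(t)) * sin(2 pi f_v t + phi_v) + e_t

with carrier f_v uniform inside the analysis band, slow envelope s(t) a
sinusoid with period much longer than any dALFF window, and white noise e_t.

Map-level simulators (`planted_map_cohort`, `prognosis_map_cohort`) generate
per-subject amplitude maps directly — the quantity the group statistics and
pattern analyses actually consume — for simulation studies where running the
full signal pipeline per replicate would be wasteful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cohort import joa_recovery_rate
from .prep import MotionTrace, TimeSeriesImage, save_motion, save_nifti

PATIENT = "patient"
CONTROL = "control"


@dataclass(frozen=True)
class EffectBlock:
    """An axis-aligned voxel block carrying a planted group effect.

    For static effects `patient_ratio` multiplies the carrier amplitude A_v
    for patients; for dynamic effects `m_control` / `m_patient` set the
    slow-envelope modulation depth per group.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive
    patient_ratio: float = 1.0
    m_control: float = 0.0
    m_patient: float = 0.0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    def check_inside(self, grid_shape) -> None:
        for a, b, g in zip(self.lo, self.hi, grid_shape):
            if not (0 <= a < b <= g):
                raise ValueError(f"effect block {self.lo}..{self.hi} outside grid {grid_shape}")


@dataclass
class SynthSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the acquisition protocol the package targets (TR 2 s,
    180 timepoints, 3 mm voxels, 0.01-0.08 Hz band) on a small synthetic
    brain grid.  Clinical recovery scores are drawn around 0.70 with spread
    0.156 (the study population's reported recovery distribution), linked to
    the planted prognosis pattern.
    """

    n_per_group: int = 10
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_timepoints: int = 180
    band_hz: tuple[float, float] = (0.01, 0.08)
    static_effect_regions: tuple[EffectBlock, ...] = ()
    dynamic_effect_regions: tuple[EffectBlock, ...] = ()
    baseline: float = 100.0
    base_amplitude: float = 1.0
    amp_subject_sd: float = 0.2  # relative between-subject global amplitude scatter
    amp_regional_sd: float = 0.3  # extra scatter inside the prognosis pattern
    envelope_period_s: float = 240.0
    noise_sd: float = 0.25
    motion_sd_mm: float = 0.02
    motion_sd_deg: float = 0.02
    motion_bound_mm: float = 0.5
    motion_bound_deg: float = 0.5
    prognosis_weight_map: np.ndarray | None = None
    recovery_mean: float = 0.70
    recovery_spread: float = 0.156
    recovery_noise_sd: float = 0.03
    joa_pre_range: tuple[int, int] = (6, 14)
    age_mean: float = 52.0
    age_sd: float = 8.0
    education_mean: float = 10.0
    education_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for blk in tuple(self.static_effect_regions) + tuple(self.dynamic_effect_regions):
            blk.check_inside(self.grid_shape)
        for name in ("noise_sd", "motion_sd_mm", "motion_sd_deg", "base_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.prognosis_weight_map is not None:
            w = np.asarray(self.prognosis_weight_map, dtype=float)
            if w.shape != tuple(self.grid_shape):
                raise ValueError("prognosis_weight_map shape must match grid")
            object.__setattr__(self, "prognosis_weight_map", w)

    def static_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for blk in self.static_effect_regions:
            m[blk.slices()] = True
        return m

    def dynamic_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        for blk in self.dynamic_effect_regions:
            m[blk.slices()] = True
        return m


@dataclass
class GroundTruth:
    """What was planted: effect masks and per-patient recovery signal."""

    static_effect_mask: np.ndarray
    dynamic_effect_mask: np.ndarray
    true_recovery_scores: np.ndarray  # per patient, before JOA quantisation
    amplitude_fields: list = field(default_factory=list)  # per subject A_v grid


def _subject_rng(spec_seed: int, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, subject_seed)))


def _amplitude_field(spec: SynthSpec, group: str, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel carrier amplitude for one subject (before modulation).

    Besides the global between-subject scale, voxels inside the prognosis
    weight pattern get an extra subject-specific regional scale — a global
    scale alone would be removed by within-subject z-scoring and could not
    carry a prognosis signal into the standardized maps.
    """
    scale = 1.0 + spec.amp_subject_sd * rng.standard_normal()
    scale = max(scale, 0.05)
    A = np.full(spec.grid_shape, spec.base_amplitude * scale)
    if group == PATIENT:
        for blk in spec.static_effect_regions:
            A[blk.slices()] *= blk.patient_ratio
    if spec.prognosis_weight_map is not None:
        rscale = max(1.0 + spec.amp_regional_sd * rng.standard_normal(), 0.05)
        A[spec.prognosis_weight_map != 0] *= rscale
    return A


def generate_subject(
    spec: SynthSpec, group: str, subject_seed: int
) -> tuple[TimeSeriesImage, MotionTrace]:
    """Generate one subject's 4D image and motion trace; seed-deterministic."""
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
    rng = _subject_rng(spec.seed, subject_seed)
    shape = tuple(spec.grid_shape)
    T = spec.n_timepoints
    t = np.arange(T) * spec.tr_s

    A = _amplitude_field(spec, group, rng)
    f = rng.uniform(*spec.band_hz, size=shape)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    m = np.zeros(shape)
    for blk in spec.dynamic_effect_regions:
        depth = blk.m_patient if group == PATIENT else blk.m_control
        m[blk.slices()] = depth
    psi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sin(2.0 * np.pi * t / spec.envelope_period_s + psi)

    carrier = np.sin(2.0 * np.pi * f[..., None] * t + phi[..., None])
    envelope = 1.0 + m[..., None] * s
    data = spec.baseline + A[..., None] * envelope * carrier
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(shape + (T,))

    steps = np.empty((T, 6))
    steps[:, :3] = spec.motion_sd_mm * rng.standard_normal((T, 3))
    steps[:, 3:] = np.radians(spec.motion_sd_deg) * rng.standard_normal((T, 3))
    walk = np.cumsum(steps, axis=0)
    walk[0] = 0.0
    bounds = np.array(
        [spec.motion_bound_mm] * 3 + [np.radians(spec.motion_bound_deg)] * 3
    )
    # reflect the walk into [-bound, bound]
    period = 4.0 * bounds
    walk = np.abs(((walk + bounds) % period) - period / 2.0) - bounds
    img = TimeSeriesImage(data, (spec.voxel_size_mm,) * 3, spec.tr_s)
    return img, MotionTrace(walk)


def generate_cohort(spec: SynthSpec):
    """Generate the full cohort: subject data, cohort table, ground truth.

    Patients come first (`sub-p00`...), then controls.  Covariates are drawn
    independently of group; JOA scores are built so the recovery rate is a
    noisy linear function of each patient's planted-pattern amplitude
    projection (then quantised through integer JOA scores).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 999_983)))
    subjects = []
    rows = []
    amp_fields = []
    groups = [PATIENT] * spec.n_per_group + [CONTROL] * spec.n_per_group
    for i, group in enumerate(groups):
        img, trace = generate_subject(spec, group, i)
        subjects.append((img, trace))
        sub_rng = _subject_rng(spec.seed, i)
        amp_fields.append(_amplitude_field(spec, group, sub_rng))
        rows.append(
            {
                "subject_id": f"sub-{'p' if group == PATIENT else 'c'}{i:02d}",
                "group": group,
                "age": int(np.clip(round(rng.normal(spec.age_mean, spec.age_sd)), 20, 85)),
                "gender": int(rng.integers(0, 2)),
                "education": int(np.clip(round(rng.normal(spec.education_mean, spec.education_sd)), 0, 22)),
            }
        )
    table = pd.DataFrame(rows)

    # recovery scores for patients from the planted pattern projection
    n_pat = spec.n_per_group
    if spec.prognosis_weight_map is not None:
        proj = np.array(
            [float((amp_fields[i] * spec.prognosis_weight_map).sum()) for i in range(n_pat)]
        )
    else:
        proj = np.zeros(n_pat)
    sd = proj.std()
    z = (proj - proj.mean()) / sd if sd > 0 else np.zeros(n_pat)
    noise = spec.recovery_noise_sd * rng.standard_normal(n_pat)
    true_recovery = np.minimum(spec.recovery_mean + spec.recovery_spread * z + noise, 1.0)

    joa_pre = np.full(len(table), np.nan)
    joa_post = np.full(len(table), np.nan)
    recovery = np.full(len(table), np.nan)
    for i in range(n_pat):
        pre = int(rng.integers(spec.joa_pre_range[0], spec.joa_pre_range[1] + 1))
        post = int(np.clip(round(pre + true_recovery[i] * (17 - pre)), 0, 17))
        joa_pre[i] = pre
        joa_post[i] = post
        recovery[i] = joa_recovery_rate(pre, post)
    table["joa_pre"] = joa_pre
    table["joa_post"] = joa_post
    table["recovery_rate"] = recovery

    truth = GroundTruth(
        static_effect_mask=spec.static_mask(),
        dynamic_effect_mask=spec.dynamic_mask(),
        true_recovery_scores=true_recovery,
        amplitude_fields=amp_fields,
    )
    return subjects, table, truth


def generate_atlas(
    grid_shape, n_regions: int, seed: int = 0, min_voxels: int = 8
) -> np.ndarray:
    """Integer-labelled parcellation of an ellipsoidal brain-like mask.

    Labels 1..n_regions tile the mask (k-means on voxel coordinates, so
    regions are compact blobs); label 0 is background.  Region sizes sum to
    the mask size and each region has at least `min_voxels` voxels.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    grid_shape = tuple(grid_shape)
    center = (np.array(grid_shape) - 1) / 2.0
    radii = np.maximum(np.array(grid_shape) / 2.0 - 0.5, 0.5)
    idx = np.indices(grid_shape).reshape(3, -1).T
    inside = (((idx - center) / radii) ** 2).sum(axis=1) <= 1.0
    coords = idx[inside]
    if n_regions * min_voxels > len(coords):
        raise ValueError(
            f"{n_regions} regions of >= {min_voxels} voxels do not fit in a "
            f"mask of {len(coords)} voxels"
        )
    labels = np.zeros(grid_shape, dtype=int)
    if n_regions == 1:
        labels[tuple(coords.T)] = 1
        return labels
    km = KMeans(n_clusters=n_regions, n_init=4, random_state=seed)
    assign = km.fit_predict(coords.astype(float))
    # enforce the minimum size by reassigning from the largest region
    sizes = np.bincount(assign, minlength=n_regions)
    while sizes.min() < min_voxels:
        small = int(sizes.argmin())
        big = int(sizes.argmax())
        donors = np.flatnonzero(assign == big)
        d2 = ((coords[donors] - km.cluster_centers_[small]) ** 2).sum(axis=1)
        take = donors[np.argsort(d2)[: min_voxels - sizes[small]]]
        assign[take] = small
        sizes = np.bincount(assign, minlength=n_regions)
    labels[tuple(coords.T)] = assign + 1
    return labels


# ---------------------------------------------------------------------------
# map-level simulators (amplitude maps generated directly)


def planted_map_cohort(
    n_per_group: int,
    grid_shape,
    effect_mask: np.ndarray | None = None,
    effect_size: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Per-subject amplitude maps with an additive group shift in a mask.

    Patients' maps are raised by `effect_size * noise_sd` inside
    `effect_mask` (so `effect_size` is Cohen's d per voxel).  Returns
    (maps (2n, x, y, z) with patients first, group labels (1=patient),
    effect mask).
    """
    rng = np.random.default_rng(seed)
    grid_shape = tuple(grid_shape)
    n = 2 * n_per_group
    maps = noise_sd * rng.standard_normal((n,) + grid_shape)
    if effect_mask is None:
        effect_mask = np.zeros(grid_shape, dtype=bool)
    effect_mask = np.asarray(effect_mask, dtype=bool)
    if effect_size != 0.0:
        maps[:n_per_group, effect_mask] += effect_size * noise_sd
    y = np.array([1] * n_per_group + [0] * n_per_group)
    return maps, y, effect_mask


def prognosis_map_cohort(
    n_patients: int,
    grid_shape,
    pattern_mask: np.ndarray,
    pattern_strength: float = 1.0,
    noise_sd: float = 1.0,
    target_noise_frac: float = 0.2,
    seed: int = 0,
):
    """Patient maps whose in-pattern amplitude predicts a recovery score.

    Each patient i has a latent severity score s_i ~ N(0, 1); voxels inside
    `pattern_mask` gain `pattern_strength * s_i` on top of white noise.  The
    simulated recovery target is the z-scored pattern projection plus
    Gaussian noise with sd `target_noise_frac` of the signal sd.  Returns
    (maps, target, true latent scores).
    """
    rng = np.random.default_rng(seed)
    grid_shape = tuple(grid_shape)
    pattern_mask = np.asarray(pattern_mask, dtype=bool)
    s = rng.standard_normal(n_patients)
    maps = noise_sd * rng.standard_normal((n_patients,) + grid_shape)
    maps[:, pattern_mask] += pattern_strength * s[:, None]
    proj = maps[:, pattern_mask].sum(axis=1)
    z = (proj - proj.mean()) / proj.std()
    target = z + target_noise_frac * rng.standard_normal(n_patients)
    return maps, target, s


# ---------------------------------------------------------------------------
# on-disk cohort


def write_cohort(spec: SynthSpec, out_dir) -> Path:
    """Materialise a cohort on disk: NIfTI images, motion text files, TSV
    cohort table, ground-truth masks and a JSON manifest.  Returns out_dir."""
    out = Path(out_dir)
    (out / "sub").mkdir(parents=True, exist_ok=True)
    subjects, table, truth = generate_cohort(spec)
    img_paths, trace_paths = [], []
    for (img, trace), sid in zip(subjects, table["subject_id"]):
        ipath = out / "sub" / f"{sid}_bold.nii.gz"
        tpath = out / "sub" / f"{sid}_motion.txt"
        save_nifti(ipath, img.data, img.voxel_size_mm, img.tr_s)
        save_motion(tpath, trace)
        img_paths.append(str(ipath))
        trace_paths.append(str(tpath))
    table = table.assign(image_path=img_paths, trace_path=trace_paths)
    table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    vs = (spec.voxel_size_mm,) * 3
    save_nifti(out / "static_effect_mask.nii.gz", truth.static_effect_mask.astype(np.uint8), vs)
    save_nifti(out / "dynamic_effect_mask.nii.gz", truth.dynamic_effect_mask.astype(np.uint8), vs)
    manifest = {
        "seed": spec.seed,
        "n_per_group": spec.n_per_group,
        "grid_shape": list(spec.grid_shape),
        "tr_s": spec.tr_s,
        "n_timepoints": spec.n_timepoints,
        "band_hz": list(spec.band_hz),
        "true_recovery_scores": [float(v) for v in truth.true_recovery_scores],
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return out
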