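"""Synthetic resting-state cohort generator with planted latent structure.

The generator emulates the statistical shape of a two-group (at-risk /
control) older-adult resting-state study: 4-D BOLD series whose per-voxel
temporal SD carries a low-rank brain-behavior correlation, an
8-variable behavior panel (age, MoCA, global FA/MD and four cognitive
factor scores), a 14-test neuropsychological battery with a known 4-factor
loading structure, medial-temporal-lobe (MTL) subregion volumes negatively
coupled to MTL SD_BOLD, and benign motion traces.  The planted ground
truth (voxel salience, behavior salience, per-subject latent scores,
battery loadings) is retained so downstream recovery can be tested.

Effect-size semantics: ``effect_size`` is the fractional SD modulation at
the most salient voxel per unit latent score, and equally the Pearson
correlation between the latent score and the most strongly loaded
behavioral variable.  Internally the stored unit-norm salience and
behavior-salience vectors are rescaled to unit maximum before use, so the
parameter has the same meaning regardless of how many voxels or variables
carry signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .factors import LOWER_BETTER, REFERENCE_LOADINGS, TEST_NAMES
from .variability import BoldSeries

MTL_LABEL = 1
OCCIPITAL_LABEL = 2
OTHER_LABEL = 0

GROUPS = ("at_risk", "control")

BEHAVIOR_NAMES = ["age", "MoCA", "global_FA", "global_MD",
                  "visuospatial", "control_speed", "memory", "intelligence"]

VOLUME_NAMES = ["CA1", "CA2/3-DG", "subiculum", "alERC", "pmERC", "PRC", "PHC"]

#: Mean MTL subregion volumes (mm^3) for the synthetic volume panel.
VOLUME_MEANS = {"CA1": 600.0, "CA2/3-DG": 900.0, "subiculum": 350.0,
                "alERC": 450.0, "pmERC": 250.0, "PRC": 700.0, "PHC": 800.0}

#: Subregions coupled to MTL SD_BOLD by default (negative volume coupling).
COUPLED_VOLUMES = ("CA1", "CA2/3-DG", "alERC", "PHC")

#: Default behavior-salience pattern over BEHAVIOR_NAMES (before unit-norm):
#: higher SD_BOLD goes with better cognitive control/speed and intelligence,
#: worse visuospatial and memory performance, lower global MD, and is
#: essentially unrelated to age in the reference (control) group.
DEFAULT_BEHAVIOR_PATTERN = np.array([0.0, 0.3, 0.2, -0.55, -0.6, 1.0, -0.8, 0.8])

#: Behaviors whose coupling sign flips in the at-risk group (the reversed
#: control/speed relation).
DEFAULT_GROUP_FLIP = ("control_speed",)

#: Group-level demographics (mean, SD) used for realistic behavior units.
DEMOGRAPHICS = {
    "at_risk": {"age": (71.5, 6.1), "MoCA": (23.4, 1.9)},
    "control": {"age": (70.3, 4.5), "MoCA": (27.9, 1.7)},
}


class CohortError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_per_group: int = 20
    grid_dims: tuple = (12, 12, 12)
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    effect_size: float = 0.5
    noise_sd: float = 1.0  # baseline temporal SD of the BOLD fluctuation
    baseline_mean: float = 100.0  # raw signal level (grand-mean scaling target)
    seed: int = 0
    region_labels: np.ndarray | None = None  # int volume: 1=MTL, 2=occipital
    ar_coef: float = 0.0  # optional AR(1) coefficient for robustness tests
    volume_coupling: float = -0.5
    volume_coupling_at_risk_only: bool = True
    group_flip: tuple = DEFAULT_GROUP_FLIP
    battery_noise_sd: float | None = None  # None -> per-test sqrt(1 - h^2)

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise CohortError("n_per_group must be >= 3")
        if self.n_timepoints < 8:
            raise CohortError("n_timepoints must be >= 8")
        if len(self.grid_dims) != 3 or any(d < 4 for d in self.grid_dims):
            raise CohortError("grid_dims must be 3 integers, each >= 4")
        if not 0.0 <= self.effect_size <= 1.0:
            raise CohortError("effect_size must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise CohortError("noise_sd must be positive")
        if self.tr_seconds <= 0:
            raise CohortError("tr_seconds must be positive")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels)
            if self.region_labels.shape != tuple(self.grid_dims):
                raise CohortError("region_labels shape must match grid_dims")
        if not -1.0 <= self.volume_coupling <= 0.0:
            raise CohortError("volume_coupling must lie in [-1, 0]")


@dataclass
class GroundTruth:
    voxel_salience: np.ndarray  # unit norm, over in-mask voxels
    behavior_salience: np.ndarray  # unit norm, over BEHAVIOR_NAMES
    subject_scores: np.ndarray
    battery_loadings: np.ndarray


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    subject_ids: list
    group: np.ndarray
    series: dict  # subject_id -> BoldSeries
    behavior: pd.DataFrame
    battery: pd.DataFrame
    volumes: pd.DataFrame
    motion: dict  # subject_id -> DataFrame(t, abs_mm, rel_mm)
    gm_prob: np.ndarray
    region_labels: np.ndarray
    truth: GroundTruth
    battery_direction: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# geometry


def make_gm_prob(grid_dims: tuple) -> np.ndarray:
    """Gray-matter probability volume: interior box at 0.9, 1-voxel rim at 0.1."""
    p = np.full(grid_dims, 0.1)
    p[1:-1, 1:-1, 1:-1] = 0.9
    return p


def make_region_labels(grid_dims: tuple) -> np.ndarray:
    """Default anatomical labels: an MTL blob and a posterior occipital slab.

    The MTL block sits inferior-medial and covers roughly 6% of the
    interior; the occipital slab sits at the posterior face and covers
    roughly 10%, so the salient loci occupy a realistic minority of gray
    matter.
    """
    nx, ny, nz = grid_dims
    lab = np.zeros(grid_dims, dtype=np.int16)
    # MTL: small central-inferior block
    x0, x1 = max(1, nx // 2 - max(1, nx // 6)), nx // 2 + max(1, nx // 6)
    y0, y1 = max(1, ny // 3), ny // 3 + max(2, ny // 4)
    z0, z1 = 1, 1 + max(2, nz // 4)
    lab[x0:x1, y0:y1, z0:z1] = MTL_LABEL
    # occipital: posterior slab
    lab[1:-1, ny - 1 - max(2, ny // 5):ny - 1, 1 + nz // 4:nz - 1 - nz // 4] = OCCIPITAL_LABEL
    return lab


# ---------------------------------------------------------------------------
# planted structure


def make_salience_map(spec: CohortSpec) -> np.ndarray:
    """Smooth, unit-norm voxel salience concentrated in the MTL and
    occipital labels.

    In-region weights are a spatially autocorrelated field with mean 1 and
    moderate relative variation (~0.3); outside the regions a tiny smooth
    residue (~0.5% of the in-region level) keeps the map strictly nonzero.
    """
    labels = spec.region_labels if spec.region_labels is not None \
        else make_region_labels(spec.grid_dims)
    if labels.shape != tuple(spec.grid_dims):
        raise CohortError("region label volume shape must match grid_dims")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    field_ = gaussian_filter(rng.standard_normal(spec.grid_dims), sigma=1.2)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    in_region = (labels == MTL_LABEL) | (labels == OCCIPITAL_LABEL)
    sal = np.where(in_region, np.clip(1.0 + 0.3 * field_, 0.2, None),
                   0.005 * np.abs(field_) + 1e-6)
    return sal / np.linalg.norm(sal)


def _unit_peak(v: np.ndarray) -> np.ndarray:
    m = np.abs(v).max()
    return v / m if m > 0 else v


def _ar1(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """AR(1) innovations with unit marginal variance along the last axis."""
    eps = rng.standard_normal(shape)
    if phi == 0.0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0]
    c = np.sqrt(1.0 - phi**2)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + c * eps[..., t]
    return out


def simulate_subject_series(spec: CohortSpec, salience: np.ndarray,
                            score: float, seed) -> BoldSeries:
    """One subject's 4-D series with SD modulated by score x salience.

    The per-voxel fluctuation is zero-mean noise with SD
    ``noise_sd * (1 + effect_size * score * salience_v)`` (clipped below at
    10% of baseline), superimposed on the constant ``baseline_mean`` signal
    level.  The planted structure lives entirely in the variance; voxel
    means are flat.
    """
    if not np.isfinite(score):
        raise CohortError("subject score must be finite")
    if spec.noise_sd <= 0:
        raise CohortError("baseline noise_sd must be positive")
    sal = np.asarray(salience, dtype=float)
    if sal.shape != tuple(spec.grid_dims):
        raise CohortError("salience map shape must match grid_dims")
    rng = np.random.default_rng(seed)
    sd = spec.noise_sd * (1.0 + spec.effect_size * score * sal)
    sd = np.clip(sd, 0.1 * spec.noise_sd, None)
    noise = _ar1(rng, (*spec.grid_dims, spec.n_timepoints), spec.ar_coef)
    data = spec.baseline_mean + sd[..., None] * noise
    return BoldSeries(data, spec.tr_seconds)


def _noisy_channel(rng, score, weight, effect):
    """Standardized variable with corr(x, score) = effect * weight (|weight|<=1)."""
    n = len(score)
    if effect == 0.0 or weight == 0.0:
        return rng.standard_normal(n)
    r = effect * weight
    sigma = abs(weight) * np.sqrt(1.0 - r * r) / abs(r)
    return weight * score + sigma * rng.standard_normal(n)


def simulate_behavior(spec: CohortSpec, truth: GroundTruth,
                      subject_scores: np.ndarray, group: np.ndarray,
                      seed=None) -> pd.DataFrame:
    """Behavior panel with planted score-behavior correlations.

    Each variable correlates with the latent score by
    ``effect_size * pattern_j`` where the pattern is the stored behavior
    salience rescaled to unit maximum.  Variables named in
    ``spec.group_flip`` reverse their coupling sign in the at-risk group.
    Standardized channels are mapped onto realistic units (years, MoCA
    points, FA/MD scales) with group-specific demographics for age and
    MoCA.
    """
    scores = np.asarray(subject_scores, dtype=float)
    if scores.shape[0] != group.shape[0]:
        raise CohortError("one score per subject required")
    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence([spec.seed, 202]))
    pattern = _unit_peak(truth.behavior_salience)
    at_risk = group == "at_risk"
    z = np.empty((len(scores), len(BEHAVIOR_NAMES)))
    for j, name in enumerate(BEHAVIOR_NAMES):
        w = pattern[j]
        if name in spec.group_flip:
            col = np.empty(len(scores))
            col[at_risk] = _noisy_channel(rng, scores[at_risk], -w, spec.effect_size)
            col[~at_risk] = _noisy_channel(rng, scores[~at_risk], w, spec.effect_size)
        else:
            col = _noisy_channel(rng, scores, w, spec.effect_size)
        z[:, j] = col

    df = pd.DataFrame(index=range(len(scores)))
    for gname in GROUPS:
        sel = group == gname
        for var in ("age", "MoCA"):
            m, s = DEMOGRAPHICS[gname][var]
            df.loc[sel, var] = m + s * z[sel, BEHAVIOR_NAMES.index(var)]
    df["MoCA"] = df["MoCA"].clip(0.0, 30.0)
    df["global_FA"] = 0.45 + 0.03 * z[:, 2]
    df["global_MD"] = 7.5e-4 + 5e-5 * z[:, 3]
    for name in BEHAVIOR_NAMES[4:]:
        df[name] = z[:, BEHAVIOR_NAMES.index(name)]
    return df[BEHAVIOR_NAMES]


#: Per-test affine (mean, sd) giving the battery plausible raw units;
#: affine maps leave every correlation untouched.
BATTERY_SCALING = {
    "RCFT immediate recall": (22.0, 6.0), "RCFT delayed recall": (21.0, 6.0),
    "VOSP silhouettes": (20.0, 3.0), "VOSP progressive silhouettes": (15.0, 4.0),
    "WASI block design": (40.0, 12.0), "TMT A": (45.0, 12.0),
    "TMT B": (95.0, 30.0), "Digit span forward": (10.0, 2.0),
    "Digit span backward": (8.0, 2.0), "WMS immediate recall": (25.0, 7.0),
    "WMS delayed recall": (22.0, 8.0), "WASI matrix reasoning": (18.0, 6.0),
    "WASI vocabulary": (55.0, 12.0), "WASI similarity": (32.0, 6.0),
}


def simulate_battery(spec: CohortSpec, loadings: np.ndarray | None = None,
                     n: int | None = None, seed=None,
                     return_factors: bool = False):
    """14-test battery scores from a linear common-factor model.

    ``test_i = sum_k loadings_ik * factor_k + unique noise`` with i.i.d.
    standard-normal factors.  By default the reference loading matrix is
    used with per-test unique SD ``sqrt(1 - communality)`` so each test has
    unit variance before the affine unit scaling.  Timed tests (TMT) are
    negated (lower = better) to exercise orientation downstream.
    """
    if loadings is None:
        loadings = REFERENCE_LOADINGS
    L = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(L)):
        raise CohortError("loadings must be finite")
    if L.shape != (14, 4):
        raise CohortError(f"default battery needs 14x4 loadings, got {L.shape}")
    n = n if n is not None else 2 * spec.n_per_group
    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence([spec.seed, 303]))
    F = rng.standard_normal((n, L.shape[1]))
    if spec.battery_noise_sd is not None:
        unique_sd = np.full(L.shape[0], spec.battery_noise_sd)
    else:
        unique_sd = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.05, None))
    X = F @ L.T + unique_sd * rng.standard_normal((n, L.shape[0]))
    df = pd.DataFrame(index=range(n))
    for i, t in enumerate(TEST_NAMES):
        m, s = BATTERY_SCALING[t]
        x = X[:, i]
        if t in LOWER_BETTER:
            x = -x  # longer completion time = worse performance
        df[t] = m + s * x
    return (df, F) if return_factors else df


def simulate_mtl_volumes(spec: CohortSpec, mtl_sd_summary: np.ndarray,
                         coupling: float | None = None,
                         group: np.ndarray | None = None,
                         at_risk_only: bool | None = None,
                         seed=None, cv: float = 0.10) -> pd.DataFrame:
    """MTL subregion volumes negatively coupled to MTL SD_BOLD.

    ``coupling`` in [-1, 0] is the target correlation between each coupled
    subregion's volume and the subject's mean MTL SD_BOLD within the
    coupled scope (the at-risk group only, by default).  Uncoupled
    subregions and uncoupled subjects get independent volume noise.
    """
    coupling = spec.volume_coupling if coupling is None else coupling
    if coupling > 0:
        raise CohortError("volume coupling must be <= 0 "
                          "(the emulated pattern is negative)")
    if coupling < -1:
        raise CohortError("volume coupling must lie in [-1, 0]")
    at_risk_only = (spec.volume_coupling_at_risk_only
                    if at_risk_only is None else at_risk_only)
    s = np.asarray(mtl_sd_summary, dtype=float)
    n = s.shape[0]
    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence([spec.seed, 404]))
    scope = (group == "at_risk") if (at_risk_only and group is not None) \
        else np.ones(n, dtype=bool)
    z = np.zeros(n)
    sd_scope = s[scope].std()
    if sd_scope > 0:
        z[scope] = (s[scope] - s[scope].mean()) / sd_scope
    df = pd.DataFrame(index=range(n))
    for name in VOLUME_NAMES:
        eps = rng.standard_normal(n)
        w = np.where(scope & (name in COUPLED_VOLUMES),
                     coupling * z + np.sqrt(1.0 - coupling**2) * eps, eps)
        df[name] = np.clip(VOLUME_MEANS[name] * (1.0 + cv * w), 1.0, None)
    return df


def _simulate_motion(rng: np.random.Generator, t: int) -> pd.DataFrame:
    """Benign motion trace: slow drift below the exclusion thresholds."""
    drift = np.abs(np.cumsum(rng.normal(0.0, 0.02, size=t)))
    abs_mm = np.clip(drift + np.abs(rng.normal(0.05, 0.03, size=t)), 0.0, 1.8)
    rel_mm = np.abs(rng.normal(0.04, 0.03, size=t)).clip(0.0, 1.0)
    return pd.DataFrame({"t": np.arange(t), "abs_mm": abs_mm, "rel_mm": rel_mm})


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort: series, behavior, battery, volumes, motion.

    All randomness derives from ``spec.seed``; identical specs yield
    identical cohorts.
    """
    labels = spec.region_labels if spec.region_labels is not None \
        else make_region_labels(spec.grid_dims)
    spec = replace(spec, region_labels=labels)
    gm_prob = make_gm_prob(spec.grid_dims)
    mask = gm_prob > 0.43

    sal3d = make_salience_map(spec)
    sal_mod = _unit_peak(sal3d)

    bsal = DEFAULT_BEHAVIOR_PATTERN / np.linalg.norm(DEFAULT_BEHAVIOR_PATTERN)

    n = 2 * spec.n_per_group
    group = np.array([GROUPS[0]] * spec.n_per_group + [GROUPS[1]] * spec.n_per_group)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    root = np.random.SeedSequence([spec.seed, 1])
    score_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    scores = score_rng.standard_normal(n)
    scores = (scores - scores.mean()) / scores.std()

    truth = GroundTruth(
        voxel_salience=sal3d[mask] / np.linalg.norm(sal3d[mask]),
        behavior_salience=bsal,
        subject_scores=scores,
        battery_loadings=REFERENCE_LOADINGS.copy(),
    )

    series = {}
    motion = {}
    child_seeds = root.spawn(n)
    motion_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    for i, sid in enumerate(subject_ids):
        s = simulate_subject_series(spec, sal_mod, scores[i], child_seeds[i])
        s.subject_id = sid
        series[sid] = s
        motion[sid] = _simulate_motion(motion_rng, spec.n_timepoints)

    behavior = simulate_behavior(spec, truth, scores, group)
    battery = simulate_battery(spec, n=n)

    # expected mean MTL SD per subject (linear in score by construction)
    mtl_mask = (labels == MTL_LABEL) & mask
    sd_exp = spec.noise_sd * (1.0 + spec.effect_size * np.outer(scores, sal_mod[mtl_mask]))
    volumes = simulate_mtl_volumes(spec, sd_exp.mean(axis=1), group=group)

    for df in (behavior, battery, volumes):
        df.insert(0, "subject_id", subject_ids)
        df.insert(1, "group", group)

    direction = {t: ("lower_better" if t in LOWER_BETTER else "higher_better")
                 for t in TEST_NAMES}
    return SyntheticCohort(spec, subject_ids, group, series, behavior,
                           battery, volumes, motion, gm_prob, labels, truth,
                           direction)


# ---------------------------------------------------------------------------
# disk round-trip


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write a cohort to disk: NIfTI volumes, CSV tables, TSV motion, JSON truth."""
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    for sid, s in cohort.series.items():
        nib.save(nib.Nifti1Image(s.data.astype(np.float32), aff),
                 path / f"{sid}_bold.nii.gz")
    nib.save(nib.Nifti1Image(cohort.gm_prob.astype(np.float32), aff),
             path / "gm_prob.nii.gz")
    nib.save(nib.Nifti1Image(cohort.region_labels.astype(np.int16), aff),
             path / "region_labels.nii.gz")
    kw = dict(index=False, float_format="%.10g")
    cohort.behavior.to_csv(path / "behavior.csv", **kw)
    cohort.battery.to_csv(path / "battery.csv", **kw)
    cohort.volumes.to_csv(path / "volumes.csv", **kw)
    mdir = path / "motion"
    mdir.mkdir(exist_ok=True)
    for sid, df in cohort.motion.items():
        df.to_csv(mdir / f"{sid}_motion.tsv", sep="\t", **kw)
    truth = {
        "voxel_salience": cohort.truth.voxel_salience.tolist(),
        "behavior_salience": cohort.truth.behavior_salience.tolist(),
        "subject_scores": cohort.truth.subject_scores.tolist(),
        "battery_loadings": cohort.truth.battery_loadings.tolist(),
    }
    (path / "truth.json").write_text(json.dumps(truth))
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(cohort.spec).items() if k != "region_labels"}
    (path / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2))
    return path


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Re-read a written cohort (inverse of :func:`write_cohort`)."""
    import nibabel as nib

    path = Path(path)
    spec_dict = json.loads((path / "cohort_spec.json").read_text())
    spec_dict["grid_dims"] = tuple(spec_dict["grid_dims"])
    spec_dict["group_flip"] = tuple(spec_dict["group_flip"])
    labels = np.asarray(nib.load(path / "region_labels.nii.gz").dataobj)
    spec = CohortSpec(region_labels=labels.astype(np.int16),
                      **{k: v for k, v in spec_dict.items()})
    gm_prob = np.asarray(nib.load(path / "gm_prob.nii.gz").dataobj, dtype=float)
    behavior = pd.read_csv(path / "behavior.csv")
    battery = pd.read_csv(path / "battery.csv")
    volumes = pd.read_csv(path / "volumes.csv")
    subject_ids = behavior["subject_id"].tolist()
    group = behavior["group"].to_numpy()
    series = {}
    motion = {}
    for sid in subject_ids:
        data = np.asarray(nib.load(path / f"{sid}_bold.nii.gz").dataobj, dtype=float)
        series[sid] = BoldSeries(data, spec.tr_seconds, sid)
        motion[sid] = pd.read_csv(path / "motion" / f"{sid}_motion.tsv", sep="\t")
    t = json.loads((path / "truth.json").read_text())
    truth = GroundTruth(np.asarray(t["voxel_salience"]),
                        np.asarray(t["behavior_salience"]),
                        np.asarray(t["subject_scores"]),
                        np.asarray(t["battery_loadings"]))
    direction = {tn: ("lower_better" if tn in LOWER_BETTER else "higher_better")
                 for tn in TEST_NAMES}
    return SyntheticCohort(spec, subject_ids, group, series, behavior,
                           battery, volumes, motion, gm_prob,
                           labels.astype(np.int16), truth, direction)
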