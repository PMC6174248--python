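"""Synthetic four-group rs-fMRI cohort generator.

Emulates an aging/dementia study design — four diagnostic groups
(NC, EMCI, LMCI, AD; default sizes 30/33/32/29), 140 volumes at TR = 3 s
of which the first 10 are scanner-equilibration dummies — with a
controllable, region-localized complexity contrast and clinical scores
coupled to that complexity.

Signal model.  Each voxel is a standardized mixture

    w * pink + (1 - w) * white

of independently unit-variance spectral-synthesis 1/f noise and i.i.d.
Gaussian noise.  The pink weight ``w`` directly controls the shape of the
MSE curve: w = 0 gives a curve that falls steeply with scale, w = 1 an
almost flat curve, so larger w means higher large-scale entropy
("more complex" dynamics).  Background voxels share one group-independent
weight; voxels inside planted ROI spheres take a group-specific weight
(plus a per-subject jitter), which is what the group inference downstream
is expected to recover.  Because the mixture is standardized voxelwise,
the contrast lives purely in temporal structure, not amplitude.

Clinical coupling.  Each subject's complexity summary c (mean planted
weight) drives the scores: MMSE increases with c, FAQ and CDR decrease
(CDR clamped to [0, 3]).  Age, sex and education are drawn independently
of group, so covariate adjustment is a no-op on average; a confounded
mode shifts age in AD to exercise the adjustment path.

What this generator does NOT emulate: hemodynamic response shape, spatial
autocorrelation of real fMRI, scanner noise physics, or tissue anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mapping import RoiSpec, sphere_mask
from .preprocess import Bold4D, ConfoundSet

__all__ = [
    "GROUPS",
    "PlantedRoi",
    "ScoreCoupling",
    "CohortConfig",
    "SubjectData",
    "generate_voxel_signal",
    "generate_subject",
    "generate_cohort",
    "default_affine",
]

GROUPS = ("NC", "EMCI", "LMCI", "AD")


@dataclass(frozen=True)
class PlantedRoi:
    """A sphere whose pink weight differs by group."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0
    group_weights: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.90, "EMCI": 0.75, "LMCI": 0.60, "AD": 0.45}
    )

    def as_roi_spec(self) -> RoiSpec:
        return RoiSpec(self.name, self.center_mm, self.radius_mm)


@dataclass(frozen=True)
class ScoreCoupling:
    """score = intercept + slope * c + Normal(0, noise_sd), clipped."""

    intercept: float
    slope: float
    noise_sd: float
    lo: float
    hi: float
    integer: bool = False

    def draw(self, c: float, rng: np.random.Generator) -> float:
        val = self.intercept + self.slope * c + rng.normal(0.0, self.noise_sd)
        val = float(np.clip(val, self.lo, self.hi))
        return float(round(val)) if self.integer else val


def _default_rois() -> tuple[PlantedRoi, ...]:
    return (PlantedRoi("planted", (0.0, 0.0, 0.0)),)


def _default_scores() -> dict[str, ScoreCoupling]:
    # slopes chosen so the group means echo the familiar clinical pattern:
    # MMSE ~29 in NC falling toward ~20 in AD; FAQ/CDR rising with severity
    return {
        "MMSE": ScoreCoupling(10.0, 21.0, 2.0, 0, 30, integer=True),
        "FAQ": ScoreCoupling(26.0, -28.0, 3.0, 0, 30, integer=True),
        "CDR": ScoreCoupling(2.3, -2.25, 0.15, 0.0, 3.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 30, "EMCI": 33, "LMCI": 32, "AD": 29}
    )
    shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 140
    n_dummy: int = 10
    tr_seconds: float = 3.0
    background_weight: float = 0.60
    rois: tuple[PlantedRoi, ...] = field(default_factory=_default_rois)
    subject_weight_sd: float = 0.05
    scores: dict[str, ScoreCoupling] = field(default_factory=_default_scores)
    gmv_intercept: float = 4.0
    gmv_slope: float = 3.0
    gmv_noise_sd: float = 0.4
    confound_amplitude: float = 0.8
    dummy_offset: float = 100.0
    ar1_mode: bool = False  # alternative complexity model (AR(1) coefficient = w)
    confounded_age: bool = False

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least 2 subjects")
        for roi in self.rois:
            if any(not 0 <= w <= 1 for w in roi.group_weights.values()):
                raise ValueError("pink weights must lie in [0, 1]")
        if not 0 <= self.background_weight <= 1:
            raise ValueError("background_weight must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def null(self) -> "CohortConfig":
        """Copy with every planted weight set to the background weight."""
        from dataclasses import replace

        rois = tuple(
            PlantedRoi(
                r.name,
                r.center_mm,
                r.radius_mm,
                {g: self.background_weight for g in GROUPS},
            )
            for r in self.rois
        )
        return replace(self, rois=rois)


def default_affine(config: CohortConfig) -> np.ndarray:
    """Isotropic affine with the mm origin at the grid center."""
    v = config.voxel_size_mm
    aff = np.diag([v, v, v, 1.0])
    aff[:3, 3] = -v * (np.asarray(config.shape) - 1) / 2.0
    return aff


def _pink_noise(
    rng: np.random.Generator, n_series: int, n: int, dtype=np.float64
) -> np.ndarray:
    """Spectral-synthesis 1/f noise: power ~ 1/f, random phases, unit SD."""
    n_freq = n // 2 + 1
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(n_freq, dtype=dtype)
    amp[1:] = freqs[1:] ** -0.5
    spec = amp * (
        rng.standard_normal((n_series, n_freq), dtype=dtype)
        + 1j * rng.standard_normal((n_series, n_freq), dtype=dtype)
    )
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _white_noise(
    rng: np.random.Generator, n_series: int, n: int, dtype=np.float64
) -> np.ndarray:
    x = rng.standard_normal((n_series, n), dtype=dtype)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _ar1_noise(rng: np.random.Generator, phi: np.ndarray, n: int) -> np.ndarray:
    """AR(1) series with per-row coefficient phi, standardized."""
    n_series = phi.shape[0]
    eps = rng.standard_normal((n_series, n + 50))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    for t in range(1, eps.shape[1]):
        x[:, t] = phi * x[:, t - 1] + eps[:, t]
    x = x[:, 50:]
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def _mix_signals(
    rng: np.random.Generator,
    weights: np.ndarray,
    n: int,
    ar1: bool = False,
    dtype=np.float64,
) -> np.ndarray:
    """Standardized weight*pink + (1-weight)*white, rows = voxels."""
    if ar1:
        return _ar1_noise(rng, weights, n).astype(dtype)
    nv = weights.shape[0]
    pink = _pink_noise(rng, nv, n, dtype=dtype)
    white = _white_noise(rng, nv, n, dtype=dtype)
    w = weights.astype(dtype)[:, None]
    x = w * pink + (1.0 - w) * white
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_voxel_signal(
    weight: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """One standardized pink/white mixture series (pink weight ``weight``)."""
    if not 0 <= weight <= 1:
        raise ValueError("weight must lie in [0, 1]")
    if n < 20:
        raise ValueError("n must be >= 20")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return _mix_signals(rng, np.array([float(weight)]), n)[0]


def _make_confounds(
    rng: np.random.Generator, n_t: int, tr: float
) -> pd.DataFrame:
    t = np.arange(n_t) * tr
    cols = {}
    # slow global drift: linear ramp + two slow sinusoids
    cols["global_signal"] = (
        0.6 * (t / t[-1] - 0.5)
        + 0.5 * np.sin(2 * np.pi * t / (t[-1] * 0.9) + rng.uniform(0, 2 * np.pi))
        + 0.3 * np.sin(2 * np.pi * t / (t[-1] * 0.37) + rng.uniform(0, 2 * np.pi))
    )
    for i in range(6):  # pseudo-motion: smoothed random walks
        w = np.cumsum(rng.standard_normal(n_t))
        w = np.convolve(w, np.ones(5) / 5.0, mode="same")
        cols[f"motion_{i + 1}"] = (w - w.mean()) / (w.std() + 1e-12)
    for name in ("csf", "wm"):
        s = _mix_signals(rng, np.array([0.7]), n_t)[0]
        cols[name] = s
    return pd.DataFrame(cols)


@dataclass
class SubjectData:
    subject_id: str
    group: str
    bold: Bold4D
    confounds: ConfoundSet
    covariates: dict[str, float]
    scores: dict[str, float]
    gmv: dict[str, float]
    planted_weight: float


def _roi_voxel_masks(config: CohortConfig, affine: np.ndarray):
    return {
        roi.name: sphere_mask(config.shape, affine, roi.as_roi_spec())
        for roi in config.rois
    }


def generate_subject(
    config: CohortConfig,
    group: str,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "",
) -> SubjectData:
    """One subject: BOLD volume (dummies included), confounds, covariates
    and clinical scores, all derived deterministically from the seed."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    ss = (
        subject_seed
        if isinstance(subject_seed, np.random.SeedSequence)
        else np.random.SeedSequence(subject_seed)
    )
    rng = np.random.default_rng(ss)
    affine = default_affine(config)
    n_vox = int(np.prod(config.shape))
    n_t = config.n_timepoints

    weights = np.full(n_vox, config.background_weight)
    roi_masks = _roi_voxel_masks(config, affine)
    subject_weights = {}
    for roi in config.rois:
        w = roi.group_weights[group] + rng.normal(0.0, config.subject_weight_sd)
        w = float(np.clip(w, 0.0, 1.0))
        subject_weights[roi.name] = w
        weights[roi_masks[roi.name].ravel()] = w
    c = float(np.mean(list(subject_weights.values())))

    # bulk voxel synthesis runs in float32: the volumes are stored as
    # float32 anyway and the entropy contrast is far above that precision
    data = _mix_signals(rng, weights, n_t, ar1=config.ar1_mode,
                        dtype=np.float32)
    conf = _make_confounds(rng, n_t, config.tr_seconds)
    loadings = rng.normal(
        0.0, config.confound_amplitude, (n_vox, conf.shape[1])
    ).astype(np.float32)
    data = data + loadings @ conf.to_numpy(dtype=np.float32).T
    data[:, : config.n_dummy] += np.float32(config.dummy_offset)

    vol = Bold4D(
        data=data.reshape(config.shape + (n_t,)),
        affine=affine,
        tr_seconds=config.tr_seconds,
    )
    # pipeline consumes confound rows for the retained volumes only
    confounds = ConfoundSet(conf.iloc[config.n_dummy:].reset_index(drop=True))

    age_mu = 76.0 if (config.confounded_age and group == "AD") else 73.0
    covariates = {
        "age": float(np.clip(rng.normal(age_mu, 6.5), 55.0, 92.0)),
        "sex": int(rng.integers(0, 2)),
        "education": float(np.clip(rng.normal(16.0, 2.3), 8.0, 20.0)),
    }
    scores = {name: sc.draw(c, rng) for name, sc in config.scores.items()}
    gmv = {
        roi.name: float(
            config.gmv_intercept
            + config.gmv_slope * subject_weights[roi.name]
            + rng.normal(0.0, config.gmv_noise_sd)
        )
        for roi in config.rois
    }
    return SubjectData(
        subject_id=subject_id,
        group=group,
        bold=vol,
        confounds=confounds,
        covariates=covariates,
        scores=scores,
        gmv=gmv,
        planted_weight=c,
    )


def iter_subject_seeds(config: CohortConfig, master_seed: int):
    """Deterministic (subject_id, group, SeedSequence) triples."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(config.n_subjects)
    k = 0
    for group in GROUPS:
        for i in range(config.group_sizes.get(group, 0)):
            yield f"sub-{group}{i + 1:03d}", group, children[k]
            k += 1


def generate_cohort(
    config: CohortConfig,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[SubjectData] | None]:
    """Generate the full cohort.

    With ``out_dir`` the subjects are written to disk (NIfTI + confound
    CSVs + manifest CSV + config YAML) and only the manifest is returned;
    without it, all subjects are returned in memory alongside the manifest.
    """
    import nibabel as nib

    rows = []
    subjects: list[SubjectData] | None = None if out_dir else []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "func").mkdir(parents=True, exist_ok=True)
    for sid, group, child in iter_subject_seeds(config, master_seed):
        subj = generate_subject(config, group, child, subject_id=sid)
        row = {
            "id": sid,
            "group": group,
            **subj.covariates,
            **subj.scores,
            **{f"gmv_{k}": v for k, v in subj.gmv.items()},
        }
        if out_dir is not None:
            img_path = out_dir / "func" / f"{sid}_bold.nii.gz"
            conf_path = out_dir / "func" / f"{sid}_confounds.csv"
            nib.save(
                nib.Nifti1Image(subj.bold.data, subj.bold.affine), img_path
            )
            subj.confounds.regressors.to_csv(conf_path, index=False)
            row["path"] = str(img_path)
            row["confounds_path"] = str(conf_path)
        else:
            subjects.append(subj)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        cfg = _plain(asdict(config))
        cfg["master_seed"] = master_seed
        with open(out_dir / "cohort_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, default_flow_style=False)
    return manifest, subjects


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
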