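"""Temporal conditioning of BOLD voxel time series.

The entropy estimator sees each voxel only after a fixed chain of
per-voxel operations: drop initial dummy volumes, remove the linear
trend, regress out nuisance signals (global signal, motion, CSF, WM),
band-pass filter, and standardize to zero mean / unit SD.  Standardization
is last, so every analyzable voxel enters entropy mapping with population
SD exactly 1 and the fractional similarity radius r equals the absolute
tolerance r_abs.

Spatial preprocessing (slice timing, realignment, template normalization,
smoothing) is assumed to have been done upstream; volumes arrive here
already on a common grid.

Band-pass caveat: with a repetition time of 3 s the Nyquist frequency is
~0.167 Hz, below the nominal 0.2 Hz upper edge of the standard
0.01-0.2 Hz resting-state band.  A requested upper edge at or above
Nyquist is clipped to 0.99 x Nyquist (effectively a high-pass at the lower
edge) and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "Bold4D",
    "ConfoundSet",
    "PreprocessConfig",
    "drop_initial_volumes",
    "detrend_linear",
    "regress_confounds",
    "bandpass_filter",
    "standardize",
    "preprocess_subject",
]

log = logging.getLogger(__name__)


@dataclass
class Bold4D:
    """A subject's 4-D BOLD volume: (x, y, z, t) data, voxel-to-mm affine
    and repetition time in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_matrix(self) -> np.ndarray:
        """(n_voxels, t) float64 view of the volume, C voxel order."""
        return self.data.reshape(-1, self.n_timepoints).astype(np.float64)

    def with_data(self, matrix: np.ndarray) -> "Bold4D":
        data = np.asarray(matrix).reshape(self.spatial_shape + (-1,))
        return replace(self, data=data)


@dataclass
class ConfoundSet:
    """Labeled per-volume nuisance regressors (one row per retained volume)."""

    regressors: pd.DataFrame

    def __post_init__(self) -> None:
        self.regressors = pd.DataFrame(self.regressors)

    @property
    def n_rows(self) -> int:
        return len(self.regressors)

    @property
    def columns(self) -> list[str]:
        return list(self.regressors.columns)

    def matrix(self) -> np.ndarray:
        return self.regressors.to_numpy(dtype=float)

    @classmethod
    def empty(cls, n_rows: int) -> "ConfoundSet":
        return cls(pd.DataFrame(index=range(n_rows)))


@dataclass(frozen=True)
class PreprocessConfig:
    n_drop: int = 10
    f_low_hz: float = 0.01
    f_high_hz: float = 0.2
    detrend: bool = True
    standardize: bool = True


def drop_initial_volumes(vol: Bold4D, n_drop: int) -> Bold4D:
    """Remove the first ``n_drop`` volumes (scanner equilibration dummies)."""
    n_drop = int(n_drop)
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= vol.n_timepoints:
        raise ValueError(
            f"cannot drop {n_drop} of {vol.n_timepoints} volumes"
        )
    return replace(vol, data=vol.data[..., n_drop:])


def _check_series_matrix(series: np.ndarray, min_len: int = 2) -> np.ndarray:
    """Accept a 1-D series or (n_series, t) matrix; return 2-D float64."""
    x = np.asarray(series, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D input, got shape {x.shape}")
    if x.shape[1] < min_len:
        raise ValueError(f"need at least {min_len} time points")
    return x


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """OLS residual after regressing on [intercept, time index].

    Accepts a single series or a (n_series, t) matrix (fit per row).
    """
    x = np.asarray(series, dtype=np.float64)
    mat = _check_series_matrix(x, min_len=3)
    t = mat.shape[1]
    design = np.column_stack([np.ones(t), np.arange(t, dtype=np.float64)])
    resid = _ols_residual(mat, design)
    return resid[0] if x.ndim == 1 else resid


def _ols_residual(mat: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Row-wise OLS residuals via an orthonormal basis of the design."""
    q = np.linalg.qr(design)[0]
    return mat - (mat @ q) @ q.T


class DegenerateDesignError(ValueError):
    """Raised when a confound design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "confound design is rank deficient; offending columns: "
            + ", ".join(columns)
        )


def regress_confounds(series: np.ndarray, confounds: ConfoundSet) -> np.ndarray:
    """OLS residual after regressing on [intercept | confound columns].

    With an empty confound set this reduces to demeaning.  The design must
    have full column rank; near-duplicate columns raise
    :class:`DegenerateDesignError` naming the offenders.
    """
    x = np.asarray(series, dtype=np.float64)
    mat = _check_series_matrix(x)
    t = mat.shape[1]
    if confounds.n_rows != t:
        raise ValueError(
            f"confound rows ({confounds.n_rows}) != time points ({t})"
        )
    C = confounds.matrix()
    design = np.column_stack([np.ones(t), C]) if C.size else np.ones((t, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank on top of the preceding ones
        bad = []
        for k in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : k + 1]) == np.linalg.matrix_rank(
                design[:, :k]
            ):
                bad.append(confounds.columns[k - 1])
        raise DegenerateDesignError(bad)
    resid = _ols_residual(mat, design)
    return resid[0] if x.ndim == 1 else resid


_warned_bands: set[tuple[float, float]] = set()
_filter_ops: dict[tuple, np.ndarray] = {}


def bandpass_filter(
    series: np.ndarray,
    tr_seconds: float,
    f_low: float,
    f_high: float,
    *,
    clip_to_nyquist: bool = True,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 2 per pass, forward-backward).

    ``f_low = 0`` degenerates to a low-pass.  If ``f_high`` reaches the
    Nyquist frequency it is clipped to 0.99 x Nyquist when
    ``clip_to_nyquist`` is set, otherwise the call is rejected.
    """
    x = np.asarray(series, dtype=np.float64)
    mat = _check_series_matrix(x, min_len=12)
    nyq = 1.0 / (2.0 * tr_seconds)
    if not 0 <= f_low < f_high:
        raise ValueError(f"need 0 <= f_low < f_high, got ({f_low}, {f_high})")
    if f_high >= nyq:
        if not clip_to_nyquist:
            raise ValueError(
                f"f_high {f_high} Hz is at/above Nyquist {nyq:.4g} Hz"
            )
        f_high_eff = 0.99 * nyq
        key = (round(f_high, 6), round(nyq, 6))
        if key not in _warned_bands:  # one warning per band, not per voxel
            _warned_bands.add(key)
            log.warning(
                "band upper edge %.4g Hz >= Nyquist %.4g Hz; clipping to %.4g Hz",
                f_high,
                nyq,
                f_high_eff,
            )
    else:
        f_high_eff = f_high
    if f_low <= 0:
        b, a = butter(2, f_high_eff / nyq, btype="low")
    else:
        b, a = butter(2, [f_low / nyq, f_high_eff / nyq], btype="band")
    # zero-phase filtering with fixed padding is linear in the input, so
    # one cached (t x t) operator turns a whole voxel matrix into a
    # single BLAS product instead of t sequential IIR sweeps per voxel
    key = (mat.shape[1], round(f_low, 9), round(f_high_eff, 9),
           round(tr_seconds, 9))
    op = _filter_ops.get(key)
    if op is None:
        op = filtfilt(b, a, np.eye(mat.shape[1]), axis=1)
        _filter_ops[key] = op
    out = mat @ op
    return out[0] if x.ndim == 1 else out


def standardize(series: np.ndarray) -> np.ndarray:
    """Rescale to mean 0 and population SD 1.

    For a single series, zero variance is an error; for a matrix,
    zero-variance rows come back as NaN (non-analyzable voxels) and the
    caller is expected to mask them.
    """
    x = np.asarray(series, dtype=np.float64)
    mat = _check_series_matrix(x)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    if x.ndim == 1:
        if sd[0, 0] <= 0:
            raise ValueError("zero-variance series cannot be standardized")
        return ((mat - mu) / sd)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (mat - mu) / sd
    out[(sd <= 0).ravel() | ~np.isfinite(sd).ravel()] = np.nan
    return out


def preprocess_subject(
    vol: Bold4D,
    confounds: ConfoundSet | None = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[Bold4D, np.ndarray]:
    """Full per-subject temporal chain.

    Order: drop dummies -> detrend -> nuisance regression -> band-pass ->
    standardize.  Returns the preprocessed volume and a boolean
    analyzability mask (False where the voxel was constant or non-finite);
    non-analyzable voxels are NaN in the output.
    """
    vol = drop_initial_volumes(vol, config.n_drop)
    mat = vol.to_matrix()
    analyzable = np.all(np.isfinite(mat), axis=1) & (mat.std(axis=1) > 0)
    n_bad = int((~analyzable).sum())
    if n_bad:
        log.info("excluding %d non-analyzable voxel(s)", n_bad)
    work = mat[analyzable]
    if config.detrend:
        work = detrend_linear(work)
    if confounds is None:
        confounds = ConfoundSet.empty(vol.n_timepoints)
    work = regress_confounds(work, confounds)
    work = bandpass_filter(work, vol.tr_seconds, config.f_low_hz, config.f_high_hz)
    if config.standardize:
        work = standardize(work)
    # filtering can annihilate a voxel that was pure trend/confound
    still_ok = np.all(np.isfinite(work), axis=1)
    out = np.full_like(mat, np.nan)
    idx = np.flatnonzero(analyzable)
    out[idx[still_ok]] = work[still_ok]
    mask = np.zeros(mat.shape[0], dtype=bool)
    mask[idx[still_ok]] = True
    return vol.with_data(out), mask.reshape(vol.spatial_shape)
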