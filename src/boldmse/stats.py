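"""Group inference on MSE maps.

Covariate-adjusted voxelwise ANOVA, permutation cluster correction,
fivefold cross-validated ROI selection, Bonferroni post-hoc pairwise
tests, and Spearman correlations with clinical scores.

The omnibus test per voxel is the general-linear-model partial F comparing
[intercept, age, sex, education, group dummies] against
[intercept, age, sex, education]; p-values come from F(g-1, n-g-c).
Cluster-level multiple-comparison control is by label permutation: the
ANOVA is recomputed under random relabelings (Freedman-Lane residual
permutation, so covariates stay fixed) and observed face-connected
supra-threshold clusters are compared against the permutation null of the
maximum cluster size.  This is a deliberate, exact-level substitution for
parametric Gaussian-random-field correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mapping import MseMapStack, RoiSpec

__all__ = [
    "GROUPS",
    "FMapResult",
    "Cluster",
    "anova_designs",
    "voxelwise_anova",
    "cluster_correct",
    "stratified_folds",
    "fivefold_roi_selection",
    "posthoc_pairwise",
    "spearman_clinical",
    "correlation_table",
]

log = logging.getLogger(__name__)

GROUPS = ("NC", "EMCI", "LMCI", "AD")
COVARIATES = ("age", "sex", "education")


def anova_designs(
    manifest: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATES,
) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) design matrices: [1 | covs | group dummies] and
    [1 | covs], with treatment coding of group."""
    n = len(manifest)
    covs = (
        manifest.loc[:, list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((n, 0))
    )
    if not np.all(np.isfinite(covs)):
        raise ValueError("covariates contain non-finite values")
    groups = manifest["group"].to_numpy()
    levels = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    dummies = np.column_stack(
        [(groups == g).astype(float) for g in levels[1:]]
    ) if len(levels) > 1 else np.empty((n, 0))
    reduced = np.column_stack([np.ones(n), covs])
    full = np.column_stack([reduced, dummies])
    for X, nm in ((reduced, "reduced"), (full, "full")):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"{nm} design matrix is rank deficient")
    return full, reduced


@dataclass
class FMapResult:
    f: np.ndarray  # per-voxel F, NaN where not computable
    p: np.ndarray
    df1: int
    df2: int


def _partial_f(
    Y: np.ndarray, qf: np.ndarray, qr: np.ndarray, df1: int, df2: int
) -> np.ndarray:
    """Partial F per column of Y given orthonormal bases of both designs."""
    ss_y = np.einsum("ij,ij->j", Y, Y)
    rss_f = ss_y - np.einsum("ij,ij->j", qf.T @ Y, qf.T @ Y)
    rss_r = ss_y - np.einsum("ij,ij->j", qr.T @ Y, qr.T @ Y)
    rss_f = np.maximum(rss_f, 0.0)
    num = np.maximum(rss_r - rss_f, 0.0) / df1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / (rss_f / df2)
    f[~np.isfinite(f)] = np.nan
    return f


def voxelwise_anova(
    Y: np.ndarray,
    manifest: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATES,
) -> FMapResult:
    """Covariate-adjusted group F test at every voxel.

    ``Y`` is (n_subjects, n_voxels); voxels with a missing value in any
    subject are NaN in the output.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != len(manifest):
        raise ValueError("Y rows must match manifest length")
    counts = manifest["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    full, reduced = anova_designs(manifest, covariates)
    df1 = full.shape[1] - reduced.shape[1]
    df2 = len(manifest) - full.shape[1]
    qf = np.linalg.qr(full)[0]
    qr = np.linalg.qr(reduced)[0]
    ok = np.all(np.isfinite(Y), axis=0)
    f = np.full(Y.shape[1], np.nan)
    f[ok] = _partial_f(Y[:, ok], qf, qr, df1, df2)
    p = np.full_like(f, np.nan)
    good = np.isfinite(f)
    p[good] = sps.f.sf(f[good], df1, df2)
    return FMapResult(f=f, p=p, df1=df1, df2=df2)


@dataclass
class Cluster:
    voxels: np.ndarray  # flat indices into the map
    size: int
    peak_index: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_f: float
    p_corrected: float


def _label_clusters(supra: np.ndarray) -> tuple[np.ndarray, int]:
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    return ndimage.label(supra, structure=struct)


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = _label_clusters(supra)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(
    Y: np.ndarray,
    manifest: pd.DataFrame,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[Cluster]:
    """Permutation max-cluster-size correction of the voxelwise ANOVA.

    Returns the surviving clusters (corrected p < ``cluster_p``), largest
    first.  An empty list is a valid outcome.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Y = np.asarray(Y, dtype=np.float64)
    n = Y.shape[0]
    full, reduced = anova_designs(manifest)
    df1 = full.shape[1] - reduced.shape[1]
    df2 = n - full.shape[1]
    qf = np.linalg.qr(full)[0]
    qr = np.linalg.qr(reduced)[0]
    f_crit = sps.f.isf(voxel_p, df1, df2)

    ok = np.all(np.isfinite(Y), axis=0)
    Yok = Y[:, ok]
    f_obs = np.full(Y.shape[1], np.nan)
    f_obs[ok] = _partial_f(Yok, qf, qr, df1, df2)
    supra = (f_obs > f_crit) & np.isfinite(f_obs)
    labels, n_clust = _label_clusters(supra.reshape(shape))
    if n_clust == 0:
        return []

    # Freedman-Lane: permute reduced-model residuals, keep reduced fit
    fitted = qr @ (qr.T @ Yok)
    resid = Yok - fitted
    null_max = np.empty(n_perm, dtype=np.int64)
    fshape_supra = np.zeros(Y.shape[1], dtype=bool)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = fitted + resid[perm]
        fp = _partial_f(Yp, qf, qr, df1, df2)
        fshape_supra[:] = False
        fshape_supra[ok] = (fp > f_crit) & np.isfinite(fp)
        null_max[b] = _max_cluster_size(fshape_supra.reshape(shape))

    clusters = []
    flat_labels = labels.ravel()
    for c in range(1, n_clust + 1):
        vox = np.flatnonzero(flat_labels == c)
        size = vox.size
        p_corr = float((1 + np.sum(null_max >= size)) / (n_perm + 1))
        if p_corr >= cluster_p:
            continue
        peak_flat = vox[np.nanargmax(f_obs[vox])]
        peak_idx = np.unravel_index(peak_flat, shape)
        peak_mm = (np.asarray(affine) @ np.array([*peak_idx, 1.0]))[:3]
        clusters.append(
            Cluster(
                voxels=vox,
                size=int(size),
                peak_index=tuple(int(i) for i in peak_idx),
                peak_mm=tuple(float(v) for v in peak_mm),
                peak_f=float(f_obs[peak_flat]),
                p_corrected=p_corr,
            )
        )
    clusters.sort(key=lambda cl: -cl.size)
    return clusters


def stratified_folds(
    groups: np.ndarray | pd.Series,
    n_folds: int = 5,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Group-stratified folds with sizes as equal as possible.

    Each group is shuffled and split into ``n // n_folds`` per fold;
    remainder subjects go one-by-one to the currently smallest folds, so
    124 subjects over 5 folds give sizes {24, 25} with every group in
    every fold.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    groups = np.asarray(groups)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    levels = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    for g in levels:
        idx = np.flatnonzero(groups == g)
        if idx.size < n_folds:
            log.warning(
                "group %s has %d subjects (< %d folds); rebalancing",
                g, idx.size, n_folds,
            )
        idx = rng.permutation(idx)
        base = idx.size // n_folds
        pos = 0
        for f in range(n_folds):
            folds[f].extend(idx[pos : pos + base].tolist())
            pos += base
        for extra in idx[pos:]:
            smallest = min(range(n_folds), key=lambda f: (len(folds[f]), f))
            folds[smallest].append(int(extra))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class FoldResult:
    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    rois: list[RoiSpec]
    clusters: list[Cluster]


def fivefold_roi_selection(
    Y: np.ndarray,
    manifest: pd.DataFrame,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    roi_radius_mm: float = 8.0,
    n_folds: int = 5,
) -> list[FoldResult]:
    """Cross-validated ROI definition.

    For each fold, the ANOVA + cluster correction runs on the other folds
    and surviving cluster peaks become sphere ROIs; the held-out fold is
    reserved for unbiased ROI-value extraction downstream.
    """
    if len(manifest) < 10:
        raise ValueError("need at least 10 subjects for fold selection")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(manifest["group"], n_folds=n_folds, seed=rng)
    results = []
    all_idx = np.arange(len(manifest))
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        clusters = cluster_correct(
            Y[train_idx],
            manifest.iloc[train_idx].reset_index(drop=True),
            shape,
            affine,
            voxel_p=voxel_p,
            cluster_p=cluster_p,
            n_perm=n_perm,
            seed=rng,
        )
        rois = [
            RoiSpec(f"fold{k}_cluster{i + 1}", cl.peak_mm, roi_radius_mm)
            for i, cl in enumerate(clusters)
        ]
        results.append(
            FoldResult(
                fold=k,
                train_index=train_idx,
                test_index=test_idx,
                rois=rois,
                clusters=clusters,
            )
        )
    return results


def posthoc_pairwise(
    values: np.ndarray | pd.Series,
    manifest: pd.DataFrame,
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Bonferroni-adjusted two-sample t tests on all six group pairs.

    Tests run on covariate-adjusted residuals for consistency with the
    omnibus model; raw p-values are multiplied by the number of pairs and
    capped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = manifest["group"].to_numpy()
    if adjust_covariates:
        covs = manifest.loc[:, list(COVARIATES)].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(values)), covs])
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        values = values - X @ coef
    levels = [g for g in GROUPS if g in set(groups)] or sorted(set(groups))
    pairs = [
        (a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]
    ]
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = values[groups == a], values[groups == b]
        if min(va.size, vb.size) < 2:
            rows.append(
                {"group_a": a, "group_b": b, "t": np.nan, "p_raw": np.nan,
                 "p_bonferroni": np.nan, "skipped": True}
            )
            continue
        t, p = sps.ttest_ind(va, vb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(va.mean()),
                "mean_b": float(vb.mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": float(min(1.0, p * n_pairs)),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def spearman_clinical(
    roi_values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    A constant score or value vector makes rho undefined -> (nan, nan).
    """
    x = np.asarray(roi_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need >= 5 paired observations")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector in Spearman correlation; undefined rho")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(
    roi_values: pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Spearman correlations of every ROI column against every score
    column, adjusted within each score family across ROIs.

    ``method`` is any statsmodels ``multipletests`` method
    ("fdr_bh" default, "bonferroni" for the stricter variant).
    """
    rows = []
    for score in scores.columns:
        fam = []
        for roi in roi_values.columns:
            rho, p = spearman_clinical(roi_values[roi], scores[score])
            fam.append({"score": score, "roi": roi, "rho": rho, "p_raw": p})
        ps = np.array([r["p_raw"] for r in fam])
        ok = np.isfinite(ps)
        adj = np.full_like(ps, np.nan)
        if ok.any():
            adj[ok] = multipletests(ps[ok], method=method)[1]
        for r, pa in zip(fam, adj):
            r["p_adjusted"] = float(pa) if np.isfinite(pa) else np.nan
        rows.extend(fam)
    return pd.DataFrame(rows)
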