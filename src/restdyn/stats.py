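"""Voxelwise group statistics: two-sample t-maps, cluster-extent
thresholding, FDR, across-subject correlation maps and ROI statistics.

The map-level false discovery rate at a fixed voxelwise threshold p0 is
the plug-in estimate q = p0 * m / #{p_i <= p0} (m = in-mask voxel count),
an upper bound on the expected fraction of suprathreshold voxels that are
false positives; per-voxel Benjamini-Hochberg step-up q values are
computed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .geometry import BinaryMask, VolumeGeometry, VolumeMap

__all__ = [
    "StatThresholds",
    "StatMap",
    "ROICorrelation",
    "two_sample_t_map",
    "threshold_clusters",
    "fdr_at_threshold",
    "bh_q",
    "spearman_map",
    "pearson_roi",
    "sign_test",
    "curve_table",
]


@dataclass(frozen=True)
class StatThresholds:
    """Voxel p threshold, minimum cluster extent and connectivity rule
    (6 = faces only, 18 = +edges, 26 = +corners)."""

    p_threshold: float = 0.01
    min_cluster_voxels: int = 20
    connectivity: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p threshold must be in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("minimum cluster size must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass(frozen=True)
class StatMap:
    """Per-voxel effect (group mean difference), t, two-sided p, BH q and
    cluster labels, plus the map-level FDR at the chosen threshold."""

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    geometry: VolumeGeometry
    mask: np.ndarray
    cluster_labels: np.ndarray = None  # type: ignore[assignment]
    q_at_threshold: float = float("nan")
    df: float = float("nan")

    def __post_init__(self) -> None:
        if self.cluster_labels is None:
            object.__setattr__(
                self, "cluster_labels", np.zeros(self.geometry.shape, dtype=int)
            )


@dataclass(frozen=True)
class ROICorrelation:
    """Across-subject correlation of two ROI-mean quantities."""

    r: float
    p: float
    n: int
    method: str = "pearson"


def _stack(maps: Sequence[VolumeMap]) -> tuple[np.ndarray, VolumeGeometry]:
    geom = maps[0].geometry
    if any(m.geometry != geom for m in maps):
        raise ValueError("maps must share one geometry")
    return np.stack([m.data for m in maps]), geom


def two_sample_t_map(
    group_a: Sequence[VolumeMap],
    group_b: Sequence[VolumeMap],
    mask: BinaryMask = None,
) -> StatMap:
    """Pooled-variance Student t per voxel (df = nA + nB - 2), two-sided p,
    effect = mean(A) - mean(B).  Voxels with zero pooled variance get
    t = 0, p = 1 (flagged via a warning)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    a, geom = _stack(group_a)
    b, _ = _stack(group_b)
    if group_b[0].geometry != geom:
        raise ValueError("groups must share one geometry")
    na, nb = len(group_a), len(group_b)
    df = na + nb - 2
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - mean_a) ** 2).sum(axis=0) + ((b - mean_b) ** 2).sum(axis=0)
    pooled = ss / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    effect = mean_a - mean_b
    degenerate = se == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} voxels with zero pooled variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, effect / np.where(degenerate, 1.0, se))
    p = np.where(degenerate, 1.0, 2.0 * spstats.t.sf(np.abs(t), df))
    mask_arr = (
        mask.data if mask is not None else np.ones(geom.shape, dtype=bool)
    )
    q = np.full(geom.shape, np.nan)
    q[mask_arr] = bh_q(p[mask_arr])
    return StatMap(
        effect=effect, t=t, p=p, q=q, geometry=geom, mask=mask_arr, df=float(df)
    )


def threshold_clusters(stat_map: StatMap, thresholds: StatThresholds) -> StatMap:
    """Connected components among suprathreshold (p < p0) voxels, labeled
    separately per sign of t, components below the minimum extent removed,
    surviving clusters labeled 1, 2, ... in decreasing size order."""
    supra = (stat_map.p < thresholds.p_threshold) & stat_map.mask
    structure = thresholds.structure()
    clusters: list[np.ndarray] = []
    for sign_sel in (stat_map.t > 0, stat_map.t < 0):
        labeled, n = ndimage.label(supra & sign_sel, structure=structure)
        for lab in range(1, n + 1):
            comp = labeled == lab
            if comp.sum() >= thresholds.min_cluster_voxels:
                clusters.append(comp)
    clusters.sort(key=lambda c: int(c.sum()), reverse=True)
    labels = np.zeros(stat_map.geometry.shape, dtype=int)
    for i, comp in enumerate(clusters, start=1):
        labels[comp] = i
    q_thr = fdr_at_threshold(
        stat_map.p[stat_map.mask], thresholds.p_threshold, warn_empty=False
    )
    return StatMap(
        effect=stat_map.effect,
        t=stat_map.t,
        p=stat_map.p,
        q=stat_map.q,
        geometry=stat_map.geometry,
        mask=stat_map.mask,
        cluster_labels=labels,
        q_at_threshold=q_thr,
        df=stat_map.df,
    )


def fdr_at_threshold(
    p_values: np.ndarray, p0: float, warn_empty: bool = True
) -> float:
    """Plug-in map-level FDR: q = p0 * m / #{p_i <= p0}, clipped to <= 1;
    NaN when no p value survives the threshold."""
    p_values = np.asarray(p_values, dtype=float).ravel()
    if p_values.size == 0 or np.any((p_values <= 0) | (p_values > 1)):
        raise ValueError("p values must lie in (0, 1]")
    m = p_values.size
    n_disc = int((p_values <= p0).sum())
    if n_disc == 0:
        if warn_empty:
            warnings.warn("no suprathreshold voxels; FDR undefined")
        return float("nan")
    return float(min(1.0, p0 * m / n_disc))


def bh_q(p_values: np.ndarray) -> np.ndarray:
    """Per-voxel Benjamini-Hochberg step-up q values (monotone, >= p)."""
    p_values = np.asarray(p_values, dtype=float).ravel()
    return multipletests(p_values, method="fdr_bh")[1]


def spearman_map(
    x_maps: Sequence[VolumeMap],
    y_maps: Sequence[VolumeMap],
    mask: BinaryMask = None,
) -> StatMap:
    """Voxelwise Spearman rank correlation across subjects.

    Average-rank ties; two-sided p from the t approximation with
    df = n - 2.  Voxels where either variable is constant across subjects
    are flagged NaN.
    """
    if len(x_maps) != len(y_maps):
        raise ValueError("x and y must cover the same subjects")
    n = len(x_maps)
    if n < 4:
        raise ValueError("need at least 4 subjects for a correlation map")
    x, geom = _stack(x_maps)
    y, _ = _stack(y_maps)
    if y_maps[0].geometry != geom:
        raise ValueError("x and y maps must share one geometry")
    xr = spstats.rankdata(x, axis=0)
    yr = spstats.rankdata(y, axis=0)
    xr = xr - xr.mean(axis=0)
    yr = yr - yr.mean(axis=0)
    sx = np.sqrt((xr**2).sum(axis=0))
    sy = np.sqrt((yr**2).sum(axis=0))
    degenerate = (sx == 0) | (sy == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxels with a constant variable; rho NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xr * yr).sum(axis=0) / (sx * sy)
    rho = np.where(degenerate, np.nan, np.clip(rho, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * spstats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1.0, 0.0, p))
    mask_arr = mask.data if mask is not None else np.ones(geom.shape, dtype=bool)
    valid = mask_arr & ~np.isnan(rho)
    q = np.full(geom.shape, np.nan)
    if valid.any():
        q[valid] = bh_q(p[valid])
    return StatMap(
        effect=rho, t=tstat, p=p, q=q, geometry=geom, mask=mask_arr, df=float(n - 2)
    )


def pearson_roi(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> ROICorrelation:
    """Across-subject correlation of two per-subject ROI means; two-tailed
    p from the t distribution with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance variable; correlation undefined")
        return ROICorrelation(r=float("nan"), p=float("nan"), n=x.size, method=method)
    if method == "pearson":
        res = spstats.pearsonr(x, y)
    elif method == "spearman":
        res = spstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ROICorrelation(
        r=float(res.statistic), p=float(res.pvalue), n=x.size, method=method
    )


def sign_test(differences: Sequence[float]) -> tuple[int, int, float]:
    """Two-sided exact sign test on paired differences.

    Returns (n_positive, n_nonzero, p).  Zero differences are dropped, the
    usual convention for the exact binomial sign test.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d) & (d != 0)]
    n_pos = int((d > 0).sum())
    n = int(d.size)
    if n == 0:
        return 0, 0, float("nan")
    p = spstats.binomtest(n_pos, n, 0.5).pvalue
    return n_pos, n, float(p)


def curve_table(
    axis: np.ndarray,
    rim: np.ndarray,
    mirror: np.ndarray,
    axis_name: str = "frequency_hz",
) -> pd.DataFrame:
    """Group mean and SEM per frequency/scale for rim and mirror ROIs.

    ``rim`` and ``mirror`` are (subjects, points) arrays of per-subject
    ROI-mean curves; SEM = SD / sqrt(n) with N-1 SD.
    """
    rim = np.asarray(rim, dtype=float)
    mirror = np.asarray(mirror, dtype=float)
    if rim.shape != mirror.shape or rim.ndim != 2:
        raise ValueError("rim and mirror must be (subjects, points) of equal shape")
    n = rim.shape[0]
    if rim.shape[1] != len(axis):
        raise ValueError("curves do not match the axis length")
    sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(n)  # noqa: E731
    return pd.DataFrame(
        {
            axis_name: np.asarray(axis),
            "rim_mean": rim.mean(axis=0),
            "rim_sem": sem(rim),
            "mirror_mean": mirror.mean(axis=0),
            "mirror_sem": sem(mirror),
            "n_subjects": n,
        }
    )
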