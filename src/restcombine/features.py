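"""Resting-state feature extraction: four local measures, five seed networks,
ROI-pair temporal correlation and pairwise Granger causality.

Local measures (per-voxel maps, reduced to ROI means over the atlas):

* **ALFF** — mean one-sided FFT amplitude over 0.01-0.1 Hz, computed on
  nuisance-regressed *uncensored* data, divided by the brain-wide mean.
* **ReHo** — Kendall's coefficient of concordance (W) of a voxel with its
  26 face/edge/corner neighbours, divided by the brain-wide mean.
* **VMHC** — Fisher-z Pearson correlation between a voxel and its
  mirror-symmetric counterpart across the first grid axis.
* **FCS** — mean Fisher-z correlation between a voxel and all other
  gray-matter voxels.

Network measures:

* five **seed networks** — Fisher-z correlation of every voxel with the
  pooled mean time course of a bilateral seed ROI pair, reduced to ROI means;
* **TC** — Fisher-z ROI-pair correlation matrix, lower triangle;
* **GC** — bivariate Granger F-statistics for all ordered ROI pairs, with
  the VAR order chosen by AIC, computed on *uncensored* cleaned data.

All correlations pass through the Fisher z-transform exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VoxelMap",
    "FeatureVector",
    "FeatureSet",
    "FEATURE_TYPE_ORDER",
    "LOCAL_MEASURES",
    "fisher_z",
    "alff",
    "kendall_w",
    "reho",
    "vmhc",
    "fcs",
    "seed_network",
    "roi_means",
    "roi_series",
    "temporal_correlation",
    "var_order_aic",
    "granger_f",
    "gc_matrix",
    "extract_features",
]

LOCAL_MEASURES = ("ALFF", "ReHo", "VMHC", "FCS")

#: Canonical order of the eleven feature types, used everywhere a fixed
#: ordering is required (concatenation, kernel lists, weight vectors).
FEATURE_TYPE_ORDER = (
    "ALFF", "ReHo", "VMHC", "FCS",
    "DMN", "ECN", "SN", "LN", "StrN",
    "TC", "GC",
)

_CLIP = 1.0 - 1e-7


@dataclass
class VoxelMap:
    """A per-voxel scalar field; non-brain voxels are NaN, not zero."""

    values: np.ndarray  # X x Y x Z, NaN outside the brain
    measure_tag: str


@dataclass
class FeatureVector:
    """Named per-subject feature values for one feature type."""

    feature_type: str
    names: tuple[str, ...]
    values: np.ndarray


@dataclass
class FeatureSet:
    """All extracted feature vectors for one subject."""

    subject_id: str
    label: int
    features: dict[str, FeatureVector]


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r), with |r| clipped to 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return float(out) if out.ndim == 0 else out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped N x T arrays.

    Rows with zero variance get correlation 0 (degenerate, warned by
    callers where relevant).
    """
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[denom == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# local measures
# ---------------------------------------------------------------------------

def alff(
    series4d: np.ndarray,
    atlas: np.ndarray,
    band: tuple[float, float] = (0.01, 0.1),
    tr_seconds: float = 2.0,
) -> VoxelMap:
    """Amplitude of low-frequency fluctuations, normalised to brain mean 1.

    Per voxel the one-sided FFT amplitude spectrum (square root of power)
    is averaged over the frequency bins inside ``band``; the DC bin is
    excluded.  The map is divided by the mean over brain voxels.
    """
    t = series4d.shape[-1]
    freqs = np.fft.rfftfreq(t, tr_seconds)
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError(f"no frequency bin inside band {band} for T={t}")
    brain = atlas > 0
    flat = series4d.reshape(-1, t)[brain.reshape(-1)]
    amp = np.abs(np.fft.rfft(flat, axis=1))[:, in_band].mean(axis=1)
    values = np.full(atlas.shape, np.nan)
    mean_amp = amp.mean()
    values[brain] = amp / mean_amp if mean_amp > 0 else 0.0
    return VoxelMap(values=values, measure_tag="ALFF")


def kendall_w(ranked_series: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of m time series of length T.

    Each series ranks the T time points (average ranks on ties); with
    rank sums R_t, W = 12 * sum_t (R_t - m(T+1)/2)^2 / (m^2 (T^3 - T)).
    Constant input (all ties everywhere) is degenerate: returns 0 with a
    warning.
    """
    x = np.asarray(ranked_series, dtype=float)
    m, t = x.shape
    if m < 2 or t < 2:
        raise ValueError("need m >= 2 series and T >= 2 time points")
    if np.all(x.std(axis=1) == 0):
        warnings.warn("all series constant; W undefined, returning 0",
                      stacklevel=2)
        return 0.0
    ranks = stats.rankdata(x, axis=1)
    r_t = ranks.sum(axis=0)
    s = ((r_t - m * (t + 1) / 2.0) ** 2).sum()
    return float(12.0 * s / (m * m * (t ** 3 - t)))


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
]


def reho(series4d: np.ndarray, atlas: np.ndarray) -> VoxelMap:
    """Regional homogeneity: Kendall's W over each brain voxel and its
    (up to) 26 neighbours, normalised to brain mean 1.

    Boundary / brain-edge voxels use whatever brain neighbours exist.
    Implemented with shifted rank-volume sums so the whole map is a few
    vectorised passes rather than a per-voxel loop.
    """
    if min(atlas.shape) < 3:
        raise ValueError("grid must be at least 3x3x3")
    x, y, z, t = series4d.shape
    brain = atlas > 0
    ranks = stats.rankdata(series4d, axis=-1).astype(float)
    ranks[~brain] = 0.0

    pad_r = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pad_b = np.pad(brain.astype(np.int32), 1)
    rank_sum = np.zeros_like(ranks)
    m = np.zeros(atlas.shape, dtype=np.int32)
    for dx, dy, dz in _NEIGHBOR_OFFSETS:
        rank_sum += pad_r[1 + dx:1 + dx + x, 1 + dy:1 + dy + y,
                          1 + dz:1 + dz + z]
        m += pad_b[1 + dx:1 + dx + x, 1 + dy:1 + dy + y, 1 + dz:1 + dz + z]

    values = np.full(atlas.shape, np.nan)
    mm = m[brain].astype(float)
    lone = mm < 2
    if lone.any():
        warnings.warn("voxels with no brain neighbours get ReHo 0",
                      stacklevel=2)
    dev = rank_sum[brain] - mm[:, None] * (t + 1) / 2.0
    s = (dev ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / (mm ** 2 * (t ** 3 - t))
    w[lone] = 0.0
    mean_w = w.mean()
    values[brain] = w / mean_w if mean_w > 0 else 0.0
    return VoxelMap(values=values, measure_tag="ReHo")


def vmhc(series4d: np.ndarray, atlas: np.ndarray) -> VoxelMap:
    """Fisher-z correlation of each voxel with its x-mirrored counterpart.

    Voxels whose mirror counterpart is not a brain voxel stay NaN
    (flagged missing, not zero).
    """
    brain = atlas > 0
    mirrored = series4d[::-1]
    mirror_brain = brain[::-1]
    both = brain & mirror_brain
    a = series4d[both]
    b = mirrored[both]
    degenerate = (a.std(axis=1) == 0) | (b.std(axis=1) == 0)
    if degenerate.any():
        warnings.warn("constant series in VMHC; correlation set to 0",
                      stacklevel=2)
    values = np.full(atlas.shape, np.nan)
    values[both] = fisher_z(_pearson_rows(a, b))
    return VoxelMap(values=values, measure_tag="VMHC")


def fcs(series4d: np.ndarray, gm_mask: np.ndarray) -> VoxelMap:
    """Functional connectivity strength within the gray-matter mask.

    FCS_i = mean over j != i of fisher_z(r_ij), gray-matter voxels only.
    """
    gm = gm_mask > 0
    n = int(gm.sum())
    if n < 2:
        raise ValueError("need at least 2 gray-matter voxels")
    series = series4d[gm]
    sd = series.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant voxel series in FCS; correlations set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(series)
    r[~np.isfinite(r)] = 0.0
    z = fisher_z(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(z, 0.0)
    values = np.full(gm_mask.shape, np.nan)
    values[gm] = z.sum(axis=1) / (n - 1)
    return VoxelMap(values=values, measure_tag="FCS")


# ---------------------------------------------------------------------------
# network measures
# ---------------------------------------------------------------------------

def seed_network(
    series4d: np.ndarray,
    atlas: np.ndarray,
    seed_rois: tuple[int, int] | tuple[int, ...],
    tag: str = "seed",
) -> VoxelMap:
    """Fisher-z correlation map against a pooled bilateral seed reference.

    The reference time course is the mean over all voxels of the seed ROI
    pair (single pooled reference); the map correlates every brain voxel
    with it.
    """
    in_seed = np.isin(atlas, np.asarray(seed_rois))
    if not in_seed.any():
        raise ValueError(f"seed ROIs {seed_rois} are empty in the atlas")
    reference = series4d[in_seed].mean(axis=0)
    brain = atlas > 0
    vox = series4d[brain]
    ref = np.broadcast_to(reference, vox.shape)
    values = np.full(atlas.shape, np.nan)
    values[brain] = fisher_z(_pearson_rows(vox, ref))
    return VoxelMap(values=values, measure_tag=tag)


def roi_means(vmap: VoxelMap, atlas: np.ndarray, n_rois: int) -> FeatureVector:
    """Reduce a voxel map to per-ROI means, ROI order fixed by label id."""
    if vmap.values.shape != atlas.shape:
        raise ValueError("map and atlas shapes differ")
    values = np.empty(n_rois)
    for r in range(1, n_rois + 1):
        sel = atlas == r
        if not sel.any():
            raise ValueError(f"ROI {r} is empty in the atlas")
        vals = vmap.values[sel]
        vals = vals[np.isfinite(vals)]
        values[r - 1] = vals.mean() if vals.size else np.nan
    names = tuple(str(r) for r in range(1, n_rois + 1))
    return FeatureVector(feature_type=vmap.measure_tag, names=names,
                         values=values)


def roi_series(series4d: np.ndarray, atlas: np.ndarray,
               n_rois: int) -> np.ndarray:
    """R x T mean time series per atlas ROI."""
    t = series4d.shape[-1]
    out = np.empty((n_rois, t))
    for r in range(1, n_rois + 1):
        sel = atlas == r
        if not sel.any():
            raise ValueError(f"ROI {r} is empty in the atlas")
        out[r - 1] = series4d[sel].mean(axis=0)
    return out


def temporal_correlation(roi_ts: np.ndarray) -> FeatureVector:
    """Lower-triangle Fisher-z ROI-pair correlations, row-major by (i, j).

    Names are "i~j" with 1-based ROI labels and i > j.
    """
    n_rois = roi_ts.shape[0]
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    sd = roi_ts.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant ROI series; correlations set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(roi_ts)
    r[~np.isfinite(r)] = 0.0
    z = fisher_z(np.clip(r, -1.0, 1.0))
    rows, cols = np.tril_indices(n_rois, k=-1)
    names = tuple(f"{i + 1}~{j + 1}" for i, j in zip(rows, cols))
    return FeatureVector(feature_type="TC", names=names, values=z[rows, cols])


def _lag_matrix(series: np.ndarray, p: int) -> np.ndarray:
    """T-p x p matrix of lags 1..p of a 1-D series."""
    t = series.size
    return np.column_stack([series[p - k:t - k] for k in range(1, p + 1)])


def var_order_aic(x: np.ndarray, y: np.ndarray, p_max: int = 10) -> int:
    """Bivariate VAR order minimising AIC over p in {1..p_max}.

    AIC(p) = ln det(Sigma_hat) + 2 k / T_eff with k the number of VAR
    coefficients (two equations, 2p lag terms + intercept each) and
    T_eff = T - p the number of fitted samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = x.size
    if t <= 2 * p_max + 2:
        raise ValueError(f"series too short (T={t}) for p_max={p_max}")
    best_p, best_aic = None, np.inf
    for p in range(1, p_max + 1):
        t_eff = t - p
        design = np.column_stack(
            [np.ones(t_eff), _lag_matrix(x, p), _lag_matrix(y, p)])
        target = np.column_stack([x[p:], y[p:]])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ coef
        sigma = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue  # singular fit at this order
        k = 2 * (2 * p + 1)
        aic = logdet + 2.0 * k / t_eff
        if aic < best_aic:
            best_p, best_aic = p, aic
    if best_p is None:
        raise ValueError("VAR fit singular at every candidate order")
    return best_p


def granger_f(x: np.ndarray, y: np.ndarray, p: int) -> float:
    """F-statistic for Granger causality x -> y at VAR order p.

    Restricted model: y_t on p lags of y (+ intercept); unrestricted adds
    p lags of x.  F = ((RSS_r - RSS_u)/p) / (RSS_u/(T_eff - 2p - 1)) with
    T_eff = T - p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = x.size
    if t <= 2 * p + 1:
        raise ValueError(f"series too short (T={t}) for order p={p}")
    t_eff = t - p
    ylag = _lag_matrix(y, p)
    xlag = _lag_matrix(x, p)
    target = y[p:]
    ones = np.ones(t_eff)
    restricted = np.column_stack([ones, ylag])
    unrestricted = np.column_stack([ones, ylag, xlag])
    rss_r = _rss(restricted, target)
    rss_u = _rss(unrestricted, target)
    if rss_u <= 0:
        raise ValueError("degenerate fit: unrestricted RSS is zero")
    f = ((rss_r - rss_u) / p) / (rss_u / (t_eff - 2 * p - 1))
    return float(max(f, 0.0))


def _rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid)


def gc_matrix(roi_ts: np.ndarray, p_max: int = 10) -> FeatureVector:
    """Granger F-scores for all ordered ROI pairs, row-major by (i, j).

    Names are "i->j" with 1-based labels, i != j; the VAR order of each
    pair is chosen by AIC before the F computation.
    """
    n_rois = roi_ts.shape[0]
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    names, values = [], []
    for i in range(n_rois):
        for j in range(n_rois):
            if i == j:
                continue
            p = var_order_aic(roi_ts[i], roi_ts[j],
                              min(p_max, (roi_ts.shape[1] - 3) // 2))
            values.append(granger_f(roi_ts[i], roi_ts[j], p))
            names.append(f"{i + 1}->{j + 1}")
    return FeatureVector(feature_type="GC", names=tuple(names),
                         values=np.asarray(values))


# ---------------------------------------------------------------------------
# per-subject driver
# ---------------------------------------------------------------------------

def extract_features(
    cleaned,
    feature_types: tuple[str, ...] = FEATURE_TYPE_ORDER,
    seed_map: dict[str, tuple[int, int]] | None = None,
    n_rois: int | None = None,
    p_max: int = 10,
) -> FeatureSet:
    """Compute the requested feature vectors for one ``CleanedSubject``.

    ALFF and GC use the uncensored cleaned data; everything else the
    censored variant.  Seed-network types require ``seed_map``.
    """
    atlas = cleaned.atlas
    if n_rois is None:
        n_rois = int(atlas.max())
    censored = cleaned.cleaned_censored
    uncensored = cleaned.cleaned_uncensored
    feats: dict[str, FeatureVector] = {}
    ts_censored = None
    for ft in feature_types:
        if ft == "ALFF":
            vmap = alff(uncensored, atlas, cleaned.band, cleaned.tr_seconds)
            feats[ft] = roi_means(vmap, atlas, n_rois)
        elif ft == "ReHo":
            feats[ft] = roi_means(reho(censored, atlas), atlas, n_rois)
        elif ft == "VMHC":
            feats[ft] = roi_means(vmhc(censored, atlas), atlas, n_rois)
        elif ft == "FCS":
            feats[ft] = roi_means(fcs(censored, atlas), atlas, n_rois)
        elif ft == "TC":
            if ts_censored is None:
                ts_censored = roi_series(censored, atlas, n_rois)
            feats[ft] = temporal_correlation(ts_censored)
        elif ft == "GC":
            feats[ft] = gc_matrix(roi_series(uncensored, atlas, n_rois), p_max)
        else:
            if seed_map is None or ft not in seed_map:
                raise ValueError(f"unknown feature type or missing seed: {ft}")
            vmap = seed_network(censored, atlas, seed_map[ft], tag=ft)
            feats[ft] = roi_means(vmap, atlas, n_rois)
    return FeatureSet(subject_id=cleaned.subject_id, label=cleaned.label,
                      features=feats)
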