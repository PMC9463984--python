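"""Dynamic functional connectivity: tapered sliding windows, k-means
connectivity states, and the group-vs-individual state similarity (SDFC).

Windows are tapered by the full convolution of a 22-TR rectangle with a
unit-sum Gaussian kernel (sigma = 3 TRs, truncated at +-11 TRs), giving an
effective window length of 44 TRs; windows advance in steps of 2 TRs and
only fully contained placements count (206 TRs yields 82 windows).  Within
each window, functional connectivity between every pair of component time
courses is the taper-weighted Pearson correlation.  Windowed matrices are
clustered with k-means (k = 4) on their vectorized upper triangles and
relabeled by order of first occurrence, so the first window always belongs
to state 1.  SDFC averages, over windows, the Spearman rank correlation
between the state (centroid) matrices assigned to that window at the group
and at the individual level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "DFCConfig",
    "DFCStateResult",
    "taper_weights",
    "count_windows",
    "windowed_fc",
    "cluster_states",
    "sdfc",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DFCConfig:
    """Sliding-window and clustering parameters (units: TRs)."""

    rect_width: int = 22
    gauss_sigma: float = 3.0
    gauss_halfwidth: int = 11
    step: int = 2
    k: int = 4
    kmeans_restarts: int = 20
    seed: int = 0
    state_comparison: str = "centroid"   # or "raw"
    corr_method: str = "spearman"        # or "pearson"

    @property
    def window_length(self) -> int:
        """Full convolution support L = rect_width + 2 * gauss_halfwidth."""
        return self.rect_width + 2 * self.gauss_halfwidth


@dataclass
class DFCStateResult:
    """Windowed FC tensor with state assignments and centroid matrices."""

    tensor: np.ndarray        # (W, k_net, k_net)
    assignments: np.ndarray   # (W,), states numbered 1..k by first occurrence
    centroids: np.ndarray     # (k, k_net, k_net)
    stage: str = "group"
    n_effective_states: int | None = None
    degenerate: bool = False


def taper_weights(cfg: DFCConfig) -> np.ndarray:
    """Tapered window: rectangle convolved with a truncated Gaussian.

    The rectangle is ``rect_width`` ones; the Gaussian kernel is evaluated on
    integer offsets in [-gauss_halfwidth, gauss_halfwidth] and normalized to
    sum 1 before the full convolution, so the result has length
    ``rect_width + 2 * gauss_halfwidth`` and sums to 1 after the final
    normalization.  A zero halfwidth degenerates to the flat rectangle.
    """
    rect = np.ones(cfg.rect_width)
    offsets = np.arange(-cfg.gauss_halfwidth, cfg.gauss_halfwidth + 1)
    if cfg.gauss_halfwidth == 0 or cfg.gauss_sigma <= 0:
        kernel = np.ones(1)
    else:
        kernel = np.exp(-0.5 * (offsets / cfg.gauss_sigma) ** 2)
    kernel = kernel / kernel.sum()
    w = np.convolve(rect, kernel, mode="full")
    return w / w.sum()


def count_windows(t_len: int, cfg: DFCConfig) -> int:
    """Number of fully contained window placements at the configured step."""
    L = cfg.window_length
    if t_len < L:
        raise ConfigurationError(
            f"series of {t_len} TRs shorter than window length {L}")
    return (t_len - L) // cfg.step + 1


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of columns of x (weights sum 1)."""
    mu = w @ x
    xc = x - mu
    cov = xc.T @ (w[:, None] * xc)
    var = np.diag(cov).copy()
    # relative tolerance: a constant column leaves rounding residue ~1e-32
    bad = var <= 1e-12 * np.maximum(w @ (x * x), 1e-30)
    var[bad] = 1.0
    corr = cov / np.sqrt(np.outer(var, var))
    if bad.any():
        warnings.warn(f"{int(bad.sum())} component(s) with zero weighted "
                      "variance in a window; entries set to 0", stacklevel=2)
        corr[bad, :] = 0.0
        corr[:, bad] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip((corr + corr.T) / 2.0, -1.0, 1.0)


def windowed_fc(features: np.ndarray, cfg: DFCConfig) -> np.ndarray:
    """Tapered sliding-window correlation tensor (W, k_net, k_net)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("features must be (time, k_net>=2)")
    L = cfg.window_length
    n_win = count_windows(x.shape[0], cfg)
    w = taper_weights(cfg)
    out = np.empty((n_win, x.shape[1], x.shape[1]))
    for i in range(n_win):
        start = i * cfg.step
        out[i] = _weighted_corr(x[start:start + L], w)
    return out


def _upper_tri(mats: np.ndarray) -> np.ndarray:
    k = mats.shape[-1]
    iu = np.triu_indices(k, 1)
    return mats[..., iu[0], iu[1]]


def _fold_upper(vec: np.ndarray, k: int) -> np.ndarray:
    out = np.eye(k)
    iu = np.triu_indices(k, 1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def cluster_states(tensors: np.ndarray | list[np.ndarray],
                   cfg: DFCConfig) -> DFCStateResult | list[DFCStateResult]:
    """k-means connectivity states over one or more windowed-FC tensors.

    Multiple tensors (e.g., all subjects of one level) are pooled for a
    single clustering; each input tensor gets its own
    :class:`DFCStateResult` sharing the pooled centroids.  States are
    relabeled 1..k by order of first occurrence in the concatenated window
    sequence, so the very first window is always state 1.  If the windows
    collapse onto fewer than k distinct patterns the result is flagged
    degenerate with the effective state count recorded.
    """
    single = isinstance(tensors, np.ndarray)
    tensor_list = [tensors] if single else list(tensors)
    vecs = np.vstack([_upper_tri(t) for t in tensor_list])
    if vecs.shape[0] < cfg.k:
        raise ConfigurationError(
            f"{vecs.shape[0]} windows < k = {cfg.k} clusters")
    n_unique = np.unique(np.round(vecs, 10), axis=0).shape[0]
    degenerate = n_unique < cfg.k
    k_eff = min(cfg.k, n_unique)
    if degenerate:
        warnings.warn(f"only {n_unique} distinct window pattern(s); "
                      f"clustering with k={k_eff}", stacklevel=2)
    km = KMeans(n_clusters=k_eff, n_init=cfg.kmeans_restarts,
                random_state=cfg.seed)
    labels = km.fit_predict(vecs)
    # relabel by first occurrence: first window -> state 1
    order = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    for lab in range(k_eff):
        if lab not in order:
            order.append(lab)
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels]) + 1
    k_net = tensor_list[0].shape[-1]
    centroids = np.stack([_fold_upper(km.cluster_centers_[old], k_net)
                          for old in order])
    results = []
    start = 0
    for t in tensor_list:
        stop = start + t.shape[0]
        results.append(DFCStateResult(
            tensor=t, assignments=labels[start:stop], centroids=centroids,
            n_effective_states=k_eff, degenerate=degenerate))
        start = stop
    return results[0] if single else results


def sdfc(group: DFCStateResult, indiv: DFCStateResult,
         cfg: DFCConfig | None = None) -> float:
    """Similarity of dynamic functional connectivity between two levels.

    For each window i, correlate the vectorized upper triangles (diagonal
    excluded) of the state matrices assigned to that window at group and
    individual level — centroid matrices by default, raw windowed matrices
    with ``state_comparison='raw'`` — then average the per-window Spearman
    (or Pearson) correlations over all W windows.
    """
    cfg = DFCConfig() if cfg is None else cfg
    if group.assignments.shape[0] != indiv.assignments.shape[0]:
        raise ValueError(
            f"window counts differ: {group.assignments.shape[0]} vs "
            f"{indiv.assignments.shape[0]}")
    if cfg.state_comparison == "raw":
        g_mats = group.tensor
        d_mats = indiv.tensor
    else:
        g_mats = group.centroids[group.assignments - 1]
        d_mats = indiv.centroids[indiv.assignments - 1]
    gv = _upper_tri(g_mats)
    dv = _upper_tri(d_mats)
    vals = []
    for i in range(gv.shape[0]):
        if cfg.corr_method == "spearman":
            r = stats.spearmanr(gv[i], dv[i]).statistic
        else:
            r = stats.pearsonr(gv[i], dv[i]).statistic
        vals.append(r)
    return float(np.mean(vals))
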