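"""Consistency metrics: inter-subject correlation, spatial correlation,
overlap rate, atom matching, and group-comparison statistics.

ISC quantifies how reproducible an atom's time course is across subjects;
the default variant is leave-one-out (each subject's course against the mean
course of all other subjects), with mean-pairwise available as an
alternative.  SCC is the Pearson correlation between two voxel-wise maps
(computed on z-scores, which leaves the value unchanged).  The overlap rate
R(S, T) = |S intersect T| / |T| is deliberately asymmetric: S is the
individual-level network, T the group-level reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ISCReport",
    "BinaryMap",
    "isc",
    "scc",
    "binarize_map",
    "overlap_rate",
    "match_atoms",
    "compare_scc_groups",
]


@dataclass
class ISCReport:
    """Per-atom, per-subject ISC values plus the layer-style aggregates."""

    values: np.ndarray            # (n_subjects, q); NaN where undefined
    variant: str = "loo"

    @property
    def per_subject_mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=1)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values))


@dataclass(frozen=True)
class BinaryMap:
    """Thresholded spatial map with its binarization metadata."""

    inside: np.ndarray            # boolean over m voxels
    z_threshold: float = 1.96
    sign: str = "positive"

    @property
    def size(self) -> int:
        return int(self.inside.sum())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def isc(features_per_subject: list[np.ndarray],
        variant: str = "loo") -> ISCReport:
    """Inter-subject correlation per atom and subject.

    ``features_per_subject`` holds one (time x q) matrix per subject, all of
    equal shape.  For the default leave-one-out variant, the value for
    subject i and atom j is the Pearson correlation between subject i's time
    course and the mean time course of all other subjects; ``pairwise``
    averages subject i's correlations with every other subject instead.
    Constant time courses yield NaN (excluded from aggregates) with a warning.
    """
    if len(features_per_subject) < 2:
        raise ValueError("ISC needs at least 2 subjects")
    stack = np.stack([np.asarray(f, dtype=float)
                      for f in features_per_subject])  # (n, T, q)
    if stack.ndim != 3:
        raise ValueError("subject feature matrices must share one shape")
    n, _, q = stack.shape
    values = np.full((n, q), np.nan)
    n_constant = 0
    for j in range(q):
        courses = stack[:, :, j]
        for i in range(n):
            xi = courses[i]
            if xi.std() == 0:
                n_constant += 1
                continue
            if variant == "loo":
                others = courses[np.arange(n) != i].mean(axis=0)
                if others.std() == 0:
                    n_constant += 1
                    continue
                values[i, j] = _pearson(xi, others)
            elif variant == "pairwise":
                rs = [_pearson(xi, courses[k]) for k in range(n)
                      if k != i and courses[k].std() > 0]
                values[i, j] = np.nan if not rs else float(np.mean(rs))
            else:
                raise ValueError(f"unknown ISC variant {variant!r}")
    if n_constant:
        warnings.warn(f"{n_constant} constant time course(s) excluded from "
                      "ISC", stacklevel=2)
    return ISCReport(values=values, variant=variant)


def scc(zg: np.ndarray, zd: np.ndarray) -> float:
    """Spatial correlation coefficient between two maps of equal length.

    Pearson correlation over the voxel-wise z-scores of the two maps (the
    z-scoring leaves Pearson invariant, so plain correlation is computed).
    Symmetric, in [-1, 1]; constant maps are undefined.
    """
    zg = np.asarray(zg, dtype=float).ravel()
    zd = np.asarray(zd, dtype=float).ravel()
    if zg.shape != zd.shape:
        raise ValueError(f"map lengths differ: {zg.size} vs {zd.size}")
    if zg.std() == 0 or zd.std() == 0:
        raise ValueError("SCC undefined for a constant map")
    return _pearson(zg, zd)


def binarize_map(spatial_map: np.ndarray, z_threshold: float = 1.96) -> BinaryMap:
    """Threshold a map at z > ``z_threshold`` (positive side) after z-scoring."""
    x = np.asarray(spatial_map, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot binarize a constant map")
    z = (x - x.mean()) / sd
    return BinaryMap(inside=z > z_threshold, z_threshold=z_threshold)


def overlap_rate(S: BinaryMap | np.ndarray, T: BinaryMap | np.ndarray) -> float:
    """Spatial-pattern overlap R(S, T) = |S intersect T| / |T|.

    S is the individual-level network, T the corresponding group-level
    network; the rate is the fraction of the group network's voxels that the
    individual network also covers, hence order-sensitive.
    """
    s = S.inside if isinstance(S, BinaryMap) else np.asarray(S, dtype=bool)
    t = T.inside if isinstance(T, BinaryMap) else np.asarray(T, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("binary maps must share one length")
    nt = int(t.sum())
    if nt == 0:
        raise ValueError("overlap rate undefined: T is empty")
    return float(np.logical_and(s, t).sum() / nt)


def match_atoms(maps_a: np.ndarray, maps_b: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one atom assignment maximizing total |SCC|.

    ``maps_a`` (qa x m) and ``maps_b`` (qb x m); returns (rows_a, rows_b,
    signed_scc) for the min(qa, qb) matched pairs, Hungarian-optimal on the
    absolute spatial correlation.  Constant rows correlate as 0.
    """
    A = np.atleast_2d(np.asarray(maps_a, dtype=float))
    B = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("atom maps must share voxel count")
    corr = np.zeros((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            if A[i].std() == 0 or B[j].std() == 0:
                continue
            corr[i, j] = _pearson(A[i], B[j])
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return rows, cols, corr[rows, cols]


def compare_scc_groups(values_by_network: dict[str, np.ndarray],
                       alpha: float = 0.01) -> pd.DataFrame:
    """All pairwise two-sample t tests between networks, FDR-corrected.

    ``values_by_network`` maps network name -> per-subject metric values
    (SCC or overlap).  Returns a lower-triangular DataFrame of
    Benjamini-Hochberg adjusted p-values (upper triangle and diagonal NaN),
    rows/columns in input order.  Networks with fewer than 2 subjects are
    excluded with a warning.
    """
    names = []
    for name, vals in values_by_network.items():
        if np.asarray(vals).size < 2:
            warnings.warn(f"network {name!r} has <2 subjects; excluded",
                          stacklevel=2)
        else:
            names.append(name)
    if len(names) < 2:
        raise ValueError("need at least two networks with >=2 subjects")
    pairs, raw_p = [], []
    for i in range(1, len(names)):
        for j in range(i):
            a = np.asarray(values_by_network[names[i]], dtype=float)
            b = np.asarray(values_by_network[names[j]], dtype=float)
            t = stats.ttest_ind(a, b)
            pairs.append((names[i], names[j]))
            raw_p.append(t.pvalue)
    adj = multipletests(raw_p, alpha=alpha, method="fdr_bh")[1]
    table = pd.DataFrame(np.nan, index=names, columns=names)
    for (ri, cj), p in zip(pairs, adj):
        table.loc[ri, cj] = p
    return table
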