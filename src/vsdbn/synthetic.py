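"""Synthetic multi-subject volumetric series with known hierarchical
networks, group-shared vs subject-specific temporal sources, and planted
dynamic-connectivity states.

Every downstream stage of the pipeline is exercised against data whose
ground truth is known exactly.  Each subject's time-by-voxel matrix is the
linear mixture

    Y_i = S_i @ M.T + sigma_n * noise,     S_i = sqrt(1 - a) * G + sqrt(a) * U_i

where M holds k1 nonnegative primitive spatial maps (Gaussian blobs inside
the mask), G is a time x k1 matrix of group-shared latent sources, U_i are
independent subject-specific sources of the same law, and the mixing ratio
``a`` in [0, 1] sets how much of each component's temporal drive is
subject-specific (a = 0: all subjects identical up to noise; a = 1: no
shared signal).  The sqrt mixing keeps latent variance constant across
``a``, so a component's inter-subject source correlation falls off
monotonically with ``a``.  Composite maps — sums of 2-3 primitives — play
the role of deep-layer networks that combine several shallow ones.

Latent sources are moving-average-smoothed white noise (a crude stand-in
for hemodynamic smoothness, deliberately free of HRF convolution or
physiological noise structure); the mixed latents then pass through a
rectifying nonlinearity, max(x - 0.5, 0), so each network's activity is a
sparse train of positive transients.  The rectification matters beyond
realism: with jointly Gaussian sources a linear mixture is distributionally
invariant under source-space rotations, so no blind decomposition — this
package's or any other — could identify the planted maps even in
principle.  Sparse super-Gaussian activations make the factorization
identifiable, which is also the regime a sparsity-regularized DBN is built
for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dfc import DFCConfig, count_windows
from .io_volumes import BrainMask, DataMatrix, maps_to_nifti

__all__ = [
    "GroundTruth",
    "PlantedDFCSeries",
    "make_mask",
    "make_dataset",
    "write_dataset",
    "planted_dfc_series",
    "default_states",
]


class CapacityError(ValueError):
    """Grid too small for the requested number of blob networks."""


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    mask: BrainMask
    primitive_maps: np.ndarray        # (k1, m), nonnegative, group-level
    composite_maps: np.ndarray        # (k3, m)
    composite_members: list[list[int]]
    group_sources: np.ndarray         # (v, k1)
    subject_sources: list[np.ndarray]  # per subject (v, k1)
    subject_maps: list[np.ndarray]    # per subject (k1, m), jittered blobs
    mixing_ratio: np.ndarray          # (k1,), per-component alpha
    noise_sd: float
    seed: int


def make_mask(grid: tuple[int, int, int] = (12, 12, 12),
              exponent: float = 3.0) -> BrainMask:
    """Superellipsoid brain-ish mask covering most of the grid interior."""
    axes = [np.arange(g) - (g - 1) / 2.0 for g in grid]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    radii = [g / 2.0 for g in grid]
    r = (np.abs(zz / radii[0]) ** exponent
         + np.abs(yy / radii[1]) ** exponent
         + np.abs(xx / radii[2]) ** exponent)
    return BrainMask(inside=r <= 1.0)


def _smooth_sources(v: int, k: int, rng: np.random.Generator,
                    window: int = 5) -> np.ndarray:
    """Moving-average-smoothed standardized white noise, (v, k)."""
    raw = rng.standard_normal((v + window - 1, k))
    kern = np.ones(window) / window
    out = np.column_stack([np.convolve(raw[:, j], kern, mode="valid")
                           for j in range(k)])
    out -= out.mean(axis=0)
    out /= out.std(axis=0)
    return out


def _rectify(latent: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sparse transient activations: rectify at ``threshold``, standardize."""
    s = np.maximum(latent - threshold, 0.0)
    s = s - s.mean(axis=0)
    sd = s.std(axis=0)
    sd[sd == 0] = 1.0
    return s / sd


def _blob_maps(coords: np.ndarray, centers: np.ndarray,
               sigma_voxels: float = 1.6) -> np.ndarray:
    """Gaussian blob map per center over the in-mask coordinates, (k, m)."""
    maps = np.empty((centers.shape[0], coords.shape[0]))
    for i, c in enumerate(centers):
        d2 = ((coords - c) ** 2).sum(axis=1)
        maps[i] = np.exp(-0.5 * d2 / sigma_voxels ** 2)
    return maps


def _place_centers(mask: BrainMask, k1: int, rng: np.random.Generator,
                   min_separation: float = 3.5) -> np.ndarray:
    """k1 random in-mask blob centers with a minimum mutual distance."""
    coords = mask.coordinates().astype(float)
    centers: list[np.ndarray] = []
    for _ in range(2000):
        cand = coords[rng.integers(coords.shape[0])]
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
        if len(centers) == k1:
            break
    else:
        raise CapacityError(
            f"could not place {k1} blobs at separation {min_separation} "
            f"in a mask of {mask.m} voxels")
    return np.array(centers)


def make_dataset(n_subjects: int = 8, v: int = 100,
                 grid: tuple[int, int, int] = (12, 12, 12), k1: int = 8,
                 k3: int = 4, alpha: float | np.ndarray = 0.2,
                 noise_sd: float = 0.1, seed: int = 0,
                 spatial_jitter: float = 2.0
                 ) -> tuple[list[DataMatrix], GroundTruth]:
    """Generate the multi-subject fixture with its ground truth.

    ``alpha`` may be a scalar or a length-k1 vector giving each component its
    own subject-specific mixing ratio (used to plant an ISC hierarchy where
    composite-forming components are shared and others are idiosyncratic).
    ``alpha`` controls subject specificity on both axes: temporally it mixes
    subject-specific sources into the shared drive, and spatially it scales a
    per-subject displacement of each blob center (sd ``spatial_jitter``
    voxels at alpha = 1).  At alpha = 0 all subjects are identical up to
    noise.  Deterministic under a fixed seed.
    """
    if n_subjects < 1 or v < 30 or not (k1 >= k3 >= 1):
        raise ValueError("need n_subjects >= 1, v >= 30, k1 >= k3 >= 1")
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (k1,)).copy()
    if ((alpha < 0) | (alpha > 1)).any():
        raise ValueError("mixing ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = make_mask(grid)
    coords = mask.coordinates().astype(float)
    centers = _place_centers(mask, k1, rng)
    prim = _blob_maps(coords, centers)
    members = [sorted(rng.choice(k1, size=int(rng.integers(2, 4)),
                                 replace=False).tolist()) for _ in range(k3)]
    comp = np.stack([prim[m].sum(axis=0) for m in members])
    G = _smooth_sources(v, k1, rng)
    shared = np.sqrt(1.0 - alpha)
    specific = np.sqrt(alpha)
    subjects, subject_sources, subject_maps = [], [], []
    for i in range(n_subjects):
        U = _smooth_sources(v, k1, rng)
        S = _rectify(shared * G + specific * U)
        # subject-specific anatomy: blob centers displaced in proportion to
        # alpha, so individual uniqueness lives in space as well as time
        jitter = alpha[:, None] * rng.normal(0.0, spatial_jitter, centers.shape)
        M = _blob_maps(coords, centers + jitter)
        Y = S @ M + noise_sd * rng.standard_normal((v, mask.m))
        subject_sources.append(S)
        subject_maps.append(M)
        subjects.append(DataMatrix(values=Y, mask=mask,
                                   subject_id=f"sub-{i:02d}"))
    gt = GroundTruth(mask=mask, primitive_maps=prim, composite_maps=comp,
                     composite_members=members, group_sources=_rectify(G),
                     subject_sources=subject_sources,
                     subject_maps=subject_maps, mixing_ratio=alpha,
                     noise_sd=noise_sd, seed=seed)
    return subjects, gt


def write_dataset(subjects: list[DataMatrix], gt: GroundTruth,
                  outdir) -> Path:
    """Write NIfTI volumes, TSV ground-truth tables and a JSON manifest."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.mask.to_nifti(outdir / "mask.nii")
    for dm in subjects:
        vol = np.zeros(gt.mask.shape + (dm.n_timepoints,), dtype=np.float32)
        vol[gt.mask.inside, :] = dm.values.T
        nib.save(nib.Nifti1Image(vol, np.eye(4)),
                 str(outdir / f"{dm.subject_id}.nii"))
    maps_to_nifti(gt.primitive_maps, gt.mask, outdir / "primitive_maps.nii")
    maps_to_nifti(gt.composite_maps, gt.mask, outdir / "composite_maps.nii")
    np.savetxt(outdir / "group_sources.tsv", gt.group_sources, delimiter="\t")
    np.savetxt(outdir / "primitive_maps.tsv", gt.primitive_maps,
               delimiter="\t")
    manifest = {
        "seed": gt.seed,
        "n_subjects": len(subjects),
        "v": int(subjects[0].n_timepoints),
        "grid": list(gt.mask.shape),
        "m": gt.mask.m,
        "k1": int(gt.primitive_maps.shape[0]),
        "k3": int(gt.composite_maps.shape[0]),
        "composite_members": gt.composite_members,
        "mixing_ratio": gt.mixing_ratio.tolist(),
        "noise_sd": gt.noise_sd,
        "subjects": [dm.subject_id for dm in subjects],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


# ---------------------------------------------------------------------------
# Planted dynamic-connectivity states
# ---------------------------------------------------------------------------

@dataclass
class PlantedDFCSeries:
    """Component time courses cycling through known connectivity states."""

    features: np.ndarray       # (v, k_net)
    state_per_tr: np.ndarray   # (v,), 0-based planted state index
    states: np.ndarray         # (n_states, k_net, k_net) correlation targets
    dwell: int

    def window_labels(self, cfg: DFCConfig) -> np.ndarray:
        """Planted 0-based state of each window.

        A window overlapping a state change is labelled by the state holding
        the taper-weighted majority of the window, which is the state its
        windowed correlation matrix is closest to.
        """
        from .dfc import taper_weights

        n_win = count_windows(self.features.shape[0], cfg)
        w = taper_weights(cfg)
        n_states = self.states.shape[0]
        labels = np.empty(n_win, dtype=int)
        for i in range(n_win):
            seg = self.state_per_tr[i * cfg.step:i * cfg.step + cfg.window_length]
            labels[i] = np.argmax(np.bincount(seg, weights=w,
                                              minlength=n_states))
        return labels


def default_states(k_net: int = 8, n_states: int = 4,
                   seed: int = 0) -> np.ndarray:
    """Well-separated synthetic connectivity states (valid correlation
    matrices, built from random two-factor loadings plus a diagonal)."""
    rng = np.random.default_rng(seed)
    states = np.empty((n_states, k_net, k_net))
    for s in range(n_states):
        B = rng.choice([-1.0, 1.0], size=(k_net, 2)) * rng.uniform(
            0.6, 1.0, size=(k_net, 2))
        C = B @ B.T + 0.8 * np.eye(k_net)
        d = np.sqrt(np.diag(C))
        states[s] = C / np.outer(d, d)
    return states


def planted_dfc_series(states: np.ndarray, dwell: int, v: int, seed: int = 0,
                       noise_sd: float = 0.0,
                       cfg: DFCConfig | None = None) -> PlantedDFCSeries:
    """Series whose windowed correlations cycle through the planted states.

    Within each dwell segment the k_net component courses are i.i.d. draws
    from a zero-mean Gaussian with the segment's state as correlation matrix
    (Cholesky coloring), plus optional white noise of sd ``noise_sd``.
    States cycle 1, 2, ..., n_states, 1, ... with ``dwell`` TRs each; the
    dwell must be at least the effective window length so that windows fully
    inside a segment exist for every state.
    """
    cfg = DFCConfig() if cfg is None else cfg
    states = np.asarray(states, dtype=float)
    if states.ndim != 3 or states.shape[1] != states.shape[2]:
        raise ValueError("states must be (n_states, k_net, k_net)")
    for s in states:
        if not np.allclose(s, s.T) or not np.allclose(np.diag(s), 1.0):
            raise ValueError("each state must be symmetric with unit diagonal")
    if dwell < cfg.window_length:
        raise ValueError(
            f"dwell {dwell} shorter than window length {cfg.window_length}")
    rng = np.random.default_rng(seed)
    n_states, k_net = states.shape[:2]
    chols = [np.linalg.cholesky(s + 1e-9 * np.eye(k_net)) for s in states]
    feats = np.empty((v, k_net))
    labels = np.empty(v, dtype=int)
    for t0 in range(0, v, dwell):
        s = (t0 // dwell) % n_states
        seg = min(dwell, v - t0)
        z = rng.standard_normal((seg, k_net)) @ chols[s].T
        feats[t0:t0 + seg] = z
        labels[t0:t0 + seg] = s
    if noise_sd > 0:
        feats = feats + noise_sd * rng.standard_normal(feats.shape)
    return PlantedDFCSeries(features=feats, state_per_tr=labels,
                            states=states, dwell=dwell)
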