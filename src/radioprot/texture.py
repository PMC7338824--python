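"""Voxel-wise Haralick texture maps within segmented tumor sites.

For every masked voxel a gray-level co-occurrence matrix (GLCM) is built from
the voxel's neighborhood *intersected with the voxel's own site*, so texture
near a site boundary never mixes gray levels from another site or from
background.  Four Haralick statistics are read off the normalized GLCM and
averaged over the offset directions:

    energy      = sum_ij P(i,j)^2
    entropy     = -sum_ij P(i,j) log2 P(i,j)        (0 log 0 := 0)
    contrast    = sum_ij (i-j)^2 P(i,j)
    homogeneity = sum_ij P(i,j) / (1 + |i-j|)

Windows are 2D in-plane by default: CT slices are typically much thicker
(5 mm) than the in-plane resolution, which makes 3D neighborhoods strongly
anisotropic.  A 3D window is available via ``planar=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree
from scipy.special import xlogy

from .datatypes import SegmentedVolume
from .errors import ParameterError

logger = logging.getLogger("radioprot")

FEATURE_NAMES = ("energy", "entropy", "contrast", "homogeneity")


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the voxel-wise GLCM computation.

    offsets are displacement vectors over (x, y) in-plane axes (a third
    component, along z, may be given for 3D use); with ``symmetric`` each
    offset also counts the reversed pair, the standard symmetric GLCM.
    """

    n_levels: int = 32
    window_radius: int = 2
    offsets: tuple = ((0, 1), (1, 0), (1, 1), (1, -1))
    planar: bool = True
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ParameterError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.window_radius < 1:
            raise ParameterError("window_radius must be >= 1")
        for off in self.offsets:
            o3 = tuple(off) + (0,) * (3 - len(off))
            if len(o3) != 3 or all(c == 0 for c in o3):
                raise ParameterError(f"invalid offset {off}")
            r = self.window_radius
            rz = 0 if self.planar else self.window_radius
            if abs(o3[0]) > 2 * r or abs(o3[1]) > 2 * r or abs(o3[2]) > 2 * rz:
                raise ParameterError(f"offset {off} larger than the window")

    @property
    def offsets3(self) -> tuple[tuple[int, int, int], ...]:
        return tuple(tuple(o) + (0,) * (3 - len(o)) for o in self.offsets)


def quantize(volume: SegmentedVolume, n_levels: int) -> np.ndarray:
    """Quantize masked intensities to integer gray levels 1..n_levels.

    Intensities are clipped to the 1st-99th percentile range of the masked
    voxels (robust to HU outliers) and linearly rescaled onto the level grid
    with rounding, so the clipped minimum maps to level 1 and the clipped
    maximum to level ``n_levels``.  Background voxels stay 0.
    """
    if n_levels < 2:
        raise ParameterError(f"n_levels must be >= 2, got {n_levels}")
    out = np.zeros(volume.intensities.shape, dtype=np.int32)
    sel = volume.mask > 0
    vals = volume.intensities[sel]
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        out[sel] = 1
        return out
    clipped = np.clip(vals, lo, hi)
    levels = 1 + np.rint((clipped - lo) / (hi - lo) * (n_levels - 1)).astype(np.int64)
    out[sel] = levels
    return out


def _haralick(P: np.ndarray) -> tuple[float, float, float, float]:
    """The four features of one normalized GLCM."""
    L = P.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    energy = float((P * P).sum())
    pos = P > 0
    entropy = float(-(P[pos] * np.log2(P[pos])).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    return energy, entropy, contrast, homogeneity


def _offset_slices(shape, off):
    """Source/destination index slices for pairing an array with its shift."""
    src, dst = [], []
    for size, d in zip(shape, off):
        if d >= 0:
            src.append(slice(0, size - d))
            dst.append(slice(d, size))
        else:
            src.append(slice(-d, size))
            dst.append(slice(0, size + d))
    return tuple(src), tuple(dst)


def glcm_features(window_levels: np.ndarray, params: TextureParams):
    """Haralick 4-vector of one level patch; 0 entries mark invalid voxels.

    Per offset a (symmetric, if requested) GLCM over valid level pairs is
    normalized and reduced to (energy, entropy, contrast, homogeneity); the
    vectors are averaged over offsets that produced at least one pair.
    Returns None when no offset yields a valid pair.
    """
    patch = np.asarray(window_levels)
    if patch.ndim == 2:
        patch = patch[:, :, None]
    L = params.n_levels
    acc = np.zeros(4)
    n_off = 0
    for off in params.offsets3:
        src, dst = _offset_slices(patch.shape, off)
        a, b = patch[src], patch[dst]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        P = np.zeros((L, L))
        np.add.at(P, (a[ok] - 1, b[ok] - 1), 1.0)
        if params.symmetric:
            P = P + P.T
        P /= P.sum()
        acc += np.array(_haralick(P))
        n_off += 1
    if n_off == 0:
        return None
    return tuple((acc / n_off).tolist())


@dataclass
class TextureMap:
    """Per masked voxel: a Haralick feature 4-vector plus provenance.

    ``features`` is (n_voxels, 4) aligned with ``coords`` (voxel indices) and
    ``sites`` (the voxel's site label).  ``defined`` records which voxels had
    at least one valid co-occurrence pair before imputation; ``imputed`` marks
    voxels filled from their nearest defined same-site neighbor.  Rows that
    could be neither computed nor imputed are NaN.
    """

    features: np.ndarray
    coords: np.ndarray
    sites: np.ndarray
    defined: np.ndarray
    imputed: np.ndarray
    spacing: tuple
    feature_names: tuple = FEATURE_NAMES

    @property
    def n_voxels(self) -> int:
        return self.features.shape[0]

    def finite_rows(self) -> np.ndarray:
        return np.isfinite(self.features).all(axis=1)


def _site_features(Qs: np.ndarray, coords: np.ndarray, params: TextureParams) -> np.ndarray:
    """Vectorized per-voxel GLCM features for one site.

    Qs: level grid with 0 outside the site; coords: (n,3) voxel indices of the
    site.  Returns (n, 4) with NaN rows where no offset produced a pair.
    """
    r = params.window_radius
    rz = 0 if params.planar else params.window_radius
    L = params.n_levels
    pad = np.pad(Qs, ((r, r), (r, r), (rz, rz)))
    win = (2 * r + 1, 2 * r + 1, 2 * rz + 1)
    sw = sliding_window_view(pad, win)
    W = sw[coords[:, 0], coords[:, 1], coords[:, 2]]  # (n, wx, wy, wz)
    n = W.shape[0]

    idx = np.arange(L)
    diff = idx[:, None] - idx[None, :]
    w_contrast = (diff.astype(float) ** 2).ravel()
    w_homog = (1.0 / (1.0 + np.abs(diff))).ravel()

    acc = np.zeros((n, 4))
    n_off = np.zeros(n, dtype=int)
    for off in params.offsets3:
        src, dst = _offset_slices(win, off)
        a = W[(slice(None),) + src]
        b = W[(slice(None),) + dst]
        ok = (a > 0) & (b > 0)
        vi, *_ = ok.nonzero()
        if vi.size == 0:
            continue
        ia = (a[ok] - 1).astype(np.int64)
        jb = (b[ok] - 1).astype(np.int64)
        cnt = np.zeros((n, L * L))
        np.add.at(cnt, (vi, ia * L + jb), 1.0)
        if params.symmetric:
            np.add.at(cnt, (vi, jb * L + ia), 1.0)
        tot = cnt.sum(axis=1)
        has = tot > 0
        P = cnt[has] / tot[has, None]
        energy = (P * P).sum(axis=1)
        entropy = -xlogy(P, P).sum(axis=1) / np.log(2.0)
        contrast = P @ w_contrast
        homog = P @ w_homog
        acc[has] += np.c_[energy, entropy, contrast, homog]
        n_off[has] += 1

    out = np.full((n, 4), np.nan)
    good = n_off > 0
    out[good] = acc[good] / n_off[good, None]
    return out


def texture_map(volume: SegmentedVolume, params: TextureParams | None = None) -> TextureMap:
    """Voxel-wise Haralick features over all sites of one patient.

    Quantization uses patient-level percentiles over the whole mask; windows
    are intersected with each voxel's own site.  Voxels whose window yields no
    valid pair are imputed from the nearest defined voxel of the same site
    (physical distance); a site smaller than 2 voxels stays undefined with a
    warning and is skipped by imputation.
    """
    params = params or TextureParams()
    Q = quantize(volume, params.n_levels)
    spacing = np.asarray(volume.spacing)

    all_feats, all_coords, all_sites, all_def, all_imp = [], [], [], [], []
    for s in range(1, volume.n_sites + 1):
        coords = np.argwhere(volume.mask == s)
        n = coords.shape[0]
        if n < 2:
            logger.warning("site %d of %s has %d voxel(s): features undefined, imputation skipped",
                           s, volume.patient_id, n)
            feats = np.full((n, 4), np.nan)
            defined = np.zeros(n, dtype=bool)
            imputed = np.zeros(n, dtype=bool)
        else:
            Qs = np.where(volume.mask == s, Q, 0)
            feats = _site_features(Qs, coords, params)
            defined = np.isfinite(feats).all(axis=1)
            imputed = np.zeros(n, dtype=bool)
            if not defined.all():
                if defined.any():
                    tree = cKDTree(coords[defined] * spacing)
                    _, nn = tree.query(coords[~defined] * spacing)
                    feats[~defined] = feats[defined][nn]
                    imputed = ~defined
                else:
                    logger.warning("site %d of %s has no defined voxel; imputation skipped",
                                   s, volume.patient_id)
        all_feats.append(feats)
        all_coords.append(coords)
        all_sites.append(np.full(n, s, dtype=np.int32))
        all_def.append(defined)
        all_imp.append(imputed)

    return TextureMap(
        features=np.vstack(all_feats),
        coords=np.vstack(all_coords),
        sites=np.concatenate(all_sites),
        defined=np.concatenate(all_def),
        imputed=np.concatenate(all_imp),
        spacing=volume.spacing,
    )


def standardize_features(features: np.ndarray) -> np.ndarray:
    """Per-feature z-score over a patient's masked voxels (constant -> 0)."""
    X = np.asarray(features, dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd
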