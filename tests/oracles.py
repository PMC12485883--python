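"""Independent reference computations used to validate pipeline operations.

These are deliberately written with different algorithms than the package
(brute-force threshold labelling, direct summation) so that agreement is
meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

_STRUCT = np.ones((3, 3), dtype=bool)


def pearson_direct(a: np.ndarray, b: np.ndarray) -> float:
    """PCC via the raw covariance formula sum((a-am)(b-bm)) / (sa*sb)."""
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    am, bm = a.mean(), b.mean()
    cov = float(np.sum((a - am) * (b - bm)))
    sa = float(np.sqrt(np.sum((a - am) ** 2)))
    sb = float(np.sqrt(np.sum((b - bm) ** 2)))
    return cov / (sa * sb)


def _regional_max_plateaus(img: np.ndarray):
    """Iso-value 8-connected plateaus with no strictly higher neighbor."""
    plateaus = []
    for v in np.unique(img):
        lab, n = ndi.label(img == v, _STRUCT)
        for i in range(1, n + 1):
            mask = lab == i
            ring = ndi.binary_dilation(mask, _STRUCT) & ~mask
            if not ring.any() or img[ring].max() < v:
                plateaus.append((float(v), mask))
    return plateaus


def _plateau_first_pixel(mask: np.ndarray) -> tuple[int, int]:
    return min(zip(*np.nonzero(mask)))


def _plateau_centroid_pixel(mask: np.ndarray) -> tuple[int, int]:
    pts = sorted(zip(*(np.nonzero(mask))))
    cr = sum(p[0] for p in pts) / len(pts)
    cc = sum(p[1] for p in pts) / len(pts)
    return min(pts, key=lambda p: ((p[0] - cr) ** 2 + (p[1] - cc) ** 2, p))


def prominence_map(img: np.ndarray) -> dict[tuple[int, int], float]:
    """Exhaustive saddle computation: plateau centroid pixel -> prominence.

    For each regional-max plateau P with value v, the saddle is the highest
    threshold t at which the 8-connected component of {img >= t} containing P
    also contains strictly higher ground, or an equal-value regional-max
    plateau that dominates P (smaller row-major first pixel).  Prominence is
    v - saddle; the overall dominant peak gets v - min(img).
    """
    img = np.asarray(img, dtype=np.float64)
    plateaus = _regional_max_plateaus(img)
    levels = np.unique(img)[::-1]
    vmin = float(img.min())
    out: dict[tuple[int, int], float] = {}
    for v, mask in plateaus:
        first = _plateau_first_pixel(mask)
        saddle = None
        for t in levels:
            if t > v:
                continue
            lab, _ = ndi.label(img >= t, _STRUCT)
            comp = lab == lab[first]
            if img[comp].max() > v:
                saddle = float(t)
                break
            dominated = False
            for v2, mask2 in plateaus:
                if v2 == v and mask2 is not mask and comp[mask2].any():
                    if _plateau_first_pixel(mask2) < first:
                        dominated = True
                        break
            if dominated:
                saddle = float(t)
                break
        prom = v - (saddle if saddle is not None else vmin)
        out[_plateau_centroid_pixel(mask)] = prom
    return out


def maxima_oracle(img: np.ndarray, tolerance: float) -> set[tuple[int, int]]:
    """Set of maxima positions with prominence strictly above tolerance."""
    return {pos for pos, prom in prominence_map(img).items() if prom > tolerance}


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled, normalized 1D Gaussian kernel as used by standard blurs."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def best_gaussian_r2_grid(profile: np.ndarray) -> float:
    """Coarse grid search of A*exp(-(x-mu)^2/(2 s^2)) + b maximizing R^2."""
    x = np.arange(profile.size, dtype=np.float64)
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))
    best = -np.inf
    for mu in np.linspace(0, profile.size - 1, 40):
        for sigma in np.linspace(0.5, 20, 25):
            g = np.exp(-((x - mu) ** 2) / (2 * sigma**2))
            # optimal (A, b) for fixed shape by linear least squares
            design = np.column_stack((g, np.ones_like(g)))
            coef, *_ = np.linalg.lstsq(design, profile, rcond=None)
            resid = profile - design @ coef
            r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot
            best = max(best, r2)
    return best
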