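"""Two-color STED nano-cluster analysis.

Pipeline (order follows the underlying microscopy macro): the long-red
channel is corrected for 50% spectral crosstalk from the red channel, both
channels receive a light Gaussian blur (sigma 0.5 px) for noise reduction,
local maxima are detected with an ImageJ-compatible noise-tolerance
(prominence) criterion, each maximum is refined to a sub-pixel position as
the center of mass inside a 5-px-diameter disc, and reference-channel maxima
are classified as nano-clusters when a Gaussian fitted to a 31x3 linescan has
R^2 > 0.7 with its peak in the middle third.  For every accepted reference
nano-cluster the Euclidean distance (in nm, 25 nm/px) to the nearest maximum
of the other channel is recorded; mirroring that channel yields the
purely-random control distribution of distances.  A sweep over noise
tolerance pairs checks that conclusions do not hinge on the detection
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .images import ChannelImage, InvalidParameterError, SquareROI

__all__ = [
    "MaximumCandidate",
    "SubpixelPosition",
    "LinescanFit",
    "NanoCluster",
    "NNDistanceSet",
    "StedAnalysis",
    "CandidateExcluded",
    "correct_crosstalk",
    "blur",
    "find_maxima",
    "refine_subpixel",
    "linescan_fit",
    "classify",
    "nn_distances",
    "flip_control",
    "analyze_sheet",
    "tolerance_sweep",
    "DEFAULT_TOLERANCE_PAIRS",
]

DEFAULT_TOLERANCE_PAIRS: tuple[tuple[float, float], ...] = (
    (2, 4), (4, 8), (6, 12), (2, 12),
)

LINESCAN_LENGTH = 31
LINESCAN_WIDTH = 3
MIDDLE_THIRD = (LINESCAN_LENGTH / 3.0, 2.0 * LINESCAN_LENGTH / 3.0)


class CandidateExcluded(Exception):
    """The candidate's measurement window does not fit inside the image."""


@dataclass(frozen=True)
class MaximumCandidate:
    """A detected local maximum at integer pixel position."""

    row: int
    col: int
    prominence: float
    channel_label: str = ""
    value: float = float("nan")


@dataclass(frozen=True)
class SubpixelPosition:
    """Center-of-mass refined position; stays within the 5-px disc."""

    row_sub: float
    col_sub: float


@dataclass(frozen=True)
class LinescanFit:
    """Gaussian fit A*exp(-(x-mu)^2/(2 sigma^2)) + b to a 31x3 linescan."""

    orientation: Literal["horizontal", "vertical"]
    profile: tuple[float, ...]
    amplitude: float
    center_px: float
    sigma_px: float
    offset: float
    r_squared: float
    peak_in_middle_third: bool

    @property
    def passes(self) -> bool:
        return self.r_squared > 0.7 and self.peak_in_middle_third


@dataclass(frozen=True)
class NanoCluster:
    candidate: MaximumCandidate
    subpixel: SubpixelPosition
    fits: tuple[LinescanFit, LinescanFit]
    accepted: bool


@dataclass
class NNDistanceSet:
    """Observed vs flipped-control nearest-neighbor distances in nm."""

    distances_nm: np.ndarray
    flipped_distances_nm: np.ndarray
    tolerance_pair: tuple[float, float]
    pixel_size_nm: float = 25.0

    @property
    def mean_nm(self) -> float:
        return float(np.mean(self.distances_nm)) if len(self.distances_nm) else float("nan")

    @property
    def flipped_mean_nm(self) -> float:
        return (
            float(np.mean(self.flipped_distances_nm))
            if len(self.flipped_distances_nm)
            else float("nan")
        )

    @property
    def n(self) -> int:
        return int(len(self.distances_nm))


@dataclass
class StedAnalysis:
    """Full per-sheet result: classified clusters, target maxima, distances."""

    clusters: list[NanoCluster]
    reference_maxima: list[MaximumCandidate]
    target_maxima: list[MaximumCandidate]
    target_positions: list[SubpixelPosition]
    nn: NNDistanceSet


def correct_crosstalk(
    longred: ChannelImage, red: ChannelImage, factor: float = 0.5
) -> ChannelImage:
    """Remove spectral bleed-through: ``longred - factor * red``, clipped at 0.

    Negative photon counts are unphysical and destabilize the center-of-mass
    refinement, hence the clip.
    """
    if longred.shape != red.shape:
        raise InvalidParameterError(
            f"shape mismatch: {longred.shape} vs {red.shape}"
        )
    if not (0 <= factor < 1):
        raise InvalidParameterError(f"factor must be in [0, 1), got {factor}")
    return longred.with_pixels(np.maximum(longred.pixels - factor * red.pixels, 0.0))


def blur(image: ChannelImage, sigma_px: float = 0.5) -> ChannelImage:
    """Isotropic Gaussian blur for noise reduction (reflective borders)."""
    if sigma_px <= 0:
        raise InvalidParameterError(f"sigma_px must be > 0, got {sigma_px}")
    return image.with_pixels(
        ndimage.gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    )


# ---------------------------------------------------------------------------
# ImageJ-style "Find maxima": prominence via descending-order union-find flood
# ---------------------------------------------------------------------------


def _plateau_representative(
    img: np.ndarray, start_r: int, start_c: int
) -> tuple[int, int]:
    """Pixel of the iso-value plateau nearest its centroid (lexicographic ties)."""
    rows, cols = img.shape
    v = img[start_r, start_c]
    stack = [(start_r, start_c)]
    seen = {(start_r, start_c)}
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < rows and 0 <= cc < cols
                    and (rr, cc) not in seen and img[rr, cc] == v
                ):
                    seen.add((rr, cc))
                    stack.append((rr, cc))
    pts = sorted(seen)
    cr = sum(p[0] for p in pts) / len(pts)
    cc_ = sum(p[1] for p in pts) / len(pts)
    return min(pts, key=lambda p: ((p[0] - cr) ** 2 + (p[1] - cc_) ** 2, p))


def _prominence_maxima(img: np.ndarray, tolerance: float) -> list[tuple[int, int, float, float]]:
    """All local peaks with prominence > tolerance.

    Pixels are merged in descending intensity order (union-find).  When two
    growing regions meet at level v, the region whose peak is lower (ties:
    later in row-major order) dies; its prominence is peak - v.  The overall
    dominant peak's prominence is peak - min(img).  Returns
    (row, col, prominence, value) with (row, col) the plateau representative.
    """
    rows, cols = img.shape
    flat = img.ravel()
    n = flat.size
    rr, cc = np.divmod(np.arange(n), cols)
    order = np.lexsort((cc, rr, -flat))  # by value desc, then row, then col

    comp = np.full(n, -1, dtype=np.int64)  # pixel -> component id (unrooted)
    parent: list[int] = []        # union-find over component ids
    peak_value: list[float] = []  # per component: its peak's value
    peak_pixel: list[int] = []    # per component: flat index of peak's first pixel
    accepted: list[tuple[int, float, float]] = []  # (peak flat idx, prominence, value)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for p in order:
        v = flat[p]
        pr, pc = p // cols, p % cols
        roots = []
        for dr, dc in neigh:
            qr, qc = pr + dr, pc + dc
            if 0 <= qr < rows and 0 <= qc < cols:
                q = qr * cols + qc
                if comp[q] != -1:
                    root = find(comp[q])
                    if root not in roots:
                        roots.append(root)
        if not roots:
            cid = len(parent)
            parent.append(cid)
            peak_value.append(v)
            peak_pixel.append(p)
            comp[p] = cid
            continue
        # best surviving peak: highest value, then earliest (row-major) pixel
        best = roots[0]
        for r in roots[1:]:
            if (peak_value[r], -peak_pixel[r]) > (peak_value[best], -peak_pixel[best]):
                best = r
        for r in roots:
            if r is best or r == best:
                continue
            prom = peak_value[r] - v
            if prom > tolerance:
                accepted.append((peak_pixel[r], prom, peak_value[r]))
            parent[r] = best
        comp[p] = best

    # the single surviving root is the dominant peak
    final_root = find(comp[order[-1]])
    prom = peak_value[final_root] - float(flat.min())
    if prom > tolerance:
        accepted.append((peak_pixel[final_root], prom, peak_value[final_root]))

    out = []
    for p, prom, value in accepted:
        r, c = _plateau_representative(img, p // cols, p % cols)
        out.append((r, c, float(prom), float(value)))
    out.sort(key=lambda t: (-t[3], t[0], t[1]))
    return out


def find_maxima(
    image: ChannelImage,
    roi: SquareROI | None = None,
    noise_tolerance: float = 2.0,
) -> list[MaximumCandidate]:
    """Detect local maxima with prominence above ``noise_tolerance``.

    Implements the flood semantics of ImageJ's "Find maxima": regions grow
    from pixels in descending intensity order, and a local peak is rejected
    when its region touches a region with a higher peak before descending
    more than ``noise_tolerance`` below its own peak value.  A constant image
    yields no maxima.  Plateau maxima are reported at the plateau pixel
    nearest the plateau centroid.  Positions are in full-image coordinates.
    """
    if noise_tolerance <= 0:
        raise InvalidParameterError(
            f"noise_tolerance must be > 0, got {noise_tolerance}"
        )
    if roi is not None:
        sub = image.roi_view(roi)
        off_r, off_c = roi.row0, roi.col0
    else:
        sub = image.pixels
        off_r = off_c = 0
    if sub.size == 0:
        raise InvalidParameterError("empty ROI")
    return [
        MaximumCandidate(
            row=r + off_r, col=c + off_c, prominence=prom,
            channel_label=image.channel_label, value=value,
        )
        for r, c, prom, value in _prominence_maxima(sub, noise_tolerance)
    ]


# ---------------------------------------------------------------------------
# Sub-pixel refinement and linescan classification
# ---------------------------------------------------------------------------

def _disc_offsets(diameter_px: int) -> np.ndarray:
    radius = diameter_px / 2.0
    reach = int(np.floor(radius))
    offs = [
        (dr, dc)
        for dr in range(-reach, reach + 1)
        for dc in range(-reach, reach + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    return np.asarray(offs, dtype=np.int64)


def refine_subpixel(
    image: ChannelImage, candidate: MaximumCandidate, diameter_px: int = 5
) -> SubpixelPosition:
    """Intensity-weighted centroid over a disc centered on the candidate pixel.

    The disc contains the pixels whose centers lie within ``diameter_px / 2``
    of the candidate pixel center.  The disc minimum is subtracted before
    weighting (local baseline correction): a plain center of mass over a
    fixed window shrinks sub-pixel offsets toward the window center by the
    truncated flux, while the baseline-corrected centroid localizes a
    diffraction-limited spot to well under 0.1 px.  Raises
    :class:`CandidateExcluded` when the disc does not fit inside the image;
    falls back to the integer position (with a warning) when the disc
    carries no signal above its baseline.
    """
    offs = _disc_offsets(diameter_px)
    reach = int(np.abs(offs).max())
    rows, cols = image.shape
    r0, c0 = candidate.row, candidate.col
    if r0 - reach < 0 or r0 + reach >= rows or c0 - reach < 0 or c0 + reach >= cols:
        raise CandidateExcluded(
            f"{diameter_px}-px disc at ({r0}, {c0}) leaves the image"
        )
    weights = image.pixels[r0 + offs[:, 0], c0 + offs[:, 1]]
    weights = weights - weights.min()
    total = float(weights.sum())
    if total <= 0:
        import warnings

        warnings.warn(
            "no intensity above the local baseline in the center-of-mass disc; "
            "falling back to integer position",
            UserWarning,
            stacklevel=2,
        )
        return SubpixelPosition(float(r0), float(c0))
    dr = float(np.dot(weights, offs[:, 0])) / total
    dc = float(np.dot(weights, offs[:, 1])) / total
    return SubpixelPosition(r0 + dr, c0 + dc)


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float, offset: float):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + offset


def _gaussian_jac(x: np.ndarray, amplitude: float, mu: float, sigma: float, offset: float):
    z = (x - mu) / sigma
    e = np.exp(-0.5 * z**2)
    return np.column_stack((e, amplitude * e * z / sigma,
                            amplitude * e * z**2 / sigma, np.ones_like(x)))


def linescan_fit(
    image: ChannelImage,
    candidate: MaximumCandidate,
    orientation: Literal["horizontal", "vertical"],
) -> LinescanFit:
    """Fit a Gaussian to a 31-px-long, 3-px-wide linescan through the maximum.

    The profile averages over the 3-px width.  Fit model is
    ``A * exp(-(x - mu)^2 / (2 sigma^2)) + b`` with sigma bounded to
    [0.5, 31] px; a non-convergent fit gets ``r_squared = -inf``.  The peak
    counts as "in the middle third" when mu lies in [31/3, 62/3] (0-based
    continuous linescan coordinates).
    """
    half_len = LINESCAN_LENGTH // 2
    half_w = LINESCAN_WIDTH // 2
    rows, cols = image.shape
    r0, c0 = candidate.row, candidate.col
    if orientation == "horizontal":
        if (
            r0 - half_w < 0 or r0 + half_w >= rows
            or c0 - half_len < 0 or c0 + half_len >= cols
        ):
            raise CandidateExcluded("horizontal linescan leaves the image")
        window = image.pixels[r0 - half_w:r0 + half_w + 1,
                              c0 - half_len:c0 + half_len + 1]
        profile = window.mean(axis=0)
    elif orientation == "vertical":
        if (
            c0 - half_w < 0 or c0 + half_w >= cols
            or r0 - half_len < 0 or r0 + half_len >= rows
        ):
            raise CandidateExcluded("vertical linescan leaves the image")
        window = image.pixels[r0 - half_len:r0 + half_len + 1,
                              c0 - half_w:c0 + half_w + 1]
        profile = window.mean(axis=1)
    else:
        raise InvalidParameterError(f"unknown orientation {orientation!r}")

    x = np.arange(LINESCAN_LENGTH, dtype=np.float64)
    pmin, pmax = float(profile.min()), float(profile.max())
    p0 = np.array([pmax - pmin, float(np.argmax(profile)), 2.0, pmin])
    lower = np.array([0.0, -5.0, 0.5, -np.inf])
    upper = np.array([np.inf, LINESCAN_LENGTH + 4.0, 31.0, np.inf])
    p0 = np.clip(p0, lower, upper)
    try:
        sol = optimize.least_squares(
            lambda p: _gaussian(x, *p) - profile,
            p0,
            jac=lambda p: _gaussian_jac(x, *p),
            bounds=(lower, upper),
            max_nfev=2000,
        )
        if not sol.success:
            raise RuntimeError(sol.message)
        amplitude, mu, sigma, offset = (float(v) for v in sol.x)
        ss_res = float(np.dot(sol.fun, sol.fun))
        centered = profile - profile.mean()
        ss_tot = float(np.dot(centered, centered))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    except (RuntimeError, ValueError):
        amplitude = mu = sigma = offset = float("nan")
        r_squared = -np.inf
    in_middle = bool(MIDDLE_THIRD[0] <= mu <= MIDDLE_THIRD[1]) if np.isfinite(mu) else False
    return LinescanFit(
        orientation=orientation,
        profile=tuple(float(v) for v in profile),
        amplitude=amplitude,
        center_px=mu,
        sigma_px=sigma,
        offset=offset,
        r_squared=r_squared,
        peak_in_middle_third=in_middle,
    )


def classify(
    candidate: MaximumCandidate,
    subpixel: SubpixelPosition,
    fits: tuple[LinescanFit, LinescanFit],
) -> NanoCluster:
    """Accept a maximum as a nano-cluster if at least one linescan passes.

    A linescan passes when its own fit has R^2 > 0.7 AND its peak lies in the
    middle third — the conjunction is per linescan, so a good fit with an
    off-center peak plus a centered but poor fit does not qualify.
    """
    return NanoCluster(
        candidate=candidate,
        subpixel=subpixel,
        fits=fits,
        accepted=bool(fits[0].passes or fits[1].passes),
    )


# ---------------------------------------------------------------------------
# Nearest-neighbor distances with flipped-image control
# ---------------------------------------------------------------------------

def _positions_array(positions: Sequence[SubpixelPosition]) -> np.ndarray:
    return np.asarray([(p.row_sub, p.col_sub) for p in positions], dtype=np.float64)


def nn_distances(
    reference: Sequence[SubpixelPosition],
    targets: Sequence[SubpixelPosition],
    pixel_size_nm: float = 25.0,
) -> np.ndarray:
    """Distance in nm from each reference position to its nearest target."""
    if len(targets) == 0:
        raise InvalidParameterError("target position list is empty")
    if len(reference) == 0:
        return np.empty(0, dtype=np.float64)
    tree = cKDTree(_positions_array(targets))
    d, _ = tree.query(_positions_array(reference), k=1)
    return np.asarray(d, dtype=np.float64) * pixel_size_nm


def flip_control(
    targets: Sequence[SubpixelPosition],
    image_cols: int,
    axis: Literal["h", "v"] = "h",
    image_rows: int | None = None,
) -> list[SubpixelPosition]:
    """Mirror target positions to obtain a spatially unrelated control.

    ``axis='h'`` mirrors left-right (col -> image_cols - 1 - col);
    ``axis='v'`` mirrors top-bottom and needs ``image_rows``.  Applying the
    flip twice restores the input.
    """
    if axis == "h":
        return [
            SubpixelPosition(p.row_sub, (image_cols - 1) - p.col_sub) for p in targets
        ]
    if axis == "v":
        if image_rows is None:
            raise InvalidParameterError("image_rows required for a vertical flip")
        return [
            SubpixelPosition((image_rows - 1) - p.row_sub, p.col_sub) for p in targets
        ]
    raise InvalidParameterError(f"axis must be 'h' or 'v', got {axis!r}")


# ---------------------------------------------------------------------------
# Full per-sheet pipeline and tolerance sweep
# ---------------------------------------------------------------------------

def _refined_positions(
    image: ChannelImage, candidates: Iterable[MaximumCandidate], refine: bool
) -> tuple[list[SubpixelPosition], list[MaximumCandidate]]:
    positions, kept = [], []
    for cand in candidates:
        if refine:
            try:
                positions.append(refine_subpixel(image, cand))
            except CandidateExcluded:
                continue
        else:
            positions.append(SubpixelPosition(float(cand.row), float(cand.col)))
        kept.append(cand)
    return positions, kept


def analyze_sheet(
    reference: ChannelImage,
    target: ChannelImage,
    roi: SquareROI | None = None,
    reference_tolerance: float = 2.0,
    target_tolerance: float = 4.0,
    crosstalk_factor: float = 0.5,
    blur_sigma_px: float = 0.5,
    refine_targets: bool = True,
    flip_axis: Literal["h", "v"] = "h",
    pixel_size_nm: float | None = None,
) -> StedAnalysis:
    """Run the full two-color STED nearest-neighbor analysis on one sheet.

    ``reference`` is the red channel whose maxima are classified as
    nano-clusters; ``target`` is the long-red channel, corrected for spectral
    crosstalk from the reference before any detection.  Distances are
    measured from accepted reference clusters to the nearest target maximum,
    and again after mirroring the target positions (the random control).
    """
    if pixel_size_nm is None:
        pixel_size_nm = reference.pixel_size_nm
    target_corr = correct_crosstalk(target, reference, crosstalk_factor)
    ref_b = blur(reference, blur_sigma_px)
    tgt_b = blur(target_corr, blur_sigma_px)

    ref_maxima = find_maxima(ref_b, roi, reference_tolerance)
    clusters: list[NanoCluster] = []
    for cand in ref_maxima:
        try:
            sub = refine_subpixel(ref_b, cand)
            fits = (
                linescan_fit(ref_b, cand, "horizontal"),
                linescan_fit(ref_b, cand, "vertical"),
            )
        except CandidateExcluded:
            continue
        clusters.append(classify(cand, sub, fits))

    tgt_maxima = find_maxima(tgt_b, roi, target_tolerance)
    tgt_positions, tgt_kept = _refined_positions(tgt_b, tgt_maxima, refine_targets)

    accepted = [cl.subpixel for cl in clusters if cl.accepted]
    if tgt_positions:
        observed = nn_distances(accepted, tgt_positions, pixel_size_nm)
        flipped_targets = flip_control(
            tgt_positions, image_cols=target.shape[1], axis=flip_axis,
            image_rows=target.shape[0],
        )
        flipped = nn_distances(accepted, flipped_targets, pixel_size_nm)
    else:
        observed = np.empty(0)
        flipped = np.empty(0)
    nnset = NNDistanceSet(
        distances_nm=observed,
        flipped_distances_nm=flipped,
        tolerance_pair=(reference_tolerance, target_tolerance),
        pixel_size_nm=pixel_size_nm,
    )
    return StedAnalysis(
        clusters=clusters,
        reference_maxima=ref_maxima,
        target_maxima=tgt_kept,
        target_positions=tgt_positions,
        nn=nnset,
    )


def tolerance_sweep(
    reference: ChannelImage,
    target: ChannelImage,
    roi: SquareROI | None = None,
    pairs: Sequence[tuple[float, float]] = DEFAULT_TOLERANCE_PAIRS,
    **kwargs,
) -> list[NNDistanceSet]:
    """Repeat the full analysis for several (reference, target) tolerances.

    Higher tolerances detect fewer maxima, which increases the shortest
    distances; the sweep verifies that observed-vs-control conclusions are
    threshold independent.
    """
    if len(pairs) == 0:
        raise InvalidParameterError("tolerance pair list is empty")
    return [
        analyze_sheet(
            reference, target, roi,
            reference_tolerance=rt, target_tolerance=tt, **kwargs,
        ).nn
        for rt, tt in pairs
    ]
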