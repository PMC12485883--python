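"""Two-channel colocalization: Pearson correlation with Costes validation.

The Pearson correlation coefficient (PCC) between the raw pixel values of two
channels inside a square ROI is 1 for perfectly overlapping images, 0 for
unrelated images and -1 for an image and its negative.  Small average PCC
differences are validated with the Costes block-scrambling test: one channel
is cut into PSF-sized pixel blocks which are randomly rearranged many times;
the PCC of the true arrangement is compared with the scrambled null
distribution, and ROIs whose Costes P-value falls below 0.95 are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .images import ChannelImage, InvalidParameterError, SquareROI

__all__ = [
    "PCCResult",
    "CostesResult",
    "ZeroVarianceError",
    "pearson",
    "costes_test",
    "filter_by_costes",
]

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Correlation is undefined: a channel is constant inside the ROI."""


@dataclass(frozen=True)
class PCCResult:
    pcc: float
    n_pixels: int
    sheet_id: str = ""
    channel_pair: tuple[str, str] = ("", "")


@dataclass(frozen=True)
class CostesResult:
    """Outcome of the block-scramble significance test for one ROI.

    ``p_value`` is the fraction of scrambled PCCs strictly below the observed
    PCC; the ROI is kept when ``p_value >= 0.95``.
    """

    observed_pcc: float
    n_scrambles: int
    n_below: int
    p_value: float
    block_px: int
    keep: bool


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    af = a.ravel().astype(np.float64)
    bf = b.ravel().astype(np.float64)
    da = af - af.mean()
    db = bf - bf.mean()
    va = float(np.dot(da, da))
    vb = float(np.dot(db, db))
    if va == 0.0 or vb == 0.0:
        raise ZeroVarianceError("constant channel inside ROI; PCC undefined")
    return float(np.dot(da, db) / np.sqrt(va * vb))


def pearson(a: ChannelImage, b: ChannelImage, roi: SquareROI,
            sheet_id: str = "") -> PCCResult:
    """Pearson correlation of raw paired pixel values inside the ROI.

    No background subtraction is applied; the PCC is invariant under positive
    affine transforms of either channel.
    """
    if a.shape != b.shape:
        raise InvalidParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    value = _pcc(a.roi_view(roi), b.roi_view(roi))
    return PCCResult(
        pcc=value,
        n_pixels=roi.side_px**2,
        sheet_id=sheet_id,
        channel_pair=(a.channel_label, b.channel_label),
    )


def costes_test(
    a: ChannelImage,
    b: ChannelImage,
    roi: SquareROI,
    block_px: int = 4,
    n_scrambles: int = 100,
    seed: int = 0,
    p_threshold: float = 0.95,
) -> CostesResult:
    """Costes block-scramble significance test of the PCC inside an ROI.

    Channel ``b`` (the reporter channel) is partitioned into non-overlapping
    ``block_px`` x ``block_px`` tiles whose positions are permuted uniformly at
    random ``n_scrambles`` times; channel ``a`` stays fixed.  If the ROI side
    is not a multiple of ``block_px`` the ROI is cropped (bottom/right) to the
    largest multiple, and the observed PCC is computed on the same cropped
    support as the null.  Ties between scrambled and observed PCC count as
    not-below (conservative toward exclusion).
    """
    if n_scrambles < 20:
        raise InvalidParameterError(
            f"n_scrambles must be >= 20, got {n_scrambles}"
        )
    if block_px < 1:
        raise InvalidParameterError(f"block_px must be >= 1, got {block_px}")
    if roi.side_px < block_px:
        raise InvalidParameterError(
            f"ROI side {roi.side_px} is smaller than one {block_px}-px block"
        )
    if a.shape != b.shape:
        raise InvalidParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    n_blocks = roi.side_px // block_px
    side = n_blocks * block_px
    a_crop = a.roi_view(roi)[:side, :side]
    b_crop = b.roi_view(roi)[:side, :side]
    observed = _pcc(a_crop, b_crop)
    # tiles: (n_blocks*n_blocks, block_px, block_px), row-major tile order
    tiles = (
        b_crop.reshape(n_blocks, block_px, n_blocks, block_px)
        .swapaxes(1, 2)
        .reshape(-1, block_px, block_px)
    )
    rng = np.random.default_rng(seed)
    n_below = 0
    for _ in range(n_scrambles):
        perm = rng.permutation(tiles.shape[0])
        scrambled = (
            tiles[perm]
            .reshape(n_blocks, n_blocks, block_px, block_px)
            .swapaxes(1, 2)
            .reshape(side, side)
        )
        if _pcc(a_crop, scrambled) < observed:
            n_below += 1
    p_value = n_below / n_scrambles
    return CostesResult(
        observed_pcc=observed,
        n_scrambles=n_scrambles,
        n_below=n_below,
        p_value=p_value,
        block_px=block_px,
        keep=bool(p_value >= p_threshold),
    )


def filter_by_costes(
    results: Sequence[tuple[PCCResult, CostesResult]]
) -> list[PCCResult]:
    """Keep only PCCs whose Costes test passed, preserving input order."""
    kept = [pcc for pcc, costes in results if costes.keep]
    n_excluded = len(results) - len(kept)
    if n_excluded:
        logger.info(
            "Costes filter: excluded %d of %d PCC values", n_excluded, len(results)
        )
    return kept
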