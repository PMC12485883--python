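"""Square-ROI intensity quantification and retention-assay statistics.

Implements the epi-fluorescence quantification chain: mean ROI intensity with
local background subtraction, per-replicate normalization to a control
construct with a t-based 95% confidence interval (significant when the CI
excludes 100%), the retained-reporter vs. expression regression forced
through the origin, and immunoprecipitation band-intensity ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .images import ChannelImage, InvalidParameterError, SquareROI

__all__ = [
    "IntensityMeasurement",
    "RegressionFit",
    "NormalizedComparison",
    "BandRatio",
    "measure_roi",
    "normalize_to_control",
    "fit_through_origin",
    "band_ratio",
    "plot_retention",
]


@dataclass(frozen=True)
class IntensityMeasurement:
    """Background-corrected mean intensity of one ROI on one channel.

    ``mean_corrected`` is deliberately not clipped at zero: clipping would
    bias replicate averages for sheets near background.
    """

    mean_raw: float
    mean_background: float
    mean_corrected: float
    channel_label: str = ""
    sheet_id: str = ""


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares line through the origin, y = theta * x.

    ``r_squared`` uses the centered total sum of squares (may be negative for
    pathological data); the uncentered variant is kept alongside.
    """

    theta: float
    r_squared: float
    n: int
    r_squared_uncentered: float = float("nan")


@dataclass(frozen=True)
class NormalizedComparison:
    """Per-replicate test/control ratios (control = 100%) with a 95% t-CI."""

    ratios_pct: tuple[float, ...]
    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    significant: bool


@dataclass(frozen=True)
class BandRatio:
    """Co-precipitated endogenous band related to the pulled-down GFP band."""

    endo_integrated: float
    gfp_integrated: float
    ratio: float
    ratio_normalized_pct: float


def measure_roi(
    image: ChannelImage, roi: SquareROI, background_roi: SquareROI
) -> IntensityMeasurement:
    """Mean intensity in ``roi`` minus the mean of a background ROI nearby."""
    roi.require_inside(image.shape)
    background_roi.require_inside(image.shape)
    if roi.overlaps(background_roi):
        warnings.warn(
            "analysis ROI and background ROI overlap", UserWarning, stacklevel=2
        )
    mean_raw = float(image.roi_view(roi).mean())
    mean_background = float(image.roi_view(background_roi).mean())
    return IntensityMeasurement(
        mean_raw=mean_raw,
        mean_background=mean_background,
        mean_corrected=mean_raw - mean_background,
        channel_label=image.channel_label,
    )


def normalize_to_control(
    values_by_replicate: Mapping[str, Mapping[str, float]],
    confidence: float = 0.95,
) -> NormalizedComparison:
    """Normalize per-replicate test values to the replicate's control (=100%).

    The two-sided CI of the mean ratio uses the t-distribution with n-1
    degrees of freedom; the difference is called significant when the CI
    excludes 100%.
    """
    if len(values_by_replicate) < 2:
        raise InvalidParameterError(
            "at least 2 replicates are required for a confidence interval"
        )
    ratios = []
    for rep, pair in values_by_replicate.items():
        control, test = float(pair["control"]), float(pair["test"])
        if control <= 0:
            raise InvalidParameterError(
                f"replicate {rep!r}: control value must be > 0, got {control}"
            )
        ratios.append(100.0 * test / control)
    arr = np.asarray(ratios, dtype=np.float64)
    n = arr.size
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    lo, hi = mean - tcrit * sem, mean + tcrit * sem
    return NormalizedComparison(
        ratios_pct=tuple(float(r) for r in arr),
        mean_pct=mean,
        ci_low_pct=lo,
        ci_high_pct=hi,
        significant=bool(lo > 100.0 or hi < 100.0),
    )


def fit_through_origin(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Fit y = theta * x by least squares with the line forced through (0, 0).

    theta = sum(x*y) / sum(x^2).  R^2 is reported against the centered total
    sum of squares; the uncentered variant (against sum(y^2)) is also stored.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidParameterError("x and y must be 1D sequences of equal length")
    if xa.size < 2:
        raise InvalidParameterError("at least 2 points are required")
    sxx = float(np.dot(xa, xa))
    if sxx == 0.0:
        raise InvalidParameterError("all x values are zero; slope is undefined")
    theta = float(np.dot(xa, ya)) / sxx
    resid = ya - theta * xa
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(ya - ya.mean(), ya - ya.mean()))
    ss_tot_unc = float(np.dot(ya, ya))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    r2_unc = 1.0 - ss_res / ss_tot_unc if ss_tot_unc > 0 else float("nan")
    return RegressionFit(
        theta=theta, r_squared=r2, n=int(xa.size), r_squared_uncentered=r2_unc
    )


def band_ratio(endo: float, gfp: float, control_ratio: float) -> BandRatio:
    """Relate a co-precipitated endogenous band to its GFP bait band.

    ``ratio_normalized_pct`` expresses endo/gfp as a percentage of the
    control construct's ratio (control = 100%).
    """
    if gfp <= 0:
        raise InvalidParameterError(f"gfp integrated intensity must be > 0, got {gfp}")
    if control_ratio <= 0:
        raise InvalidParameterError(
            f"control_ratio must be > 0, got {control_ratio}"
        )
    ratio = endo / gfp
    return BandRatio(
        endo_integrated=float(endo),
        gfp_integrated=float(gfp),
        ratio=float(ratio),
        ratio_normalized_pct=float(100.0 * ratio / control_ratio),
    )


def plot_retention(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float], RegressionFit]],
    path: str | None = None,
    xlabel: str = "expression (GFP intensity, a.u.)",
    ylabel: str = "retained reporter (mCherry intensity, a.u.)",
):
    """Scatter of retained reporter vs expression with origin-forced lines.

    ``groups`` maps construct name -> (x, y, fit).  Returns the figure;
    saves to ``path`` (PNG/SVG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, (x, y, fit) in groups.items():
        xa = np.asarray(x, dtype=float)
        sc = ax.scatter(xa, y, s=14, alpha=0.6, label=None)
        xs = np.linspace(0.0, float(xa.max()) if xa.size else 1.0, 50)
        ax.plot(
            xs, fit.theta * xs, color=sc.get_facecolor()[0],
            label=f"{name}: $\\theta$={fit.theta:.3f}, $R^2$={fit.r_squared:.2f}",
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
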