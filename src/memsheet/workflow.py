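"""End-to-end runners, manifests, provenance, and group statistics.

Chains the pipeline stages into the three experiment types — the
antibody-patching retention assay, ROI colocalization with Costes validation,
and the STED nearest-neighbor analysis — on real TIFF inputs described by a
manifest CSV or on synthetic scenes generated in place.  Every run writes its
result tables as CSV next to a provenance YAML recording inputs, parameters,
seeds and the package version, so each number is reproducible from the
provenance record alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.spatial import cKDTree

from . import __version__
from .coloc import costes_test, pearson
from .images import (
    ChannelImage,
    InvalidParameterError,
    SquareROI,
    read_channel_tiff,
)
from .roi import fit_through_origin, measure_roi, normalize_to_control
from .sted import analyze_sheet, tolerance_sweep, DEFAULT_TOLERANCE_PAIRS
from .synthetic import (
    EPI_PIXEL_NM,
    epi_render_params,
    generate_domain_field,
    make_two_color_scene,
    place_emitters,
    render_channel,
    render_domain_reporter,
    write_scene,
)

__all__ = [
    "RunConfig",
    "run_experiment",
    "summarize_groups",
    "read_manifest",
    "simulate_retention_dataset",
    "simulate_coloc_sheet",
]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("simulate", "retention", "coloc", "sted_nn")


@dataclass
class RunConfig:
    """Validated configuration of one run (possibly several chained stages)."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    manifest: Path | None = None
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not self.stages:
            raise InvalidParameterError("config must list at least one stage")
        for stage in self.stages:
            if stage not in EXPERIMENTS:
                raise InvalidParameterError(
                    f"unknown stage {stage!r}; expected one of {EXPERIMENTS}"
                )
        if self.manifest is not None:
            self.manifest = Path(self.manifest)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stages = raw.get("stages") or [raw.get("experiment")]
        if stages == [None]:
            raise InvalidParameterError(
                f"{path}: config must set 'experiment' or 'stages'"
            )
        return cls(
            stages=list(stages),
            out_dir=raw.get("out_dir", "."),
            seed=int(raw.get("seed", 0)),
            manifest=raw.get("manifest"),
            params=raw.get("params", {}),
        )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sheets manifest CSV and pre-flight check referenced TIFFs.

    Required columns: ``sheet_id, construct, condition, treatment, replicate``
    plus ROI coordinates (``roi_row0, roi_col0, roi_side, bg_row0, bg_col0,
    bg_side``) and one ``file_<channel>`` column per channel.  File paths are
    resolved relative to the manifest location.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {
        "sheet_id", "construct", "condition", "treatment", "replicate",
        "roi_row0", "roi_col0", "roi_side", "bg_row0", "bg_col0", "bg_side",
    }
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: manifest misses columns {sorted(missing)}")
    file_cols = [c for c in df.columns if c.startswith("file_")]
    if not file_cols:
        raise InvalidParameterError(f"{path}: manifest has no file_<channel> columns")
    for col in file_cols:
        for value in df[col]:
            tiff = path.parent / str(value)
            if not tiff.exists():
                raise FileNotFoundError(f"manifest references missing TIFF: {tiff}")
    return df


def _load_sheet_channels(
    row: pd.Series, manifest_dir: Path, pixel_size_nm: float
) -> dict[str, ChannelImage]:
    channels = {}
    for col in row.index:
        if col.startswith("file_"):
            label = col[len("file_"):]
            channels[label] = read_channel_tiff(
                manifest_dir / str(row[col]), pixel_size_nm, label
            )
    return channels


def _rois_from_row(row: pd.Series) -> tuple[SquareROI, SquareROI]:
    roi = SquareROI(int(row.roi_row0), int(row.roi_col0), int(row.roi_side))
    bg = SquareROI(int(row.bg_row0), int(row.bg_col0), int(row.bg_side))
    return roi, bg


# ---------------------------------------------------------------------------
# Synthetic experiment generators (study conditions)
# ---------------------------------------------------------------------------

def simulate_retention_dataset(
    affinity: float,
    n_sheets: int = 60,
    seed: int = 0,
    construct: str = "",
    shape: tuple[int, int] = (72, 72),
    margin_px: int = 12,
    n_clusters_range: tuple[int, int] = (20, 200),
    n_reporter: int = 1500,
    capture_radius_px: float = 1.5,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate one construct's antibody-patching retention experiment.

    Per sheet: a fresh PIP2-like domain field; protein nano-clusters placed
    with the construct's ``affinity`` for the domain and an expression level
    (cluster count) varying across sheets; reporter molecules placed in the
    domain (affinity 1); the retained reporter is the subset within
    ``capture_radius_px`` of any protein cluster (patching traps proximal
    reporter).  Both channels are rendered with shot noise and quantified
    with :func:`memsheet.roi.measure_roi` exactly like real data.  Returns a
    tidy table with background-corrected GFP (expression) and mCherry
    (retained reporter) intensities per sheet.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    roi = SquareROI(margin_px, margin_px, rows - 2 * margin_px)
    bg_roi = SquareROI(0, 0, max(margin_px - 4, 4))
    mask = np.zeros(shape, dtype=bool)
    mask[margin_px:rows - margin_px, margin_px:cols - margin_px] = True
    records = []
    for i in range(n_sheets):
        s = [int(x) for x in rng.integers(0, 2**31 - 1, size=6)]
        domain = generate_domain_field(shape, correlation_length_px=4.0,
                                       enriched_fraction=0.3, seed=s[0])
        n_clusters = int(rng.integers(*n_clusters_range))
        protein = place_emitters(
            domain, n_clusters, affinity, copies_mean=4.0, seed=s[1],
            channel_label="gfp", mask=mask,
        )
        reporter = place_emitters(
            domain, n_reporter, 1.0, copies_mean=1.0, seed=s[2],
            channel_label="mcherry", mask=mask,
        )
        tree = cKDTree(protein.centers)
        d, _ = tree.query(reporter.centers, k=1)
        retained = reporter.centers[d <= capture_radius_px]
        params_g = epi_render_params(
            photons_per_emitter=200.0, background_level=20.0, seed=s[3]
        )
        params_r = epi_render_params(
            photons_per_emitter=200.0, background_level=20.0, seed=s[4]
        )
        gfp_img = render_channel(protein, params_g)
        if len(retained):
            from dataclasses import replace

            retained_set = replace(
                reporter,
                centers=retained,
                copies=np.ones(len(retained), dtype=np.int64),
            )
            mch_img = render_channel(retained_set, params_r)
        else:  # nothing trapped: background only
            bg_rng = np.random.default_rng(params_r.seed)
            mch_img = ChannelImage(
                bg_rng.poisson(params_r.background_level, shape).astype(float),
                pixel_size_nm=params_r.pixel_size_nm,
                channel_label="mcherry",
            )
        gfp = measure_roi(gfp_img, roi, bg_roi)
        mch = measure_roi(mch_img, roi, bg_roi)
        records.append(
            dict(
                sheet_id=f"{construct or affinity}-{i:03d}",
                construct=construct or f"affinity_{affinity}",
                condition="aGFP",
                treatment="none",
                replicate=f"rep{i % n_replicates + 1}",
                affinity=affinity,
                n_clusters=n_clusters,
                n_retained=int(len(retained)),
                gfp=gfp.mean_corrected,
                mcherry=mch.mean_corrected,
            )
        )
    return pd.DataFrame.from_records(records)


def simulate_coloc_sheet(
    affinity: float,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    n_clusters: int = 150,
) -> tuple[ChannelImage, ChannelImage]:
    """One synthetic sheet for PCC-vs-affinity checks.

    Returns (protein channel, domain-reporter channel) rendered over the same
    domain field; the PCC between them grows with the placement affinity.
    """
    rng = np.random.default_rng(seed)
    s = [int(x) for x in rng.integers(0, 2**31 - 1, size=4)]
    domain = generate_domain_field(shape, correlation_length_px=6.0,
                                   enriched_fraction=0.3, seed=s[0])
    protein = place_emitters(domain, n_clusters, affinity, copies_mean=4.0,
                             seed=s[1], channel_label="gfp")
    pimg = render_channel(
        protein,
        epi_render_params(photons_per_emitter=300.0, background_level=20.0, seed=s[2]),
    )
    rimg = render_domain_reporter(
        domain,
        epi_render_params(background_level=20.0, seed=s[3]),
        amplitude=150.0,
        channel_label="mcherry",
    )
    return pimg, rimg


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_simulate(config: RunConfig, out: Path) -> dict:
    p = config.params.get("simulate", {})
    n_scenes = int(p.get("n_scenes", 1))
    shape = tuple(p.get("shape", (256, 256)))
    manifest_rows = []
    for i in range(n_scenes):
        scene = make_two_color_scene(
            shape=shape,
            preset=p.get("preset", "sted"),
            n_clusters=tuple(p.get("n_clusters", (500, 500))),
            affinity=tuple(p.get("affinity", (2.0, 0.0))),
            shared_fraction=float(p.get("shared_fraction", 0.0)),
            crosstalk_factor=float(p.get("crosstalk_factor", 0.0)),
            seed=config.seed + i,
        )
        scene_dir = out / f"scene_{i:03d}"
        written = write_scene(scene, scene_dir)
        labels = list(scene.images)
        side = min(shape) - 16
        manifest_rows.append(
            {
                "sheet_id": f"scene_{i:03d}",
                "construct": "synthetic",
                "condition": "directly_fixed",
                "treatment": "none",
                "replicate": f"rep{i + 1}",
                "roi_row0": 8, "roi_col0": 8, "roi_side": side,
                "bg_row0": 0, "bg_col0": 0, "bg_side": 8,
                **{
                    f"file_{label}": str(written[label].relative_to(out))
                    for label in labels
                },
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return {"manifest": str(manifest_path), "n_scenes": n_scenes}


def _run_retention(config: RunConfig, out: Path) -> dict:
    p = config.params.get("retention", {})
    manifest_path = config.manifest or out / "manifest.csv"
    df = read_manifest(manifest_path)
    pixel_size = float(p.get("pixel_size_nm", EPI_PIXEL_NM))
    expr_ch = p.get("expression_channel", "gfp")
    rep_ch = p.get("reporter_channel", "mcherry")
    rows = []
    for _, row in df.iterrows():
        channels = _load_sheet_channels(row, Path(manifest_path).parent, pixel_size)
        roi, bg = _rois_from_row(row)
        for label in (expr_ch, rep_ch):
            if label not in channels:
                raise InvalidParameterError(
                    f"sheet {row.sheet_id}: channel {label!r} not in manifest"
                )
        expr = measure_roi(channels[expr_ch], roi, bg)
        rep = measure_roi(channels[rep_ch], roi, bg)
        rows.append(
            dict(
                sheet_id=row.sheet_id, construct=row.construct,
                condition=row.condition, treatment=row.treatment,
                replicate=row.replicate,
                expression=expr.mean_corrected, retained=rep.mean_corrected,
                expression_raw=expr.mean_raw, retained_raw=rep.mean_raw,
            )
        )
    measurements = pd.DataFrame(rows)
    measurements.to_csv(out / "measurements.csv", index=False)
    fits = []
    for construct, grp in measurements.groupby("construct", sort=True):
        if len(grp) >= 2 and float(np.dot(grp.expression, grp.expression)) > 0:
            fit = fit_through_origin(grp.expression.to_numpy(), grp.retained.to_numpy())
            fits.append(
                dict(construct=construct, theta=fit.theta,
                     r_squared=fit.r_squared, n=fit.n)
            )
    pd.DataFrame(fits).to_csv(out / "retention_fits.csv", index=False)
    outputs = {"measurements": str(out / "measurements.csv"),
               "retention_fits": str(out / "retention_fits.csv")}
    control = p.get("control_construct")
    if control:
        comparisons = []
        rep_means = (
            measurements.groupby(["construct", "replicate"], sort=True)["retained"]
            .mean().unstack("construct")
        )
        for construct in rep_means.columns:
            if construct == control:
                continue
            paired = rep_means[[control, construct]].dropna()
            if len(paired) < 2 or (paired[control] <= 0).any():
                continue
            cmp = normalize_to_control(
                {
                    rep: {"control": paired.at[rep, control],
                          "test": paired.at[rep, construct]}
                    for rep in paired.index
                }
            )
            comparisons.append(
                dict(construct=construct, control=control,
                     mean_pct=cmp.mean_pct, ci_low_pct=cmp.ci_low_pct,
                     ci_high_pct=cmp.ci_high_pct, significant=cmp.significant)
            )
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
        outputs["comparisons"] = str(out / "comparisons.csv")
    return outputs


def _run_coloc(config: RunConfig, out: Path) -> dict:
    p = config.params.get("coloc", {})
    manifest_path = config.manifest or out / "manifest.csv"
    df = read_manifest(manifest_path)
    pixel_size = float(p.get("pixel_size_nm", EPI_PIXEL_NM))
    file_cols = [c for c in df.columns if c.startswith("file_")]
    ch_a = p.get("channel_a", file_cols[0][len("file_"):])
    ch_b = p.get("channel_b", file_cols[1][len("file_"):] if len(file_cols) > 1 else ch_a)
    block_px = int(p.get("block_px", 4))
    n_scrambles = int(p.get("n_scrambles", 100))
    p_threshold = float(p.get("p_threshold", 0.95))
    rows = []
    for i, (_, row) in enumerate(df.iterrows()):
        channels = _load_sheet_channels(row, Path(manifest_path).parent, pixel_size)
        roi, _ = _rois_from_row(row)
        res = pearson(channels[ch_a], channels[ch_b], roi, sheet_id=str(row.sheet_id))
        costes = costes_test(
            channels[ch_a], channels[ch_b], roi, block_px=block_px,
            n_scrambles=n_scrambles, seed=config.seed + i, p_threshold=p_threshold,
        )
        rows.append(
            dict(sheet_id=row.sheet_id, channel_a=ch_a, channel_b=ch_b,
                 pcc=res.pcc, p_value=costes.p_value, keep=costes.keep)
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "coloc.csv", index=False)
    return {"coloc": str(out / "coloc.csv"),
            "n_excluded": int((~table.keep).sum()) if len(table) else 0}


def _run_sted(config: RunConfig, out: Path) -> dict:
    p = config.params.get("sted", {})
    pixel_size = float(p.get("pixel_size_nm", 25.0))
    base = Path(config.manifest).parent if config.manifest else out
    ref = read_channel_tiff(base / p["reference_tiff"], pixel_size, "red")
    tgt = read_channel_tiff(base / p["target_tiff"], pixel_size, "longred")
    roi = None
    if "roi" in p:
        r = p["roi"]
        roi = SquareROI(int(r["row0"]), int(r["col0"]), int(r["side"]))
    kwargs = dict(
        crosstalk_factor=float(p.get("crosstalk_factor", 0.5)),
        blur_sigma_px=float(p.get("blur_sigma_px", 0.5)),
        refine_targets=bool(p.get("refine_targets", True)),
        flip_axis=p.get("flip_axis", "h"),
        pixel_size_nm=pixel_size,
    )
    pairs = [tuple(pair) for pair in p.get("tolerance_pairs", DEFAULT_TOLERANCE_PAIRS)]
    results = tolerance_sweep(ref, tgt, roi, pairs=pairs, **kwargs)
    summary = pd.DataFrame(
        [
            dict(
                ref_tolerance=nn.tolerance_pair[0],
                target_tolerance=nn.tolerance_pair[1],
                n_clusters=nn.n,
                mean_nm=nn.mean_nm,
                flipped_mean_nm=nn.flipped_mean_nm,
            )
            for nn in results
        ]
    )
    summary.to_csv(out / "nn_summary.csv", index=False)
    first = analyze_sheet(
        ref, tgt, roi,
        reference_tolerance=pairs[0][0], target_tolerance=pairs[0][1], **kwargs,
    )
    clusters = pd.DataFrame(
        [
            dict(
                row=cl.candidate.row, col=cl.candidate.col,
                prominence=cl.candidate.prominence,
                row_sub=cl.subpixel.row_sub, col_sub=cl.subpixel.col_sub,
                r2_h=cl.fits[0].r_squared, r2_v=cl.fits[1].r_squared,
                center_h=cl.fits[0].center_px, center_v=cl.fits[1].center_px,
                accepted=cl.accepted,
            )
            for cl in first.clusters
        ]
    )
    clusters.to_csv(out / "clusters.csv", index=False)
    return {"nn_summary": str(out / "nn_summary.csv"),
            "clusters": str(out / "clusters.csv")}


_RUNNERS = {
    "simulate": _run_simulate,
    "retention": _run_retention,
    "coloc": _run_coloc,
    "sted_nn": _run_sted,
}


def run_experiment(config: RunConfig) -> dict:
    """Run the configured stages in order; write tables and provenance.

    Deterministic for identical configuration: re-running produces
    byte-identical CSVs.  Missing inputs fail before any computation.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if config.manifest is not None and not Path(config.manifest).exists():
        raise FileNotFoundError(f"manifest not found: {config.manifest}")
    outputs: dict = {}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        outputs[stage] = _RUNNERS[stage](config, out)
    provenance = {
        "memsheet_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "manifest": str(config.manifest) if config.manifest else None,
        "params": config.params,
        "outputs": outputs,
    }
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return outputs


# ---------------------------------------------------------------------------
# Group summaries and stock hypothesis tests
# ---------------------------------------------------------------------------

def summarize_groups(
    table: pd.DataFrame,
    value: str,
    groups: str | Sequence[str],
    test: str = "auto",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +- SD with a stock hypothesis test.

    ``test='auto'`` picks Welch-free Student t for two groups, one-way ANOVA
    for more, and two-way ANOVA (statsmodels) when two grouping columns are
    given.  Groups with a single observation get SD reported as missing.
    Returns (summary table, tests table).
    """
    group_cols = [groups] if isinstance(groups, str) else list(groups)
    grouped = table.groupby(group_cols, sort=True)[value]
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    summary = summary.rename(columns={"std": "sd", "count": "n"})

    tests: list[dict] = []
    if len(group_cols) == 2 and test in ("auto", "two_way_anova"):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = table.rename(columns={value: "_y"})
        model = smf.ols(
            f"_y ~ C({group_cols[0]}) * C({group_cols[1]})", data=data
        ).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        for name, row in anova.iterrows():
            if name == "Residual":
                continue
            tests.append(dict(test="two-way ANOVA", term=name,
                              statistic=float(row.F), p_value=float(row["PR(>F)"])))
    else:
        samples = [grp.to_numpy(dtype=float) for _, grp in grouped]
        if len(samples) < 2:
            raise InvalidParameterError("at least 2 groups are required for a test")
        if all(np.std(s) == 0 for s in samples) and test == "auto":
            logger.warning("exact separation: zero within-group variance")
        if len(samples) == 2 and test in ("auto", "t"):
            stat, pval = stats.ttest_ind(*samples)
            tests.append(dict(test="unpaired two-tailed t", term=value,
                              statistic=float(stat), p_value=float(pval)))
        else:
            stat, pval = stats.f_oneway(*samples)
            tests.append(dict(test="one-way ANOVA", term=value,
                              statistic=float(stat), p_value=float(pval)))
    return summary, pd.DataFrame(tests)
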