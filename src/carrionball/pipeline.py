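"""End-to-end orchestration: score images, simulate studies, analyze tables.

A run joins image-derived roundness scores onto the breeding table by
``pair_id``, fits the prediction models and variance comparisons, and
writes a machine-readable RunReport (JSON) listing every output file with
a content hash, so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .errors import InvalidInputError
from .inference import (
    FitSummary,
    VarianceComparison,
    check_normality,
    correlate,
    run_prediction_models,
    run_variance_comparisons,
)
from .shape_scoring import score_carcass
from .synthetic_data import ArtifactSpec, StudyParams, link_images_to_table, simulate_study

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scoring a manifest
# ---------------------------------------------------------------------------


def score_manifest(
    manifest: pd.DataFrame,
    occlusions: dict | None = None,
    **score_options,
) -> pd.DataFrame:
    """Score every pair in a manifest; returns the scores table."""
    occlusions = occlusions or {}
    rows = []
    for pair_id, group in manifest.groupby("pair_id", sort=True):
        views = {}
        for row in group.itertuples(index=False):
            px = None if pd.isna(row.px_per_mm) else float(row.px_per_mm)
            views[row.view] = cio.load_image(row.path, row.view, px)
        if set(views) != {"top", "side"}:
            raise InvalidInputError(
                f"pair {pair_id} needs exactly one top and one side image, "
                f"got views {sorted(views)}"
            )
        result = score_carcass(
            views["top"],
            views["side"],
            occlusions_top=occlusions.get((str(pair_id), "top"), ()),
            occlusions_side=occlusions.get((str(pair_id), "side"), ()),
            **score_options,
        )
        rows.append(
            {
                "pair_id": pair_id,
                "roundness_top": result.top.roundness,
                "roundness_side": result.side.roundness,
                "roundness_overall": result.overall,
                "area_top_px2": result.top.area_px2,
                "perimeter_top_px": result.top.perimeter_px,
                "area_side_px2": result.side.area_px2,
                "perimeter_side_px": result.side.perimeter_px,
                "warnings": "; ".join(result.warnings),
            }
        )
        logger.info("scored %s: overall %.4f", pair_id, result.overall)
    return pd.DataFrame(rows, columns=cio.SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = (
    "roundness",
    "brood_size",
    "avg_larval_mass",
    "brood_mass",
    "carcass_mass_unprepared",
    "carcass_mass_prepared",
)


def summarize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, SEM and range per key column (those present in the table).

    With a single row the SD/SEM are undefined and flagged as NaN.
    """
    if len(table) == 0:
        raise InvalidInputError("cannot summarize an empty table")
    rows = []
    for col in SUMMARY_COLUMNS:
        if col not in table.columns:
            continue
        x = table[col].dropna().to_numpy(float)
        if len(x) == 0:
            continue
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        rows.append(
            {
                "variable": col,
                "n": len(x),
                "mean": float(np.mean(x)),
                "sd": sd,
                "sem": sd / np.sqrt(len(x)) if len(x) > 1 else float("nan"),
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "n", "mean", "sd", "sem", "min", "max"])


# ---------------------------------------------------------------------------
# analysis stage
# ---------------------------------------------------------------------------

NORMALITY_COLUMNS = (
    "male_lifespan",
    "female_lifespan",
    "brood_size",
    "avg_larval_mass",
    "roundness",
)


@dataclass
class AnalysisResult:
    models: dict[str, FitSummary]
    variance_tests: dict[str, VarianceComparison]
    normality: dict[str, tuple[float, float]]
    brood_correlation: tuple[float, float]
    summary: pd.DataFrame


def analyze_table(table: pd.DataFrame) -> AnalysisResult:
    """Run the full statistical analysis on a study table."""
    normality = {c: check_normality(table[c]) for c in NORMALITY_COLUMNS}
    models = run_prediction_models(table)
    variance_tests = run_variance_comparisons(table)
    brood_r = correlate(table["brood_size"], table["brood_mass"])
    return AnalysisResult(
        models=models,
        variance_tests=variance_tests,
        normality=normality,
        brood_correlation=brood_r,
        summary=summarize_scores(table),
    )


def _plot_regressions(table: pd.DataFrame, out_dir: Path) -> list[Path]:
    """Raw-value scatter plots with fitted lines for the two headline
    relationships: roundness vs male size, female lifespan vs roundness."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("male_size", "roundness", "Male pronotum width (mm)", "Nest roundness"),
        (
            "roundness",
            "female_lifespan",
            "Nest roundness",
            "Female lifespan after reproduction (days)",
        ),
    ]
    paths = []
    for x, y, xlabel, ylabel in panels:
        sub = table[[x, y]].dropna()
        slope, intercept = np.polyfit(sub[x], sub[y], 1)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(sub[x], sub[y], s=18, color="k")
        grid = np.linspace(sub[x].min(), sub[x].max(), 50)
        ax.plot(grid, intercept + slope * grid, color="firebrick")
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = out_dir / f"{y}_vs_{x}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def write_analysis(result: AnalysisResult, out_dir: str | Path, table: pd.DataFrame,
                   plots: bool = True) -> list[Path]:
    """Write model tables, traces, variance tests and plots; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for response, fit in result.models.items():
        path = out_dir / f"model_{response}.csv"
        frame = fit.to_frame()
        frame.insert(1, "response", response)
        frame["mass_variant"] = fit.mass_variant
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        tpath = out_dir / f"trace_{response}.csv"
        pd.DataFrame(
            fit.elimination_trace, columns=["dropped_term", "aic_before", "aic_after"]
        ).to_csv(tpath, index=False, float_format="%.10g")
        written.append(tpath)

    vrows = [dataclasses.asdict(v) for v in result.variance_tests.values()]
    vpath = out_dir / "variance_tests.csv"
    vframe = pd.DataFrame(vrows)
    vframe["df"] = vframe["df"].map(lambda d: f"{d[0]},{d[1]}")
    vframe.to_csv(vpath, index=False, float_format="%.10g")
    written.append(vpath)
    # footer: df convention note
    (out_dir / "variance_tests_README.txt").write_text(
        "Degrees of freedom are reported as (numerator, denominator) = "
        "(1, n - 2), the conventional ordering for a two-group Levene test.\n"
    )
    written.append(out_dir / "variance_tests_README.txt")

    spath = out_dir / "summary_statistics.csv"
    result.summary.to_csv(spath, index=False, float_format="%.10g")
    written.append(spath)

    npath = out_dir / "normality.csv"
    pd.DataFrame(
        [
            {"variable": k, "shapiro_w": w, "p": p}
            for k, (w, p) in result.normality.items()
        ]
    ).to_csv(npath, index=False, float_format="%.10g")
    written.append(npath)

    if plots:
        written.extend(_plot_regressions(table, out_dir))
    return written


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_pairs: int = 45
    simulate: bool = True
    render_images: bool = True
    table_path: str | None = None  # used when simulate=False
    manifest_path: str | None = None
    occlusions_path: str | None = None
    filter_diameter: int = 25
    perimeter_estimator: str = "contour"
    artifacts: ArtifactSpec | None = None
    study_params: StudyParams | None = None
    plots: bool = True
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Execute simulate -> render -> score -> analyze and write a RunReport.

    Image scores are joined onto the study table by ``pair_id``; pairs
    present on only one side are reported as join warnings and the run
    continues on the intersection.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    report: dict = {"stages": {}, "warnings": warnings}

    snapshot = dataclasses.asdict(config)
    if config.study_params is not None:
        snapshot["study_params"] = dataclasses.asdict(config.study_params)
    if config.artifacts is not None:
        snapshot["artifacts"] = dataclasses.asdict(config.artifacts)
    (out_dir / "config_snapshot.json").write_text(json.dumps(snapshot, indent=2))

    # --- table ---
    if config.simulate:
        params = config.study_params or StudyParams(
            n_pairs=config.n_pairs, seed=config.seed
        )
        table = simulate_study(params)
        table.to_csv(out_dir / "study_table.csv", index=False)
        report["stages"]["simulate"] = {"n_pairs": len(table)}
    else:
        if not config.table_path:
            raise InvalidInputError("table_path required when simulate=False")
        table = cio.read_study_table(config.table_path)
        report["stages"]["load_table"] = {"n_pairs": len(table)}

    # --- images + scoring ---
    scores = None
    if config.simulate and config.render_images:
        images_dir = out_dir / "images"
        manifest = link_images_to_table(
            table, images_dir, artifacts=config.artifacts, seed=config.seed
        )
        occlusions = cio.read_occlusions(images_dir / "occlusions.csv")
        report["stages"]["render"] = {"n_images": len(manifest)}
    elif config.manifest_path:
        manifest = cio.read_manifest(config.manifest_path)
        occlusions = (
            cio.read_occlusions(config.occlusions_path)
            if config.occlusions_path
            else {}
        )
    else:
        manifest, occlusions = None, {}

    if manifest is not None:
        scores = score_manifest(
            manifest,
            occlusions,
            filter_diameter=config.filter_diameter,
            perimeter_estimator=config.perimeter_estimator,
        )
        cio.write_scores(scores, out_dir / "scores.csv")
        report["stages"]["score"] = {"n_pairs": len(scores)}

    # --- join ---
    if scores is not None:
        table_ids = set(table["pair_id"].astype(str))
        score_ids = set(scores["pair_id"].astype(str))
        for pid in sorted(table_ids - score_ids):
            warnings.append(f"pair {pid} in table but not scored")
        for pid in sorted(score_ids - table_ids):
            warnings.append(f"pair {pid} scored but not in table")
        merged = table.merge(
            scores[["pair_id", "roundness_overall"]], on="pair_id", how="inner"
        )
        # the image-derived score becomes the analysis roundness
        merged["roundness"] = merged["roundness_overall"]
        analysis_table = merged.drop(columns=["roundness_overall"])
    else:
        analysis_table = table

    # --- analysis ---
    result = analyze_table(analysis_table)
    write_analysis(result, out_dir / "analysis", analysis_table,
                   plots=config.plots)
    report["stages"]["analyze"] = {
        "n_models": len(result.models),
        "n_variance_tests": len(result.variance_tests),
        "n_pairs_analyzed": len(analysis_table),
        "brood_size_brood_mass_r": result.brood_correlation[0],
    }
    report["key_results"] = {
        "models": {
            resp: {
                "retained": fit.retained,
                "aic": fit.aic,
                "mass_variant": fit.mass_variant,
                "terms": {
                    t: dataclasses.asdict(ts) for t, ts in fit.terms.items()
                },
            }
            for resp, fit in result.models.items()
        },
        "variance_tests": {
            resp: {"F": v.f, "df": list(v.df), "p": v.p}
            for resp, v in result.variance_tests.items()
        },
        "normality": {k: {"W": w, "p": p} for k, (w, p) in result.normality.items()},
    }

    # --- inventory ---
    inventory = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "run_report.json":
            inventory[str(path.relative_to(out_dir))] = _sha256(path)
    report["file_inventory"] = inventory
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
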