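"""End-to-end orchestration: ingest, background-correct, fit, summarise.

The pipeline mirrors the analysis of a batch fecal-fermentation study:

1. read long-format time-course CSVs (one row per donor/matrix/replicate/
   analyte/time);
2. subtract each donor's blank-fermenter arm from the matrix arms;
3. fit the fractional-conversion model per replicate and average the rate
   constants per (donor, matrix, analyte);
4. compute observed 48-h degradation extents where the analyte starts
   above zero;
5. run a two-way (donor, matrix) ANOVA per analyte on a summary statistic:
   the 48-h concentration for end-products, the per-curve maximum for
   transient intermediates.

All outputs are plain CSV; identical inputs and seed give identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from .kinetics import (
    CONTROL_MATRIX,
    KineticFit,
    NonIdentifiableError,
    RateTable,
    TimeCourse,
    build_rate_table,
    degradation_extent,
    fit_fractional_conversion,
    subtract_background,
)
from .stats import two_way_anova

__all__ = [
    "PipelineConfig",
    "read_timecourses",
    "write_timecourses",
    "write_rate_table",
    "correct_study",
    "fit_study",
    "anova_study",
    "run_pipeline",
]

logger = logging.getLogger("fermkin")

TIMECOURSE_COLUMNS = ["donor", "matrix", "replicate", "analyte", "time_h", "conc_mM"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``end_products`` are summarised at 48 h for the ANOVA, ``intermediates``
    at their per-curve maximum; the two lists must be disjoint.
    """

    input_path: Path | str
    out_dir: Path | str
    control_label: str = CONTROL_MATRIX
    end_products: tuple[str, ...] = net.END_PRODUCTS
    intermediates: tuple[str, ...] = net.INTERMEDIATES
    clip_at_zero: bool = True
    extent_time_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.end_products) & set(self.intermediates)
        if overlap:
            raise ValueError(
                f"analytes listed as both end-product and intermediate: {sorted(overlap)}"
            )


def read_timecourses(path: Path | str) -> list[TimeCourse]:
    """Read a long-format time-course CSV into TimeCourse objects.

    Expected header: ``donor,matrix,replicate,analyte,time_h,conc_mM``.
    Row order inside the file does not matter; times are sorted per arm.
    """
    try:
        df = pd.read_csv(path, dtype={"donor": str, "matrix": str, "analyte": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_h", "conc_mM"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])

    out: list[TimeCourse] = []
    for (donor, matrix, rep, analyte), grp in df.groupby(
        ["donor", "matrix", "replicate", "analyte"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                donor_id=donor,
                matrix_id=matrix,
                replicate=int(rep),
                analyte=analyte,
                times=grp["time_h"].to_numpy(),
                conc=grp["conc_mM"].to_numpy(),
            )
        )
    return out


def timecourses_to_frame(tcs: list[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        for t, c in zip(tc.times, tc.conc):
            rows.append((tc.donor_id, tc.matrix_id, tc.replicate, tc.analyte, t, c))
    return pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)


def write_timecourses(tcs: list[TimeCourse], path: Path | str) -> None:
    """Write time courses as the canonical long-format CSV (sorted rows)."""
    df = timecourses_to_frame(tcs).sort_values(TIMECOURSE_COLUMNS[:5])
    df.to_csv(path, index=False, float_format="%.8g")


def write_rate_table(table: RateTable, path: Path | str) -> None:
    table.to_csv(path)


def correct_study(
    tcs: list[TimeCourse],
    control_label: str = CONTROL_MATRIX,
    clip_at_zero: bool = True,
) -> list[TimeCourse]:
    """Background-correct every matrix arm with its donor's control arm.

    Controls are paired by (donor, replicate, analyte).  A donor whose
    control arm is missing is an error naming the donor.
    """
    controls = {
        (tc.donor_id, tc.replicate, tc.analyte): tc
        for tc in tcs
        if tc.matrix_id == control_label
    }
    corrected = []
    for tc in tcs:
        if tc.matrix_id == control_label:
            continue
        key = (tc.donor_id, tc.replicate, tc.analyte)
        if key not in controls:
            raise ValueError(
                f"no control arm ({control_label!r}) for donor {tc.donor_id}, "
                f"replicate {tc.replicate}, analyte {tc.analyte}"
            )
        ctrl = controls[key]
        if ctrl.matrix_id != CONTROL_MATRIX:
            ctrl = TimeCourse(
                ctrl.donor_id, CONTROL_MATRIX, ctrl.replicate, ctrl.analyte,
                ctrl.times, ctrl.conc,
            )
        out = subtract_background(tc, ctrl, clip_at_zero=clip_at_zero)
        if out.clipped_points:
            logger.info(
                "clipped %d negative point(s) in %s at indices %s",
                len(out.clipped_points), out.key, out.clipped_points,
            )
        corrected.append(out)
    return corrected


def fit_study(
    tcs: list[TimeCourse],
    extent_time_h: float = 48.0,
) -> tuple[pd.DataFrame, RateTable]:
    """Fit every arm per replicate, then average K per (donor, matrix, analyte).

    Returns the per-replicate fit table and the aggregated rate table.
    Flat (non-identifiable) replicates are recorded with K = NaN and
    excluded from the average; an arm is marked converged only if every
    usable replicate fit converged.
    """
    rows = []
    for tc in tcs:
        try:
            fit = fit_fractional_conversion(tc)
            rows.append((*tc.key, fit.K_hat, fit.C0_hat, fit.Cinf_hat,
                         fit.rss, fit.converged))
            if not fit.converged:
                logger.warning("fit did not converge for %s", tc.key)
        except NonIdentifiableError:
            logger.warning("flat series, no fit for %s", tc.key)
            rows.append((*tc.key, np.nan, np.nan, np.nan, np.nan, False))
    fits_df = pd.DataFrame(
        rows,
        columns=["donor", "matrix", "replicate", "analyte",
                 "K_per_h", "C0_mM", "Cinf_mM", "rss", "converged"],
    ).sort_values(["donor", "matrix", "analyte", "replicate"])

    by_arm = {tc.key: tc for tc in tcs}
    agg: dict[tuple[str, str, str], KineticFit] = {}
    extents: dict[tuple[str, str, str], float] = {}
    for (donor, matrix, analyte), grp in fits_df.groupby(
        ["donor", "matrix", "analyte"], sort=True
    ):
        ok = grp.dropna(subset=["K_per_h"])
        if ok.empty:
            continue
        agg[(donor, matrix, analyte)] = KineticFit(
            C0_hat=float(ok["C0_mM"].mean()),
            Cinf_hat=float(ok["Cinf_mM"].mean()),
            K_hat=float(ok["K_per_h"].mean()),
            rss=float(ok["rss"].sum()),
            n_points=int(len(by_arm[(donor, matrix, int(ok["replicate"].iloc[0]), analyte)].times)),
            converged=bool(ok["converged"].all()),
        )
        # Extent is a degradation summary; production arms get NaN.
        if agg[(donor, matrix, analyte)].direction == "degradation":
            exts = []
            for rep in ok["replicate"]:
                tc = by_arm[(donor, matrix, int(rep), analyte)]
                try:
                    exts.append(degradation_extent(tc, t_end=extent_time_h))
                except ValueError:
                    pass
            if exts:
                extents[(donor, matrix, analyte)] = float(np.mean(exts))
    return fits_df, build_rate_table(agg, extents)


def _summary_statistic(tc: TimeCourse, end_products: tuple[str, ...],
                       at_time: float = 48.0) -> float:
    # End-products: concentration at the final time point; transient
    # intermediates: per-curve maximum over the grid.
    if tc.analyte in end_products:
        return tc.value_at(at_time)
    return float(tc.conc.max())


def anova_study(
    tcs: list[TimeCourse],
    end_products: tuple[str, ...] = net.END_PRODUCTS,
    at_time: float = 48.0,
) -> pd.DataFrame:
    """Per-analyte two-way (donor, matrix) ANOVA on per-arm summaries.

    Returns a tidy frame with one row per analyte and factor: df, SS, F, p,
    stars, plus the residual MS and df.
    """
    recs = []
    for tc in tcs:
        recs.append(
            (tc.analyte, tc.donor_id, tc.matrix_id,
             _summary_statistic(tc, end_products, at_time))
        )
    df = pd.DataFrame(recs, columns=["analyte", "donor", "matrix", "value"])
    rows = []
    for analyte, grp in df.groupby("analyte", sort=True):
        res = two_way_anova(grp["value"], grp["donor"], grp["matrix"])
        for factor, eff in (("donor", res.donor), ("matrix", res.matrix)):
            rows.append(
                {
                    "analyte": analyte,
                    "factor": factor,
                    "df": eff.df,
                    "SS": eff.ss,
                    "F": eff.F,
                    "p": eff.p,
                    "stars": eff.stars,
                    "residual_df": res.residual_df,
                    "residual_MS": res.residual_ms,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write all artifacts to ``config.out_dir``.

    Writes ``corrected.csv`` (background-corrected time courses),
    ``fits.csv`` (per-replicate fits), ``rate_table.csv`` (per-arm averaged
    K and 48-h extents) and ``anova.csv``.  Returns the artifact paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tcs = read_timecourses(config.input_path)
    corrected = correct_study(tcs, config.control_label, config.clip_at_zero)
    fits_df, table = fit_study(corrected, config.extent_time_h)
    anova_df = anova_study(corrected, config.end_products, config.extent_time_h)

    paths = {
        "corrected": out_dir / "corrected.csv",
        "fits": out_dir / "fits.csv",
        "rate_table": out_dir / "rate_table.csv",
        "anova": out_dir / "anova.csv",
    }
    write_timecourses(corrected, paths["corrected"])
    fits_df.to_csv(paths["fits"], index=False, float_format="%.8g")
    write_rate_table(table, paths["rate_table"])
    anova_df.to_csv(paths["anova"], index=False, float_format="%.8g")
    logger.info("pipeline wrote %d artifacts to %s", len(paths), out_dir)
    return paths
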