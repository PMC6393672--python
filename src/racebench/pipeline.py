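"""One-command three-step analysis of a trial table.

For every participant x condition cell the pipeline runs:

1. preprocessing — validation, rate-space outlier correction, history
   labelling, per-modality median/MAD summaries;
2. Step 1 — empirical benefit and Raab's probability-summation
   prediction on 50-point quantile grids;
3. Step 2 — history effect and Miller's-bound violation area;
4. Step 3 — LATER fits to the unisensory conditions and the
   maximum-likelihood (rho, eta) context-variant race fit, with the
   model-implied benefit.

Failures are isolated per cell: a cell that cannot be analysed (e.g. no
redundant trials) is reported in ``AnalysisReport.errors`` while all
other cells complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trial_data
from .distributions import downsample_quantiles
from .benefit import empirical_benefit, raab_predicted_quantiles, predicted_benefit
from .interaction import history_effect, miller_bound_quantiles, violation_area
from .race_model import fit_later, fit_race, model_benefit

__all__ = ["AnalysisReport", "run_pipeline", "write_report", "HEADLINE_STATISTICS"]

CONDITION_KEYS = ["construction", "features"]

#: Group-level statistics reported with mean +/- SEM in every summary.
HEADLINE_STATISTICS = (
    "empirical_benefit_s",
    "predicted_benefit_s",
    "model_benefit_s",
    "history_effect_s",
    "violation_area_s",
    "rho",
    "eta",
)


@dataclass
class AnalysisReport:
    """Per-cell results plus isolated per-cell failures.

    ``cells`` holds one row per participant x condition with medians,
    MADs, benefits, history effect, violation area, LATER and race
    parameters; ``outliers`` the per-cell exclusion counts; ``errors``
    the cells that failed, with context.
    """

    cells: pd.DataFrame
    outliers: pd.DataFrame
    performance: dict
    errors: list[dict] = field(default_factory=list)
    n_quantiles: int = 50

    def group_summary(self) -> pd.DataFrame:
        """Grand mean across conditions per participant, then mean +/- SEM.

        Each participant contributes one value per statistic (the mean
        over their conditions); the SEM is taken over participants.
        """
        if self.cells.empty:
            raise ValueError("empty report: no analysed cells")
        per_participant = self.cells.groupby("participant")[list(HEADLINE_STATISTICS)].mean()
        mean = per_participant.mean()
        n = len(per_participant)
        sem = per_participant.std(ddof=1) / np.sqrt(n) if n > 1 else mean * 0.0
        return pd.DataFrame({"mean": mean, "sem": sem})


def _analyse_cell(sub: pd.DataFrame, n_quantiles: int, fit_model: bool) -> dict:
    out: dict = {}
    rts = {
        m: sub.loc[(sub["modality"] == m) & sub["responded"], "rt_s"].to_numpy()
        for m in ("A", "V", "AV")
    }
    for m, x in rts.items():
        if x.size < 3:
            raise ValueError(f"too few {m} trials ({x.size}) after preprocessing")
        med, mad = trial_data.rt_summary(x)
        out[f"median_rt_{m}_s"] = med
        out[f"mad_rt_{m}_s"] = mad
        out[f"n_{m}"] = int(x.size)

    q = {m: downsample_quantiles(x, n_quantiles) for m, x in rts.items()}

    # Step 1: empirical benefit and Raab's parameter-free prediction
    out["empirical_benefit_s"] = empirical_benefit(q["A"], q["V"], q["AV"])
    raab_q = raab_predicted_quantiles(rts["A"], rts["V"], n_quantiles)
    out["predicted_benefit_s"] = predicted_benefit(q["A"], q["V"], raab_q)

    # Step 2: history effect and Miller's-bound violation
    hist = history_effect(sub)
    out["history_effect_s"] = hist.effect
    out["history_effect_A_s"] = hist.effect_a
    out["history_effect_V_s"] = hist.effect_v
    miller_q = miller_bound_quantiles(rts["A"], rts["V"], n_quantiles)
    out["violation_area_s"] = violation_area(miller_q, q["AV"]).violation

    # Step 3: LATER fits and the context-variant race model
    fit_a = fit_later(rts["A"])
    fit_v = fit_later(rts["V"])
    out["mu_A"] = fit_a.mu_
    out["sigma_A"] = fit_a.sigma_
    out["mu_V"] = fit_v.mu_
    out["sigma_V"] = fit_v.sigma_
    if fit_model:
        race = fit_race(rts["AV"], fit_a, fit_v)
        out["rho"] = race.rho_
        out["eta"] = race.eta_
        out["loglik"] = race.loglik_
        out["converged"] = race.converged_
        out["model_benefit_s"] = model_benefit(q["A"], q["V"], race.rt_quantiles(n_quantiles))
    else:
        out["rho"] = out["eta"] = out["loglik"] = out["model_benefit_s"] = np.nan
        out["converged"] = False
    return out


def run_pipeline(
    trials, n_quantiles: int = 50, fit_model: bool = True, schema: dict | None = None
) -> AnalysisReport:
    """Run the full three-step analysis on a trial table or CSV path.

    Deterministic given the input and the optimiser settings.  Errors
    in one participant x condition cell are collected in the report and
    do not abort the remaining cells.
    """
    if isinstance(trials, pd.DataFrame):
        table = trial_data.validate_trials(trials)
    else:
        table = trial_data.read_trials(trials, schema=schema)

    performance = trial_data.performance_summary(table)
    corrected, outlier_report = trial_data.outlier_correct_table(table)
    labelled = trial_data.label_history(corrected)

    rows, errors = [], []
    for (pid, cons, feat), sub in labelled.groupby(
        ["participant", *CONDITION_KEYS], sort=True
    ):
        try:
            cell = _analyse_cell(sub, n_quantiles, fit_model)
        except Exception as exc:  # noqa: BLE001 — per-cell isolation is the contract
            errors.append(
                {"participant": pid, "construction": cons, "features": feat, "error": str(exc)}
            )
            continue
        rows.append({"participant": pid, "construction": cons, "features": feat, **cell})

    return AnalysisReport(
        cells=pd.DataFrame(rows),
        outliers=outlier_report,
        performance=performance,
        errors=errors,
        n_quantiles=n_quantiles,
    )


def write_report(report: AnalysisReport, outdir, plots: bool = False) -> list:
    """Write tidy CSVs and a plain-text summary; return the paths written.

    Files: ``cells.csv`` (per participant x condition), ``outliers.csv``,
    ``performance.csv``, ``group_summary.csv``, ``errors.csv`` (if any)
    and ``summary.txt`` with group means +/- SEM of the headline
    statistics.
    """
    from pathlib import Path

    if report.cells.empty:
        raise ValueError("refusing to write an empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    _write(report.cells, "cells.csv")
    _write(report.outliers, "outliers.csv")
    _write(report.performance["per_participant"], "performance.csv")
    summary = report.group_summary()
    summary.reset_index(names="statistic").to_csv(outdir / "group_summary.csv", index=False)
    written.append(outdir / "group_summary.csv")
    if report.errors:
        _write(pd.DataFrame(report.errors), "errors.csv")

    lines = [
        "Race-model analysis summary",
        f"participants: {report.cells['participant'].nunique()}",
        f"cells analysed: {len(report.cells)} (failed: {len(report.errors)})",
        f"quantile points: {report.n_quantiles}",
        "",
        "group means +/- SEM:",
    ]
    for stat in HEADLINE_STATISTICS:
        lines.append(
            f"  {stat:22s} {summary.loc[stat, 'mean']: .4f} +/- {summary.loc[stat, 'sem']:.4f}"
        )
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)

    if plots:
        written.extend(_plot_cells(report, outdir))
    return written


def _plot_cells(report: AnalysisReport, outdir) -> list:
    """Quantile-CDF plots (empirical vs Raab vs Miller) per condition cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    stats = report.cells
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(stats["predicted_benefit_s"], stats["empirical_benefit_s"], alpha=0.6)
    lim = max(stats["predicted_benefit_s"].max(), stats["empirical_benefit_s"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("predicted benefit (s)")
    ax.set_ylabel("empirical benefit (s)")
    fig.tight_layout()
    path = outdir / "benefits.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths
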