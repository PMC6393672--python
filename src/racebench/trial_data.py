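"""Trial-level RT tables: reading, validation, outlier correction, history labels.

A trial table is a pandas DataFrame in presentation order with one row
per trial and the canonical columns

    participant, block, trial, construction, features, modality,
    responded, rt_s

``modality`` is one of ``A``, ``V``, ``AV``, ``catch``; ``rt_s`` is the
reaction time in seconds and must be present iff the participant
responded.  Any response within 1.5 s of signal onset counts as valid.

Outlier correction operates in rate space (1/RT): within each
participant x condition x modality cell, rates further than
``3 * 1.4826 * MAD`` from the cell median are excluded, which removes
the ~0.27% 3-SD tails if rates are normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "RT_WINDOW_S",
    "MAD_CRITERION_K",
    "OutlierReport",
    "read_trials",
    "validate_trials",
    "outlier_correct",
    "outlier_correct_table",
    "label_history",
    "performance_summary",
    "rt_summary",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant",
    "block",
    "trial",
    "construction",
    "features",
    "modality",
    "responded",
    "rt_s",
)

#: Valid response window (seconds after signal onset).
RT_WINDOW_S = 1.5

#: Rate-space exclusion criterion: 3 x 1.4826 MADs ~ 3 SDs under normality.
MAD_CRITERION_K = 3 * 1.4826

MODALITIES = ("A", "V", "AV", "catch")
UNISENSORY = ("A", "V")
CONSTRUCTIONS = ("simple", "complex")
FEATURES = ("consistent", "alternating")


@dataclass(frozen=True)
class OutlierReport:
    """Bookkeeping for one application of the rate-space MAD rule."""

    n_fast_excluded: int
    n_slow_excluded: int
    n_retained: int
    criterion_k: float = MAD_CRITERION_K

    @property
    def n_total(self) -> int:
        return self.n_fast_excluded + self.n_slow_excluded + self.n_retained

    @property
    def fraction_fast(self) -> float:
        return self.n_fast_excluded / self.n_total if self.n_total else 0.0

    @property
    def fraction_slow(self) -> float:
        return self.n_slow_excluded / self.n_total if self.n_total else 0.0


def read_trials(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trial CSV, validate it, and return it in presentation order.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : dict, optional
        Mapping from the file's column names to the canonical names,
        e.g. ``{"subj": "participant", "RT": "rt_s"}``.
    """
    table = pd.read_csv(path)
    if schema:
        table = table.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    table = validate_trials(table)
    return table


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants and sort into presentation order.

    Raises ``ValueError`` naming the offending rows if an RT falls
    outside ``(0, 1.5]``, an RT is present without a response (or
    missing with one), or a (participant, block, trial) index repeats.
    """
    table = table.copy()
    table["responded"] = table["responded"].astype(bool)
    table["rt_s"] = pd.to_numeric(table["rt_s"], errors="coerce")

    rts = table["rt_s"]
    bad_rt = table["responded"] & ((rts <= 0) | (rts > RT_WINDOW_S) | rts.isna())
    if bad_rt.any():
        rows = table.index[bad_rt].tolist()
        raise ValueError(
            f"rt_s must lie in (0, {RT_WINDOW_S}] for responded trials; "
            f"offending rows: {rows[:20]}"
        )
    orphan = ~table["responded"] & rts.notna()
    if orphan.any():
        rows = table.index[orphan].tolist()
        raise ValueError(f"rt_s present on trials without a response: rows {rows[:20]}")

    bad_mod = ~table["modality"].isin(MODALITIES)
    if bad_mod.any():
        raise ValueError(
            f"unknown modality values: {sorted(table.loc[bad_mod, 'modality'].unique())}"
        )

    dup = table.duplicated(subset=["participant", "block", "trial"])
    if dup.any():
        raise ValueError(
            f"duplicate (participant, block, trial) keys at rows {table.index[dup].tolist()[:20]}"
        )

    table = table.sort_values(["participant", "block", "trial"], kind="stable")
    return table.reset_index(drop=True)


def outlier_correct(rts, k: float = MAD_CRITERION_K) -> tuple[np.ndarray, OutlierReport]:
    """Apply the rate-space MAD exclusion rule to one cell of RTs.

    RTs are transformed to rates ``r = 1/rt``; points with
    ``|r - median(r)| > k * MAD(r)`` are excluded.  Fast outliers are
    rates above the high threshold, slow outliers rates below the low
    one.  If the MAD is zero the criterion is degenerate and all points
    are retained (with a warning).  Retained RTs keep their input order.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("outlier correction needs a non-empty RT vector")
    if np.any(rts <= 0):
        raise ValueError("all RTs must be positive")
    rates = 1.0 / rts
    med = np.median(rates)
    mad = np.median(np.abs(rates - med))
    if mad == 0.0:
        warnings.warn(
            "zero MAD in rate space: exclusion criterion is degenerate, retaining all points",
            stacklevel=2,
        )
        return rts.copy(), OutlierReport(0, 0, rts.size, k)
    fast = rates - med > k * mad
    slow = med - rates > k * mad
    keep = ~(fast | slow)
    report = OutlierReport(int(fast.sum()), int(slow.sum()), int(keep.sum()), k)
    return rts[keep], report


def outlier_correct_table(
    table: pd.DataFrame, k: float = MAD_CRITERION_K
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`outlier_correct` per participant x condition x modality cell.

    Only responded signal trials enter the correction; catch trials and
    misses pass through untouched.  Returns the corrected table (in
    presentation order) and a tidy per-cell report.
    """
    keys = ["participant", "construction", "features", "modality"]
    signal = table["responded"] & table["modality"].isin(("A", "V", "AV"))
    drop_idx: list[np.ndarray] = []
    rows = []
    for cell, sub in table.loc[signal].groupby(keys, sort=False, observed=True):
        rates = 1.0 / sub["rt_s"].to_numpy()
        med = np.median(rates)
        mad = np.median(np.abs(rates - med))
        if mad == 0.0:
            logger.warning("zero rate-space MAD in cell %s: retaining all points", cell)
            fast = slow = np.zeros(len(sub), dtype=bool)
        else:
            fast = rates - med > k * mad
            slow = med - rates > k * mad
        drop_idx.append(sub.index[fast | slow].to_numpy())
        rows.append(
            dict(
                zip(keys, cell),
                n_fast_excluded=int(fast.sum()),
                n_slow_excluded=int(slow.sum()),
                n_retained=int((~(fast | slow)).sum()),
            )
        )
    dropped = np.concatenate(drop_idx) if drop_idx else np.array([], dtype=int)
    corrected = table.drop(index=dropped).reset_index(drop=True)
    return corrected, pd.DataFrame(rows)


def label_history(table: pd.DataFrame) -> pd.DataFrame:
    """Label each unisensory trial as a modality repetition or switch.

    Adds ``previous_modality`` and ``transition`` columns.  A unisensory
    trial (A or V) is a *repetition* if the immediately preceding trial
    in the same block carried the same unisensory signal, a *switch* if
    it carried the other one.  The first trial of a block and trials
    preceded by AV or catch trials are *excluded* — only a preceding
    unisensory signal classifies a trial.  AV and catch trials get no
    label.
    """
    table = table.copy()
    prev = table.groupby(["participant", "block"], sort=False)["modality"].shift(1)
    table["previous_modality"] = prev

    is_uni = table["modality"].isin(UNISENSORY)
    transition = pd.Series(pd.NA, index=table.index, dtype="object")
    classifiable = is_uni & prev.isin(UNISENSORY)
    transition[is_uni] = "excluded"
    transition[classifiable & (prev == table["modality"])] = "repetition"
    transition[classifiable & (prev != table["modality"])] = "switch"
    table["transition"] = transition
    return table


def performance_summary(table: pd.DataFrame) -> dict:
    """False-alarm and miss rates, per participant and group mean +/- SEM.

    False alarms are catch trials with a response; misses are signal
    trials without one.  Percentages are computed per participant, then
    averaged with the standard error over participants.
    """
    rows = []
    for pid, sub in table.groupby("participant", sort=True):
        catch = sub["modality"] == "catch"
        signal = ~catch
        fa = 100.0 * sub.loc[catch, "responded"].mean() if catch.any() else np.nan
        miss = 100.0 * (~sub.loc[signal, "responded"]).mean() if signal.any() else np.nan
        rows.append({"participant": pid, "false_alarm_pct": fa, "miss_pct": miss})
    per_participant = pd.DataFrame(rows)
    if per_participant["false_alarm_pct"].isna().any():
        warnings.warn("some participants have no catch trials; false-alarm rate undefined", stacklevel=2)

    def _mean_sem(x: pd.Series) -> tuple[float, float]:
        x = x.dropna()
        if x.empty:
            return np.nan, np.nan
        sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        return float(x.mean()), float(sem)

    fa_mean, fa_sem = _mean_sem(per_participant["false_alarm_pct"])
    miss_mean, miss_sem = _mean_sem(per_participant["miss_pct"])
    return {
        "per_participant": per_participant,
        "false_alarm_pct_mean": fa_mean,
        "false_alarm_pct_sem": fa_sem,
        "miss_pct_mean": miss_mean,
        "miss_pct_sem": miss_sem,
    }


def rt_summary(rts) -> tuple[float, float]:
    """Median and raw median absolute deviation of RTs, in seconds.

    The MAD here carries no consistency scale factor; it is the robust
    spread statistic reported alongside the median.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("rt_summary needs a non-empty RT vector")
    med = float(np.median(rts))
    mad = float(np.median(np.abs(rts - med)))
    return med, mad
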