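"""Step 2: history effects and violations of Miller's bound.

Two interactions fall outside Raab's model.  History effects: unisensory
responses are slower after a modality switch than after a repetition,

    history effect = mean RT(switch) - mean RT(repetition),

computed per modality and averaged.  Miller's bound: under a race with
context invariance the redundant CDF can never exceed
``min(P_A + P_V, 1)``; the violation area accumulates the quantile-wise
excess of the redundant condition beyond the bound,

    violation = sum_i max(Miller_i - AV_i, 0) / N .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import (
    DEFAULT_N_QUANTILES,
    QuantileSet,
    invert_cdf,
    quantile_grid,
)
from .benefit import combine_unisensory_cdfs

__all__ = [
    "HistoryResult",
    "ViolationResult",
    "history_effect",
    "miller_bound_cdf",
    "miller_bound_quantiles",
    "violation_area",
]


@dataclass(frozen=True)
class HistoryResult:
    """Modality-switch cost in seconds, per modality and averaged."""

    effect_a: float
    effect_v: float
    mean_switch_rt: float
    mean_repetition_rt: float

    @property
    def effect(self) -> float:
        return (self.effect_a + self.effect_v) / 2.0


@dataclass(frozen=True)
class ViolationResult:
    """Area (seconds) by which the redundant CDF exceeds Miller's bound."""

    violation: float
    n: int


def history_effect(table: pd.DataFrame) -> HistoryResult:
    """Switch-minus-repetition RT difference from a labelled trial table.

    Expects the ``transition`` column added by
    :func:`racebench.trial_data.label_history`; uses responded
    unisensory trials only.  Raises if any of the four
    modality x transition cells is empty.
    """
    if "transition" not in table.columns:
        raise ValueError("table has no 'transition' column; run label_history first")
    usable = table["transition"].isin(("repetition", "switch")) & table["responded"]
    sub = table.loc[usable]
    effects = {}
    for m in ("A", "V"):
        for kind in ("repetition", "switch"):
            cell = sub.loc[(sub["modality"] == m) & (sub["transition"] == kind), "rt_s"]
            if cell.empty:
                raise ValueError(f"no trials in history cell modality={m}, transition={kind}")
            effects[(m, kind)] = float(cell.mean())
    sw = sub.loc[sub["transition"] == "switch", "rt_s"]
    rep = sub.loc[sub["transition"] == "repetition", "rt_s"]
    return HistoryResult(
        effect_a=effects[("A", "switch")] - effects[("A", "repetition")],
        effect_v=effects[("V", "switch")] - effects[("V", "repetition")],
        mean_switch_rt=float(sw.mean()),
        mean_repetition_rt=float(rep.mean()),
    )


def miller_bound_cdf(p_a, p_v):
    """Miller's bound ``min(P_A + P_V, 1)`` — pointwise on probabilities."""
    p_a = np.asarray(p_a, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    out = np.minimum(p_a + p_v, 1.0)
    return out if out.ndim else float(out)


def miller_bound_quantiles(
    a_sample, v_sample, n: int = DEFAULT_N_QUANTILES
) -> QuantileSet:
    """Quantiles of Miller's bound computed from the unisensory samples."""
    cdf = combine_unisensory_cdfs(a_sample, v_sample, miller_bound_cdf)
    return invert_cdf(cdf, quantile_grid(n))


def violation_area(miller: QuantileSet, av: QuantileSet) -> ViolationResult:
    """Positive quantile-area excess of the redundant condition over the bound.

    Zero when the redundant quantiles are everywhere at or above the
    bound quantiles (no violation); always nonnegative.
    """
    if not miller.same_grid(av):
        raise ValueError("quantile sets must share the same probability grid")
    n = len(miller)
    v = float(np.sum(np.maximum(miller.values - av.values, 0.0)) / n)
    return ViolationResult(violation=v, n=n)
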