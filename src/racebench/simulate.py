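"""Synthetic redundant-signals experiments with known generative structure.

The generator mirrors the structure the analysis assumes: unisensory
rates are Gaussian (LATER), redundant trials race two correlated units
whose sigmas are inflated by additive noise ``eta``, and an optional
additive switch cost slows unisensory responses when the preceding
signal came from the other modality.  Trials are organised into blocks
of randomly ordered A, V, AV and catch trials; all generated RTs fall
inside the 1.5-s response window (out-of-window and non-positive-rate
draws are resampled).

Default parameter scales match a fast simple-stimulus detection
experiment: mean rates near 3.3/s (~0.3 s median RT), rate SD 0.4/s,
rho = -0.18, eta = 0.16/s, 104 trials per modality, 25% catch trials.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .trial_data import RT_WINDOW_S

__all__ = ["SimConfig", "simulate_unisensory", "simulate_redundant", "simulate_experiment", "simulate_cohort"]

_BLOCK_TRIALS_PER_MODALITY = 26  # block = 26 each of A, V, AV at 25% catch


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one participant x condition cell.

    Rates are in 1/s; ``switch_cost`` is an additive RT penalty in
    seconds applied to unisensory trials preceded by the other
    unisensory modality.
    """

    mu_a: float = 3.3
    sigma_a: float = 0.4
    mu_v: float = 3.2
    sigma_v: float = 0.4
    rho: float = -0.18
    eta: float = 0.16
    switch_cost: float = 0.0
    n_per_modality: int = 104
    p_catch: float = 0.25
    seed: int = 0
    participant: str = "sim01"
    construction: str = "simple"
    features: str = "consistent"

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_v <= 0:
            raise ValueError("sigmas must be positive")
        if not 0 <= self.p_catch < 1:
            raise ValueError("p_catch must lie in [0, 1)")
        if self.switch_cost < 0:
            raise ValueError("switch_cost must be nonnegative")
        if abs(self.rho) > 1 or self.sigma_a + self.eta <= 0:
            raise ValueError("invalid race parameters")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _resample_rates(draw, accept, rng, n: int) -> np.ndarray:
    """Draw until ``n`` accepted values; rejection keeps RTs in-window."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = draw(rng, n - filled)
        ok = accept(cand)
        k = int(ok.sum())
        out[filled : filled + k] = cand[ok]
        filled += k
    return out


def simulate_unisensory(
    config: SimConfig, modality: str, n: int | None = None, rng: np.random.Generator | None = None,
    max_rt: float = RT_WINDOW_S,
) -> np.ndarray:
    """Draw unisensory RTs: ``rt = 1/r`` with Gaussian rate ``r``.

    Rates implying non-positive values or RTs beyond ``max_rt`` are
    resampled, mirroring the response window.
    """
    if modality not in ("A", "V"):
        raise ValueError(f"modality must be 'A' or 'V', got {modality!r}")
    mu, sigma = (config.mu_a, config.sigma_a) if modality == "A" else (config.mu_v, config.sigma_v)
    n = config.n_per_modality if n is None else n
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rates = _resample_rates(
        lambda g, m: g.normal(mu, sigma, size=m),
        lambda r: r >= 1.0 / max_rt,
        rng,
        n,
    )
    return 1.0 / rates


def simulate_redundant(
    config: SimConfig, n: int | None = None, rng: np.random.Generator | None = None,
    max_rt: float = RT_WINDOW_S,
) -> np.ndarray:
    """Draw redundant RTs from the correlated race.

    The rate pair is bivariate normal with means (mu_a, mu_v), SDs
    inflated additively by eta, and correlation rho; the response rate
    is the pairwise maximum.
    """
    n = config.n_per_modality if n is None else n
    rng = np.random.default_rng(config.seed) if rng is None else rng
    s_a = config.sigma_a + config.eta
    s_v = config.sigma_v + config.eta
    cov = np.array(
        [
            [s_a**2, config.rho * s_a * s_v],
            [config.rho * s_a * s_v, s_v**2],
        ]
    )
    mean = np.array([config.mu_a, config.mu_v])

    def draw(g: np.random.Generator, m: int) -> np.ndarray:
        # svd handles the singular covariance at rho = +/-1
        pair = g.multivariate_normal(mean, cov, size=m, method="svd")
        return pair.max(axis=1)

    rates = _resample_rates(draw, lambda r: r >= 1.0 / max_rt, rng, n)
    return 1.0 / rates


def simulate_experiment(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a full trial table for one participant x condition cell.

    Trials are arranged in blocks with equal counts of A, V and AV
    signals plus catch trials at the configured proportion, randomly
    ordered within each block.  Unisensory RTs receive ``+switch_cost``
    when the immediately preceding trial carried the other unisensory
    modality; the race draw itself is history-free.  Catch trials are
    correctly withheld (no false alarms or misses are simulated).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_per_modality
    n_blocks = max(1, round(n / _BLOCK_TRIALS_PER_MODALITY))
    per_block = np.full(n_blocks, n // n_blocks)
    per_block[: n % n_blocks] += 1

    max_base_rt = RT_WINDOW_S - config.switch_cost
    if max_base_rt <= 0:
        raise ValueError("switch_cost leaves no room inside the response window")

    rows = []
    for b, n_sig in enumerate(per_block, start=1):
        n_catch = round(config.p_catch / (1.0 - config.p_catch) * 3 * n_sig)
        mods = np.array(["A"] * n_sig + ["V"] * n_sig + ["AV"] * n_sig + ["catch"] * n_catch)
        rng.shuffle(mods)
        rt_a = iter(simulate_unisensory(config, "A", n_sig, rng, max_rt=max_base_rt))
        rt_v = iter(simulate_unisensory(config, "V", n_sig, rng, max_rt=max_base_rt))
        rt_av = iter(simulate_redundant(config, n_sig, rng))
        prev = None
        for t, mod in enumerate(mods, start=1):
            rt: float | None
            if mod == "catch":
                rt = None
            elif mod == "AV":
                rt = float(next(rt_av))
            else:
                rt = float(next(rt_a if mod == "A" else rt_v))
                if prev in ("A", "V") and prev != mod:
                    rt += config.switch_cost
            rows.append(
                {
                    "participant": config.participant,
                    "block": b,
                    "trial": t,
                    "construction": config.construction,
                    "features": config.features,
                    "modality": mod,
                    "responded": mod != "catch",
                    "rt_s": rt,
                }
            )
            prev = mod
    return pd.DataFrame(rows)


def simulate_cohort(
    configs: list[SimConfig] | None = None,
    n_participants: int = 20,
    base_config: SimConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Concatenate simulated experiments for a cohort of participants.

    Either pass explicit per-cell ``configs`` or a ``base_config`` that
    is replicated across ``n_participants`` with distinct seeds and
    participant ids.
    """
    if configs is None:
        base = base_config if base_config is not None else SimConfig()
        root = base.seed if seed is None else seed
        configs = [
            replace(base, participant=f"sim{p:02d}", seed=root + 1000 * p)
            for p in range(1, n_participants + 1)
        ]
    tables = []
    block_offset: dict[str, int] = {}
    for c in configs:
        table = simulate_experiment(c)
        # blocks must stay unique within a participant across condition cells
        offset = block_offset.get(c.participant, 0)
        table["block"] += offset
        block_offset[c.participant] = int(table["block"].max())
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
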