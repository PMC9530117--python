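"""Synthetic data with the statistical structure the analyses assume.

`generate_bimodal_cohort` emulates a bulk RNA-seq cohort whose marker gene
(HOXA9) is bimodal on the log2(TPM+1) scale: a low peak and a high peak of
truncated-at-zero normals, a configurable fraction of the low cohort
measured as exactly zero, unimodal background genes, and survival times
that depend on the cohort — exponential with the baseline hazard for the
high cohort and baseline x true_hr for the low cohort (hazard ratio < 1
means low expression protects).  Censoring is independent of the event
process: censoring times are uniform on (0, tau], with tau solved so that
the expected censored fraction equals censor_rate.

Defaults mirror the cohort structure the pipeline targets: 31 low / 80
high samples, peaks centred at 0.5 and 4.75 log2(TPM+1), true hazard
ratio 0.29, and 9/40 of the low cohort zero-inflated.  The printed peak
intervals (0.005-1 and 4-5.5) are read as spanning roughly +/-2-2.5 sd of
each peak, giving sds of 0.25 and 0.3.

`generate_random_qn` builds random signed networks (default target
functions, no clamps) for fuzzing the engine; `acyclic=True` yields
feed-forward networks with no feedback loops at all, hence no memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .network import ACTIVATOR, INHIBITOR, QNEdge, QNModel, QNVariable


@dataclass(frozen=True)
class CohortSimConfig:
    n_low: int = 31
    n_high: int = 80
    peak_means: Tuple[float, float] = (0.5, 4.75)
    peak_sds: Tuple[float, float] = (0.25, 0.3)
    true_hr: float = 0.29
    baseline_hazard: float = 1.0 / 365.0  # per day; median ~253 days untreated
    censor_rate: float = 0.2
    zero_fraction: float = 9.0 / 40.0  # of the low cohort measured as exactly 0
    n_background_genes: int = 50
    weibull_shape: float = 1.0  # 1 = exponential (constant hazard)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_low < 1 or self.n_high < 1:
            problems.append("cohort sizes must be >= 1")
        if any(s <= 0 for s in self.peak_sds):
            problems.append("peak sds must be positive")
        if self.true_hr <= 0:
            problems.append("true_hr must be positive")
        if self.baseline_hazard <= 0:
            problems.append("baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            problems.append("censor_rate must be in [0, 1)")
        if not 0 <= self.zero_fraction < 1:
            problems.append("zero_fraction must be in [0, 1)")
        if self.n_background_genes < 0:
            problems.append("n_background_genes must be >= 0")
        if self.weibull_shape <= 0:
            problems.append("weibull_shape must be positive")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


def _uniform_censoring_horizon(hazards, rate: float, shape: float) -> float:
    """Horizon tau for C ~ U(0, tau) giving an expected censored fraction
    of `rate` across the given subject hazards."""
    from scipy.optimize import brentq

    def p_censored(tau):
        if shape == 1.0:
            # closed form for exponential event times
            return float(np.mean((1.0 - np.exp(-hazards * tau)) / (hazards * tau)))
        # numeric quadrature of P(T > c) over c ~ U(0, tau)
        grid = np.linspace(0.0, tau, 513)[1:]
        s = np.exp(-((grid[None, :] * hazards[:, None]) ** shape))
        return float(s.mean())

    return brentq(lambda tau: p_censored(tau) - rate, 1e-9, 1e12)


def _truncated_normal(rng, mean, sd, size):
    """Draw from N(mean, sd) truncated below at 0 by redrawing."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < 0
    return out


def generate_bimodal_cohort(
    config: CohortSimConfig = CohortSimConfig(),
    marker_gene: str = "HOXA9",
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expression matrix, clinical table and true cohort labels.

    Fully determined by ``config.seed``.  Returns (matrix genes x samples,
    clinical indexed by sample with time_days/event, truth labels
    low/high per sample).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_low + config.n_high
    samples = [f"S{i:04d}" for i in range(n)]
    truth = pd.Series(
        ["low"] * config.n_low + ["high"] * config.n_high,
        index=samples, name="true_cohort", dtype=object,
    )

    marker = np.empty(n)
    marker[: config.n_low] = _truncated_normal(
        rng, config.peak_means[0], config.peak_sds[0], config.n_low
    )
    marker[config.n_low :] = _truncated_normal(
        rng, config.peak_means[1], config.peak_sds[1], config.n_high
    )
    n_zero = int(round(config.zero_fraction * config.n_low))
    if n_zero:
        marker[rng.choice(config.n_low, size=n_zero, replace=False)] = 0.0

    genes = [marker_gene] + [f"BG{i:04d}" for i in range(config.n_background_genes)]
    values = np.empty((len(genes), n))
    values[0] = marker
    if config.n_background_genes:
        # unimodal background: gene-specific means, shared within-gene noise
        bg_means = rng.uniform(2.0, 6.0, config.n_background_genes)
        values[1:] = np.clip(
            bg_means[:, None] + rng.normal(0.0, 1.0, (config.n_background_genes, n)),
            0.0, None,
        )
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)

    hazards = np.where(
        truth.to_numpy() == "low",
        config.baseline_hazard * config.true_hr,
        config.baseline_hazard,
    )
    # Weibull with scale such that shape=1 reduces to Exp(hazard)
    u = rng.uniform(size=n)
    event_times = (-np.log(u)) ** (1.0 / config.weibull_shape) / hazards
    if config.censor_rate > 0:
        tau = _uniform_censoring_horizon(hazards, config.censor_rate, config.weibull_shape)
        censor_times = rng.uniform(0.0, tau, size=n)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    else:
        events = np.ones(n, dtype=int)
        times = event_times
    clinical = pd.DataFrame(
        {"time_days": times, "event": events},
        index=pd.Index(samples, name="sample"),
    )
    return matrix, clinical, truth


@dataclass(frozen=True)
class RandomQNConfig:
    n_vars: int = 5
    edge_density: float = 0.4
    range_max: int = 2
    acyclic: bool = False
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_vars < 1:
            problems.append("n_vars must be >= 1")
        if not 0 < self.edge_density <= 1:
            problems.append("edge_density must be in (0, 1]")
        if self.range_max < 0:
            problems.append("range_max must be >= 0")
        if problems:
            raise ValueError("invalid random QN config: " + "; ".join(problems))


def generate_random_qn(config: RandomQNConfig = RandomQNConfig()) -> QNModel:
    """Random signed network with default target functions and no clamps.

    Every ordered pair (self-edges included, unless acyclic) receives an
    edge with probability edge_density and a random sign.  Reproducible
    from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = [f"v{i}" for i in range(config.n_vars)]
    variables = tuple(
        QNVariable(vid, vid, range_min=0, range_max=config.range_max) for vid in ids
    )
    edges = []
    for i in range(config.n_vars):
        for j in range(config.n_vars):
            if config.acyclic and j <= i:
                continue
            if rng.uniform() < config.edge_density:
                sign = ACTIVATOR if rng.uniform() < 0.5 else INHIBITOR
                edges.append(QNEdge(ids[i], ids[j], sign))
    return QNModel(
        name=f"random-qn-{config.seed}", variables=variables, edges=tuple(edges)
    )
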