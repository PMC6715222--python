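"""Calibration to survey prevalence targets, backward validation, and the
counterfactual openness × crossover scenario grid.

Free utility-model parameters are fitted so that the replicate-mean
simulated prevalences of conventional-cigarette and e-cigarette use at
each survey anniversary match the observed yearly prevalences. The loss is
a CI-weighted sum of squares, ``Σ ((sim − obs) / halfCI)²``, so products
measured with tighter confidence intervals weigh more. The search combines
Latin-hypercube seeding of the bounded box with Nelder–Mead refinement;
every candidate is evaluated with common random numbers (the same
replicate seeds), which makes the objective deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .engine import ScenarioResult, ScenarioSpec, run_scenario
from .utility import UtilityParameters

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "load_targets",
    "simulated_year_product",
    "calibration_loss",
    "calibrate",
    "validate_backward",
    "run_grid",
]


@dataclass(frozen=True)
class CalibrationTarget:
    """One year × product observed prevalence with its 95% CI."""

    year: int
    product: str  # "CC" or "EC"
    prev: float
    ciLow: float
    ciHigh: float

    def __post_init__(self) -> None:
        if self.product not in ("CC", "EC"):
            raise ValueError(f"product must be CC or EC, got {self.product!r}")
        if not self.ciLow <= self.prev <= self.ciHigh:
            raise ValueError(
                f"{self.year} {self.product}: CI [{self.ciLow}, {self.ciHigh}] "
                f"does not bracket the point estimate {self.prev}"
            )

    @property
    def halfCI(self) -> float:
        return (self.ciHigh - self.ciLow) / 2.0


def load_targets(path) -> list[CalibrationTarget]:
    """Read a targets CSV (columns year, product, prev, ciLow, ciHigh)."""
    df = pd.read_csv(path, comment="#")
    return [
        CalibrationTarget(
            year=int(r.year),
            product=str(r.product),
            prev=float(r.prev),
            ciLow=float(r.ciLow),
            ciHigh=float(r.ciHigh),
        )
        for r in df.itertuples(index=False)
    ]


def simulated_year_product(result: ScenarioResult) -> pd.DataFrame:
    """Replicate-mean CC-any / EC-any prevalence at each anniversary."""
    return result.year_product_means()


def calibration_loss(
    result: ScenarioResult, targets: Sequence[CalibrationTarget]
) -> float:
    """CI-half-width-normalised sum of squared prevalence errors."""
    sim = result.year_product_means().set_index("year")
    loss = 0.0
    for t in targets:
        if t.year not in sim.index:
            raise ValueError(f"target year {t.year} not simulated")
        col = "ccPrev" if t.product == "CC" else "ecPrev"
        half = t.halfCI
        if half == 0:
            half = 1e-12  # degenerate CI: any mismatch dominates
        loss += float(((sim.loc[t.year, col] - t.prev) / half) ** 2)
    return loss


@dataclass
class CalibrationResult:
    params: UtilityParameters
    loss: float
    nEvaluations: int
    trace: pd.DataFrame  # one row per evaluation: parameters + loss


def calibrate(
    spec: ScenarioSpec,
    freeParamNames: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    targets: Sequence[CalibrationTarget],
    budget: int = 200,
    seed: int = 0,
    searchReplicates: int = 20,
) -> CalibrationResult:
    """Fit the named utility parameters to yearly prevalence targets.

    A Latin-hypercube sample covers the bounded box with 60% of the budget;
    Nelder–Mead refines from the best point with the remainder. Every
    evaluation is the mean of ``searchReplicates`` replicates using the
    same seeds (common random numbers), so the whole search is
    deterministic given ``seed`` and ``budget``.
    """
    if not targets:
        raise ValueError("at least one calibration target is required")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    for name in freeParamNames:
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    names = list(freeParamNames)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    search_spec = replace(spec, nReplicates=searchReplicates)

    evaluations: list[dict] = []

    def objective(x: np.ndarray) -> float:
        if len(evaluations) >= budget:
            # budget exhausted: return a large but finite value
            return float(evaluations[-1]["loss"]) + 1e6
        xc = np.clip(x, lo, hi)
        params = replace(search_spec.params, **{k: float(v) for k, v in zip(names, xc)})
        result = run_scenario(replace(search_spec, params=params))
        loss = calibration_loss(result, targets)
        # penalise leaving the box so Nelder-Mead stays inside
        penalty = float(np.sum((x - xc) ** 2)) * 1e3
        evaluations.append({**dict(zip(names, xc)), "loss": loss + penalty})
        return loss + penalty

    n_lhs = max(1, min(budget, int(round(budget * 0.6))))
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    points = lo + sampler.random(n_lhs) * (hi - lo)
    losses = np.array([objective(p) for p in points])
    best_idx = int(np.argmin(losses))
    best_x, best_loss = points[best_idx].copy(), float(losses[best_idx])

    remaining = budget - len(evaluations)
    if remaining > 0:
        res = minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={"maxfev": remaining, "xatol": 1e-3, "fatol": 1e-3},
        )
        if res.fun < best_loss:
            best_x, best_loss = np.clip(res.x, lo, hi), float(res.fun)

    best_params = replace(spec.params, **{k: float(v) for k, v in zip(names, best_x)})
    return CalibrationResult(
        params=best_params,
        loss=best_loss,
        nEvaluations=len(evaluations),
        trace=pd.DataFrame(evaluations),
    )


def validate_backward(
    result: ScenarioResult, targets: Sequence[CalibrationTarget]
) -> pd.DataFrame:
    """Check each year × product simulated mean against the observed 95% CI.

    Returns a table with columns year, product, sim, obs, ciLow, ciHigh,
    hit; a pure function of its inputs. Years in the targets must all have
    been simulated.
    """
    sim = result.year_product_means().set_index("year")
    rows = []
    for t in targets:
        if t.year not in sim.index:
            raise ValueError(f"target year {t.year} not in simulated years")
        col = "ccPrev" if t.product == "CC" else "ecPrev"
        value = float(sim.loc[t.year, col])
        rows.append(
            {
                "year": t.year,
                "product": t.product,
                "sim": value,
                "obs": t.prev,
                "ciLow": t.ciLow,
                "ciHigh": t.ciHigh,
                "hit": bool(t.ciLow <= value <= t.ciHigh),
            }
        )
    return pd.DataFrame(rows)


def run_grid(
    baseSpec: ScenarioSpec,
    thetaValues: Sequence[float],
    crossoverValues: Sequence[float],
) -> pd.DataFrame:
    """Run the counterfactual scenario grid and tabulate horizon-year results.

    For each (theta, crossover) cell the openness offsets are applied
    jointly (thetaCC = thetaEC = theta) on top of the base parameters.
    Returns one row per cell with mean and SD of the four horizon-year
    state fractions; rows are ordered theta-major.
    """
    import warnings

    if len(thetaValues) == 0 or len(crossoverValues) == 0:
        raise ValueError("value lists must be non-empty")
    for v in list(thetaValues) + list(crossoverValues):
        if not 0.0 <= v <= 0.3:
            warnings.warn(f"grid value {v} outside the study range [0, 0.3]")
    rows = []
    for theta in thetaValues:
        for chi in crossoverValues:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = baseSpec.params.with_scenario(theta, theta, chi)
            result = run_scenario(replace(baseSpec, params=params))
            mean, sd = result.horizonMean, result.perYearSD[-1]
            rows.append(
                {
                    "theta": theta,
                    "crossover": chi,
                    "fracCCOnly_mean": mean[1],
                    "fracECOnly_mean": mean[2],
                    "fracDual_mean": mean[3],
                    "fracNone_mean": mean[0],
                    "fracCCOnly_sd": sd[1],
                    "fracECOnly_sd": sd[2],
                    "fracDual_sd": sd[3],
                    "fracNone_sd": sd[0],
                }
            )
    return pd.DataFrame(rows)
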