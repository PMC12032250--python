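"""Estimators linking experimental readouts to simulator parameters.

Covers the exact-binomial transmission-rate estimator for cross progeny
counts, conversions between measured median lifespans and the constant
(geometric) daily-survival parameters the simulators consume, the
carrier-to-allele frequency transform for screened cage readouts, the
quadratic egg-output trend fit, and parameter-recovery harnesses that check
the estimators on synthetic data with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetics import Sex

__all__ = [
    "CrossCounts",
    "estimate_transmission",
    "daily_survival_from_median",
    "mortality_multiplier_from_medians",
    "carrier_to_allele_freq",
    "allele_to_carrier_freq",
    "fit_egg_trend",
    "recover_parameters",
    "fit_cage_bloodmeal_mortality",
]


@dataclass(frozen=True)
class CrossCounts:
    """Progeny counts from one cross of a hemizygous drive parent to wild
    type: total scored progeny and how many carry the drive marker."""

    n_progeny: int
    n_drive_carriers: int
    parent_sex: Sex = Sex.FEMALE

    def __post_init__(self) -> None:
        if self.n_progeny < 0:
            raise ValueError("n_progeny must be non-negative")
        if not (0 <= self.n_drive_carriers <= self.n_progeny):
            raise ValueError("need 0 <= n_drive_carriers <= n_progeny")


def estimate_transmission(
    counts: CrossCounts, confidence: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """Point estimate and exact (Clopper-Pearson) interval for the drive
    transmission rate from progeny counts.

    Returns ``(k/n, (lower, upper))`` at the requested confidence level.
    """
    if counts.n_progeny == 0:
        raise ValueError("cannot estimate a transmission rate from 0 progeny")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    res = stats.binomtest(counts.n_drive_carriers, counts.n_progeny)
    ci = res.proportion_ci(confidence_level=confidence, method="exact")
    return counts.n_drive_carriers / counts.n_progeny, (ci.low, ci.high)


def daily_survival_from_median(median_days: float) -> float:
    """Daily survival probability of a geometric (constant-hazard) lifetime
    with the given median: ``p`` such that ``p ** median = 0.5``."""
    if median_days < 1:
        raise ValueError("median_days must be >= 1")
    return 0.5 ** (1.0 / median_days)


def mortality_multiplier_from_medians(
    median_ref: float, median_alt: float
) -> float:
    """Hazard-ratio mortality multiplier implied by two median lifespans
    under the constant-hazard model (``-ln p`` scales as ``1/median``)."""
    if median_ref < 1 or median_alt < 1:
        raise ValueError("medians must be >= 1")
    return median_ref / median_alt


def carrier_to_allele_freq(carrier_freq: float) -> float:
    """Allele frequency implied by a carrier (>=1 copy) frequency under
    Hardy-Weinberg proportions: ``q = 1 - sqrt(1 - c)``.

    Approximate in the first generations after seeding with homozygous
    founders, where genotypes are not yet at Hardy-Weinberg.
    """
    if not (0.0 <= carrier_freq <= 1.0):
        raise ValueError("carrier_freq must lie in [0, 1]")
    return 1.0 - math.sqrt(1.0 - carrier_freq)


def allele_to_carrier_freq(allele_freq: float) -> float:
    """Inverse of :func:`carrier_to_allele_freq`: ``c = 1 - (1 - q)^2``."""
    if not (0.0 <= allele_freq <= 1.0):
        raise ValueError("allele_freq must lie in [0, 1]")
    return 1.0 - (1.0 - allele_freq) ** 2


def fit_egg_trend(
    egg_series: pd.DataFrame | Mapping[str, Sequence[float]],
    exclude_generation_zero: bool = True,
) -> Dict[str, np.ndarray]:
    """Least-squares quadratic trend of egg output over generations.

    Parameters
    ----------
    egg_series:
        Table with columns ``generation`` and ``egg_output`` (replicate
        cages may simply be stacked, matching how the combined trendline is
        fitted across replicates).
    exclude_generation_zero:
        Drop the setup generation (founders are all homozygous, so its
        output is not comparable); default True.

    Returns a dict with ``coef`` (intercept, linear, quadratic), ``coef_se``,
    ``fitted``, ``fitted_se`` (pointwise standard error of the fitted line)
    and ``generation``.
    """
    df = pd.DataFrame(egg_series)
    if exclude_generation_zero:
        df = df[df["generation"] > 0]
    if len(df) < 4:
        raise ValueError("need at least 4 points to fit a quadratic trend")
    g = df["generation"].to_numpy(dtype=float)
    y = df["egg_output"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([g, g**2]))
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    return {
        "generation": g,
        "coef": np.asarray(fit.params),
        "coef_se": np.asarray(fit.bse),
        "fitted": np.asarray(pred.predicted_mean),
        "fitted_se": np.asarray(pred.se_mean),
    }


# ---------------------------------------------------------------------------
# parameter-recovery harnesses


def _recover_cross(
    table: pd.DataFrame, truth: Mapping[str, float], confidence: float
) -> Dict[str, float]:
    estimates = []
    covered = 0
    for _, row in table.iterrows():
        cc = CrossCounts(int(row["n_progeny"]), int(row["n_drive_carriers"]))
        est, (lo, hi) = estimate_transmission(cc, confidence)
        estimates.append(est)
        if lo <= truth["transmission"] <= hi:
            covered += 1
    est_arr = np.array(estimates)
    return {
        "estimate_mean": float(est_arr.mean()),
        "bias": float(est_arr.mean() - truth["transmission"]),
        "coverage": covered / len(est_arr),
        "n_replicates": int(len(est_arr)),
    }


def _empirical_median_from_table(table: pd.DataFrame) -> float:
    """Median lifetime from a daily deaths/at-risk table.

    Right-censoring at the end of follow-up is handled by reading the
    median off the survival curve (first day on which cumulative deaths
    reach half the initial cohort) rather than off the observed deaths
    only, which would be biased low.
    """
    df = pd.DataFrame(table).sort_values("day")
    days = df["day"].to_numpy()
    deaths = df["deaths"].to_numpy()
    n0 = int(df["at_risk"].iloc[0])
    if n0 == 0:
        raise ValueError("empty survival table")
    cum = np.cumsum(deaths)
    crossed = np.nonzero(cum >= n0 / 2.0)[0]
    if len(crossed) == 0:
        raise ValueError(
            "median not reached before censoring; extend follow-up"
        )
    return float(days[crossed[0]])


def _recover_survival(
    table: pd.DataFrame, truth: Mapping[str, float]
) -> Dict[str, float]:
    med = _empirical_median_from_table(table)
    p_hat = daily_survival_from_median(max(med, 1.0))
    true_median = math.log(0.5) / math.log(truth["daily_survival"])
    return {
        "median_estimate": med,
        "median_true": float(true_median),
        "median_error_days": float(med - true_median),
        "daily_survival_estimate": float(p_hat),
        "daily_survival_true": float(truth["daily_survival"]),
    }


def recover_parameters(
    data,
    truth: Mapping[str, float],
    model: str,
    confidence: float = 0.95,
) -> Dict[str, float]:
    """Run the estimator matching ``model`` on synthetic data with known
    ground truth and report bias / coverage diagnostics.

    ``model`` is one of ``"cross"`` (transmission-rate estimator over a
    table of replicate crosses), ``"survival"`` (daily-survival recovery
    from a deaths table) or ``"cage"`` (blood-meal mortality recovery from
    cage trajectories; see :func:`fit_cage_bloodmeal_mortality`).
    """
    if model == "cross":
        return _recover_cross(pd.DataFrame(data), truth, confidence)
    if model == "survival":
        return _recover_survival(pd.DataFrame(data), truth)
    if model == "cage":
        b_hat = fit_cage_bloodmeal_mortality(**data)
        return {"b_estimate": float(b_hat), "b_true": float(truth["b"]), "b_error": float(b_hat - truth["b"])}
    raise ValueError(f"unknown recovery model: {model!r}")


def fit_cage_bloodmeal_mortality(
    observed_trajectories: Sequence[Sequence[float]],
    config,
    b_grid: Sequence[float],
    replicates_per_b: int = 3,
    seed: int = 0,
) -> float:
    """Calibrate blood-meal mortality against observed carrier-frequency
    trajectories by grid search.

    For each candidate ``b`` the cage simulator is run ``replicates_per_b``
    times and the mean squared distance between simulated and observed
    drive-carrier trajectories (averaged over both sets of replicates) is
    minimised.  Simple and transparent rather than likelihood-based.
    """
    from dataclasses import replace as _dc_replace

    from .cage import run_experiment
    from .genetics import FitnessParams

    obs = [np.asarray(t, dtype=float) for t in observed_trajectories]
    horizon = min(len(t) for t in obs)
    best_b, best_loss = None, np.inf
    for i, b in enumerate(b_grid):
        fp = config.fitness
        fit_b = FitnessParams(
            daily_mort_mult_hom=fp.daily_mort_mult_hom,
            daily_mort_mult_het=fp.daily_mort_mult_het,
            bloodmeal_mort_hom=float(b),
            fecundity_mult=dict(fp.fecundity_mult),
            mating_weight=dict(fp.mating_weight),
        )
        sims = []
        for r in range(replicates_per_b):
            cfg = _dc_replace(
                config, fitness=fit_b, seed=seed + 1000 * i + r,
                generations=horizon - 1,
            )
            recs = run_experiment(cfg)
            sim = np.array([rec.drive_carrier_freq for rec in recs])
            sims.append(
                np.pad(sim, (0, horizon - len(sim)), constant_values=sim[-1])
            )
        # replicate-mean trajectory: the loss targets the expected dynamics,
        # not one noisy realisation
        sim_mean = np.mean(sims, axis=0)[:horizon]
        loss = float(
            np.mean([np.mean((sim_mean - t[:horizon]) ** 2) for t in obs])
        )
        if loss < best_loss:
            best_b, best_loss = float(b), loss
    assert best_b is not None
    return best_b
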