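"""Synthetic-data generators emulating the experimental readouts.

Each generator draws from the sampling distribution the corresponding
laboratory assay induces — binomial progeny counts for inheritance crosses,
geometric lifetimes for daily survival scoring, hypergeometric draws for
larval screening — and returns both the dataset (a plain DataFrame,
CSV-serialisable) and a sidecar ground-truth record, so estimator inputs
look like real lab tables while tests retain the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .cage import ObservationRecord
from .genetics import Sex

__all__ = [
    "GeneratorSpec",
    "gen_cross_progeny",
    "gen_survival_table",
    "gen_cage_screen",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Descriptor of one synthetic dataset: scenario name, the true
    parameters it was generated from, sample sizes and the seed."""

    scenario: str
    truth: Mapping[str, float]
    sample_sizes: Mapping[str, int]
    seed: int

    def as_dict(self) -> Dict:
        return {
            "scenario": self.scenario,
            "truth": dict(self.truth),
            "sample_sizes": dict(self.sample_sizes),
            "seed": self.seed,
        }


def gen_cross_progeny(
    n_replicates: int,
    n_per_replicate: int,
    true_t: float,
    seed: int,
    parent_sex: Sex = Sex.FEMALE,
) -> Tuple[pd.DataFrame, GeneratorSpec]:
    """Binomial drive-carrier counts for replicate inheritance crosses.

    Each replicate scores ``n_per_replicate`` progeny of a hemizygous x
    wild-type cross; carriers are Binomial(n, ``true_t``).
    """
    if not (0.0 <= true_t <= 1.0):
        raise ValueError("true_t must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    carriers = rng.binomial(n_per_replicate, true_t, size=n_replicates)
    df = pd.DataFrame(
        {
            "replicate": np.arange(1, n_replicates + 1),
            "parent_sex": parent_sex.value,
            "n_progeny": n_per_replicate,
            "n_drive_carriers": carriers.astype(int),
        }
    )
    spec = GeneratorSpec(
        scenario="cross",
        truth={"transmission": true_t},
        sample_sizes={"n_replicates": n_replicates, "n_per_replicate": n_per_replicate},
        seed=seed,
    )
    return df, spec


def gen_survival_table(
    n: int, daily_p: float, horizon: int, seed: int
) -> Tuple[pd.DataFrame, GeneratorSpec]:
    """Daily deaths/at-risk table from geometric lifetimes.

    Each of ``n`` adults survives each day with probability ``daily_p``;
    deaths are scored daily (death on day ``k`` means the individual died
    during its ``k``-th day of adult life) and survivors are right-censored
    at ``horizon`` days.
    """
    if not (0.0 < daily_p <= 1.0):
        raise ValueError("daily_p must lie in (0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    if n == 0 or daily_p == 1.0:
        lifetimes = np.full(n, horizon + 1)
    else:
        # geometric: P(die during day k) = p^(k-1) (1-p)
        lifetimes = rng.geometric(1.0 - daily_p, size=n)
    days = np.arange(1, horizon + 1)
    at_risk = np.array([(lifetimes >= d).sum() for d in days])
    deaths = np.array([(lifetimes == d).sum() for d in days])
    df = pd.DataFrame(
        {"day": days, "at_risk": at_risk.astype(int), "deaths": deaths.astype(int)}
    )
    spec = GeneratorSpec(
        scenario="survival",
        truth={"daily_survival": daily_p},
        sample_sizes={"n": n, "horizon": horizon},
        seed=seed,
    )
    return df, spec


def gen_cage_screen(
    records: Sequence[ObservationRecord],
    screen_gfp_n: int,
    screen_pcr_n: int,
    seed: int,
) -> Tuple[pd.DataFrame, GeneratorSpec]:
    """Re-screen a cage trajectory: hypergeometric marker/PCR draws from the
    true per-generation census, emulating the published screening protocol.

    Larvae are physically removed for screening, hence sampling without
    replacement.  Ground-truth census carrier frequencies are included as
    columns (the real experiment does not have them; tests do).
    """
    rng = np.random.default_rng(seed)
    rows: List[Dict] = []
    for rec in records:
        n_ind = rec.census_size
        if n_ind == 0:
            continue
        true_drive_carriers = rec.census_drive_carriers
        true_eff_carriers = rec.census_effector_carriers
        n_gfp = min(screen_gfp_n, n_ind)
        n_pcr = min(screen_pcr_n, n_ind)
        k_gfp = int(
            rng.hypergeometric(true_drive_carriers, n_ind - true_drive_carriers, n_gfp)
        ) if n_gfp else 0
        k_pcr = int(
            rng.hypergeometric(true_eff_carriers, n_ind - true_eff_carriers, n_pcr)
        ) if n_pcr else 0
        rows.append(
            {
                "generation": rec.generation,
                "screened_gfp": n_gfp,
                "gfp_positive": k_gfp,
                "screened_pcr": n_pcr,
                "pcr_positive": k_pcr,
                "egg_output": rec.egg_output,
                "census_drive_carrier_freq": true_drive_carriers / n_ind,
                "census_effector_carrier_freq": true_eff_carriers / n_ind,
            }
        )
    df = pd.DataFrame(rows)
    spec = GeneratorSpec(
        scenario="cage_screen",
        truth={},
        sample_sizes={"screen_gfp_n": screen_gfp_n, "screen_pcr_n": screen_pcr_n},
        seed=seed,
    )
    return df, spec
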