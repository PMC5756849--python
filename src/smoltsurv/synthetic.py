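"""Synthetic tag cohorts and environmental series with known ground truth.

The generator draws per-year random effects once, builds per-fish covariates
with the exact transforms used at fitting time, and draws binary
adult-return outcomes from the logit-linear survival model.  Everything is
deterministic given the seed, so downstream stages can be tested against the
true parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from smoltsurv.covariates import (
    PDO_MONTHS,
    CovariateError,
    CovariateTable,
    EnvironmentSeries,
    build_design_table,
    pdo_binary_index,
)

__all__ = [
    "TrueParameters",
    "generate_cohort",
    "generate_environment",
    "write_dataset",
]

ENV_COVARIATES: tuple[str, ...] = ("t", "f", "T", "U", "E", "V", "I")


@dataclass
class TrueParameters:
    """Ground-truth parameters of the survival model used for simulation.

    ``beta_0`` is the logit-scale intercept; ``beta_d``/``beta_d2`` the fixed
    slopes on standardized timing columns; ``beta`` maps any of
    ``t f T U E V I`` to its fixed slope (unlisted covariates are 0).
    ``sigma_0/1/2`` are the standard deviations of the year-level random
    intercept and the random slopes on ``d`` and ``d2``.

    The default intercept puts baseline survival near 1%, a typical
    smolt-to-adult return magnitude; it is an arbitrary but documented choice.
    """

    beta_0: float = -4.59512  # logit(0.01)
    beta_d: float = 0.0
    beta_d2: float = 0.0
    beta: Mapping[str, float] = field(default_factory=dict)
    sigma_0: float = 0.0
    sigma_1: float = 0.0
    sigma_2: float = 0.0
    n_years: int = 15
    fish_per_year: int = 1000
    doy_window: tuple[int, int] = (100, 180)

    def __post_init__(self) -> None:
        for name in ("sigma_0", "sigma_1", "sigma_2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.fish_per_year < 1:
            raise ValueError("fish_per_year must be >= 1")
        unknown = set(self.beta) - set(ENV_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in beta: {sorted(unknown)}")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_0, self.sigma_1, self.sigma_2])

    def to_dict(self) -> dict:
        return {
            "beta_0": self.beta_0,
            "beta_d": self.beta_d,
            "beta_d2": self.beta_d2,
            "beta": dict(self.beta),
            "sigma_0": self.sigma_0,
            "sigma_1": self.sigma_1,
            "sigma_2": self.sigma_2,
            "n_years": self.n_years,
            "fish_per_year": self.fish_per_year,
            "doy_window": list(self.doy_window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParameters":
        d = dict(d)
        if "doy_window" in d:
            d["doy_window"] = tuple(d["doy_window"])
        return cls(**d)


def generate_environment(
    n_years: int,
    cool_year_fraction: float = 0.5,
    seed: int = 0,
    start_year: int = 1999,
    doy_range: tuple[int, int] = (80, 190),
) -> EnvironmentSeries:
    """Generate daily river/ocean series plus a monthly climate index.

    River temperature and sea-surface temperature trend upward with
    day-of-year; salt-intrusion length and plume volume are linear in flow
    plus noise (so their flow-residualizations are non-degenerate); a
    ``cool_year_fraction`` share of years gets a negative May-September mean
    climate index, the remainder positive — guaranteed by construction.
    """
    if not 0.0 <= cool_year_fraction <= 1.0:
        raise ValueError(f"cool_year_fraction must lie in [0, 1], got {cool_year_fraction}")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    doys = np.arange(doy_range[0], doy_range[1] + 1)

    n_cool = int(round(n_years * cool_year_fraction))
    cool_mask = np.zeros(n_years, dtype=bool)
    cool_mask[rng.permutation(n_years)[:n_cool]] = True

    daily_rows = []
    pdo_rows = []
    for year, cool in zip(years, cool_mask):
        temp_offset = rng.normal(0.0, 0.8)
        flow_offset = rng.normal(0.0, 25.0)
        sst_offset = rng.normal(0.0, 0.6)

        river_temp = 4.0 + 0.09 * doys + temp_offset + rng.normal(0.0, 0.5, doys.size)
        # spring freshet: flow peaks mid-season then recedes
        flow = (
            150.0
            + 120.0 * np.exp(-(((doys - 140.0) / 35.0) ** 2))
            + flow_offset
            + rng.normal(0.0, 12.0, doys.size)
        )
        sst = 8.0 + 0.05 * doys + sst_offset + rng.normal(0.0, 0.4, doys.size)
        upwelling = -25.0 + 0.55 * (doys - doy_range[0]) + rng.normal(0.0, 8.0, doys.size)
        salt = 30.0 - 0.045 * flow + rng.normal(0.0, 1.2, doys.size)
        plume = 9.0e8 + 5.0e6 * flow + rng.normal(0.0, 4.0e7, doys.size)

        daily_rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "doy": doys,
                    "river_temp_c": river_temp,
                    "flow_kcfs": flow,
                    "sst_c": sst,
                    "upwelling": upwelling,
                    "salt_intrusion_km": salt,
                    "plume_volume_m3": plume,
                }
            )
        )

        center = -1.0 if cool else 1.0
        pdo = rng.normal(center, 0.4, 12)
        summer = [m - 1 for m in PDO_MONTHS]
        mean_summer = pdo[summer].mean()
        # force the May-Sep mean onto the intended side of zero
        if cool and mean_summer >= 0:
            pdo[summer] -= mean_summer + 0.2
        elif not cool and mean_summer <= 0:
            pdo[summer] += -mean_summer + 0.2
        pdo_rows.append(pd.DataFrame({"year": year, "month": np.arange(1, 13), "pdo": pdo}))

    return EnvironmentSeries(
        pd.concat(daily_rows, ignore_index=True), pd.concat(pdo_rows, ignore_index=True)
    )


def _draw_passage_days(rng: np.random.Generator, n: int, window: tuple[int, int]) -> np.ndarray:
    """Unimodal run timing: truncated normal on the window, rounded to integer days."""
    lo, hi = window
    loc, scale = 135.0, 15.0
    a, b = (lo - loc) / scale, (hi - loc) / scale
    days = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    return np.clip(np.rint(days), lo, hi).astype(int)


def linear_predictor(
    true: TrueParameters, table: CovariateTable, random_effects: pd.DataFrame | None = None
) -> np.ndarray:
    """Logit-scale survival for each row of ``table`` under ``true``.

    ``random_effects`` is indexed by year with columns ``b0 b1 b2``; omit it
    for the fixed-effects-only predictor.
    """
    df = table.data
    eta = np.full(len(df), true.beta_0)
    eta += true.beta_d * df["d"].to_numpy() + true.beta_d2 * df["d2"].to_numpy()
    for name, coef in true.beta.items():
        eta += coef * df[name].to_numpy()
    if random_effects is not None:
        b = random_effects.loc[df["year"]].to_numpy()
        eta += b[:, 0] + b[:, 1] * df["d"].to_numpy() + b[:, 2] * df["d2"].to_numpy()
    return eta


def generate_cohort(
    true: TrueParameters,
    env: EnvironmentSeries,
    seed: int = 0,
    rear_type: str = "wild",
    passage_type: str = "run_of_river",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one treatment group's tag records from known parameters.

    Per fish: an integer passage day drawn from a truncated normal over the
    migration window; covariates built with :func:`build_design_table` (the
    same transforms used at fitting time); survival probability from the
    logit-linear model with that year's random effects; outcome drawn
    Bernoulli.  Returns ``(tags, random_effects)`` where ``tags`` has one row
    per fish and ``random_effects`` holds the realized per-year ``b0 b1 b2``.
    """
    env_years = env.years
    if len(env_years) != true.n_years:
        raise CovariateError(
            f"environment covers {len(env_years)} years but true parameters specify {true.n_years}"
        )
    rng = np.random.default_rng(seed)

    b = rng.normal(size=(true.n_years, 3)) * true.sigmas
    random_effects = pd.DataFrame(b, index=pd.Index(env_years, name="year"), columns=["b0", "b1", "b2"])

    n = true.n_years * true.fish_per_year
    years = np.repeat(env_years, true.fish_per_year)
    days = _draw_passage_days(rng, n, true.doy_window)

    tags = pd.DataFrame(
        {
            "fish_id": [f"F{int(y)}-{i:06d}" for i, y in enumerate(years)],
            "year": years,
            "rear_type": rear_type,
            "passage_type": passage_type,
            "doy": days,
        }
    )

    table = build_design_table(tags, env, lo=true.doy_window[0], hi=true.doy_window[1])
    eta = linear_predictor(true, table, random_effects)
    tags["adult_return"] = rng.binomial(1, expit(eta))
    return tags, random_effects


def write_dataset(
    outdir,
    tags: pd.DataFrame,
    env: EnvironmentSeries,
    true: TrueParameters,
    random_effects: pd.DataFrame,
) -> None:
    """Write tags.csv, env.csv, pdo.csv and truth.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tags.to_csv(outdir / "tags.csv", index=False)
    env.to_csv(outdir / "env.csv", outdir / "pdo.csv")
    truth = true.to_dict()
    truth["random_effects"] = {
        str(year): row.tolist() for year, row in zip(random_effects.index, random_effects.to_numpy())
    }
    truth["cool_years"] = [int(y) for y in env.years if pdo_binary_index(env.pdo, int(y)) == 1]
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
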