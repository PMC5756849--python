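"""Covariate engineering: from raw tag and environmental tables to a design table.

Transforms applied, in order: migration-window filter (day-of-year 100-180,
inclusive); attachment of same-day river flow and temperature; right-aligned
7-day rolling means of the marine/estuary series; residualization of
temperature covariates on timing and of estuary/plume covariates on flow;
binary climate index from the May-September mean of a monthly climate series;
and standardization (mean 0, sd 1) of every covariate except the binary index.

Missing environmental days are a hard error — never silently imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariateError",
    "CovariateTable",
    "EnvironmentSeries",
    "build_design_table",
    "pdo_binary_index",
    "residualize",
    "rolling_mean_7d",
    "standardize",
    "window_filter",
]

#: Day-of-year analysis window (inclusive on both ends).
DOY_WINDOW: tuple[int, int] = (100, 180)

#: Months whose mean climate index defines the binary phase label.
PDO_MONTHS: tuple[int, ...] = (5, 6, 7, 8, 9)

DAILY_COLUMNS: tuple[str, ...] = (
    "river_temp_c",
    "flow_kcfs",
    "sst_c",
    "upwelling",
    "salt_intrusion_km",
    "plume_volume_m3",
)

#: Columns standardized in the design table (the binary index I never is).
STANDARDIZED_COLUMNS: tuple[str, ...] = ("d", "d2", "t", "f", "T", "U", "E", "V")


class CovariateError(ValueError):
    """Raised for gaps, degeneracies, or contract violations in covariate inputs."""


@dataclass
class EnvironmentSeries:
    """Daily environmental series plus a monthly climate index.

    Attributes
    ----------
    daily
        One row per (year, doy) with columns :data:`DAILY_COLUMNS`.
    pdo
        One row per (year, month) with column ``pdo``.
    """

    daily: pd.DataFrame
    pdo: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(("year", "doy") + DAILY_COLUMNS) - set(self.daily.columns)
        if missing:
            raise CovariateError(f"daily series missing columns: {sorted(missing)}")
        missing = {"year", "month", "pdo"} - set(self.pdo.columns)
        if missing:
            raise CovariateError(f"pdo series missing columns: {sorted(missing)}")

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.daily["year"].unique())

    def daily_for_year(self, year: int) -> pd.DataFrame:
        sub = self.daily[self.daily["year"] == year]
        if sub.empty:
            raise CovariateError(f"no daily environmental rows for year {year}")
        return sub.sort_values("doy")

    def to_csv(self, env_path, pdo_path) -> None:
        self.daily.to_csv(env_path, index=False)
        self.pdo.to_csv(pdo_path, index=False)

    @classmethod
    def read_csv(cls, env_path, pdo_path) -> "EnvironmentSeries":
        return cls(pd.read_csv(env_path), pd.read_csv(pdo_path))


def window_filter(records: pd.DataFrame, lo: int = DOY_WINDOW[0], hi: int = DOY_WINDOW[1]) -> pd.DataFrame:
    """Keep records whose passage day satisfies ``lo <= doy <= hi`` (both inclusive).

    Row order is preserved.
    """
    if lo > hi:
        raise ValueError(f"window bounds out of order: lo={lo} > hi={hi}")
    doy = records["doy"]
    return records.loc[(doy >= lo) & (doy <= hi)]


def rolling_mean_7d(series: pd.Series, d: int) -> float:
    """Right-aligned 7-day rolling mean: the mean of days ``d-6 .. d``.

    ``series`` is indexed by day-of-year.  Any missing day in the window is
    an error naming the gap.
    """
    wanted = range(d - 6, d + 1)
    missing = [day for day in wanted if day not in series.index]
    if missing:
        raise CovariateError(f"rolling mean at DOY {d}: missing days {missing}")
    return float(series.loc[list(wanted)].mean())


def residualize(response, predictor) -> tuple[np.ndarray, float, float]:
    """Residuals of an ordinary least-squares fit of ``response`` on ``predictor``.

    Returns ``(residuals, slope, intercept)``.  The fit uses the closed-form
    two-parameter solution ``slope = cov(x, y) / var(x)``; residuals have mean
    zero and are orthogonal to the predictor by construction.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise ValueError("response and predictor must have the same length")
    if y.size < 3:
        raise CovariateError(f"residualization needs >= 3 observations, got {y.size}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise CovariateError("constant predictor: regression slope undefined")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    return y - (intercept + slope * x), slope, intercept


def pdo_binary_index(pdo_monthly, year: int) -> int:
    """Binary climate phase for ``year``: 1 (cool) iff the May-Sep mean index < 0.

    ``pdo_monthly`` is either a DataFrame with ``year``/``month``/``pdo``
    columns or a Series indexed by month for a single year.
    """
    if isinstance(pdo_monthly, pd.DataFrame):
        sub = pdo_monthly[pdo_monthly["year"] == year]
        series = sub.set_index("month")["pdo"]
    else:
        series = pdo_monthly
    missing = [m for m in PDO_MONTHS if m not in series.index]
    if missing:
        raise CovariateError(f"pdo index for year {year}: missing months {missing}")
    return int(series.loc[list(PDO_MONTHS)].mean() < 0)


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, sd 1 (population sd).

    Returns ``(z, mean, sd)``.  A constant column is centered only and its
    sd recorded as 0.
    """
    x = np.asarray(values, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        return x - mean, mean, 0.0
    return (x - mean) / sd, mean, sd


@dataclass
class CovariateTable:
    """Per-fish design rows ready for model fitting.

    ``data`` holds, per fish: identifiers (``fish_id``, ``year``, ``doy``),
    the outcome ``y``, standardized covariates ``d d2 t f T U E V``, the
    unstandardized binary index ``I``, and the pre-standardization values as
    ``raw_*`` columns.  ``standardization`` maps each standardized column to
    its (mean, sd); ``residual_fits`` records the slope/intercept of each
    residual regression.
    """

    data: pd.DataFrame
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_fits: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def destandardize(self, column: str, z) -> np.ndarray:
        mean, sd = self.standardization[column]
        return np.asarray(z, dtype=float) * sd + mean

    def standardized_value(self, column: str, raw) -> np.ndarray:
        """Map a raw value onto the stored standardized scale of ``column``."""
        mean, sd = self.standardization[column]
        raw = np.asarray(raw, dtype=float)
        return raw - mean if sd == 0.0 else (raw - mean) / sd

    def to_csv(self, path, sidecar: str | Path | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "standardization": {k: list(v) for k, v in self.standardization.items()},
                    "residual_fits": self.residual_fits,
                },
                indent=2,
            )
        )

    @classmethod
    def read_csv(cls, path, sidecar: str | Path | None = None) -> "CovariateTable":
        path = Path(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            pd.read_csv(path),
            {k: tuple(v) for k, v in meta["standardization"].items()},
            meta["residual_fits"],
        )


def _check_daily_coverage(env: EnvironmentSeries, years, lo: int, hi: int) -> None:
    need = set(range(lo - 6, hi + 1))
    for year in years:
        have = set(env.daily_for_year(int(year))["doy"].astype(int))
        gaps = sorted(need - have)
        if gaps:
            raise CovariateError(
                f"environmental series for year {int(year)} missing DOY {gaps[:10]}"
                + ("..." if len(gaps) > 10 else "")
            )


def _rolling_lookup(env: EnvironmentSeries, years, column: str) -> dict[tuple[int, int], float]:
    """Right-aligned 7-day rolling means per (year, doy)."""
    out: dict[tuple[int, int], float] = {}
    for year in years:
        sub = env.daily_for_year(int(year)).set_index("doy")[column]
        roll = sub.rolling(7).mean()
        # rolling() assumes contiguity; coverage was checked up front
        for doy, val in roll.dropna().items():
            out[(int(year), int(doy))] = float(val)
    return out


def build_design_table(
    records: pd.DataFrame,
    env: EnvironmentSeries,
    lo: int = DOY_WINDOW[0],
    hi: int = DOY_WINDOW[1],
    quad_from_standardized: bool = False,
) -> CovariateTable:
    """Build the fitted design table from tag records and environmental series.

    Steps: window filter; attach flow ``f`` and raw river temperature at the
    passage day; attach 7-day rolling means (right-aligned at the passage
    day) of sea-surface temperature, upwelling, salt intrusion, and plume
    volume; residualize temperature covariates on ``d`` and estuary/plume
    covariates on ``f``; attach the binary climate index ``I`` per year;
    standardize every covariate except ``I``.

    ``quad_from_standardized`` switches the quadratic timing column between
    the square of raw day-of-year (default) and the square of standardized
    ``d``; either way the squared column is standardized on its own.
    """
    required = {"year", "doy"}
    missing = required - set(records.columns)
    if missing:
        raise CovariateError(f"tag records missing columns: {sorted(missing)}")

    df = window_filter(records, lo, hi).reset_index(drop=True).copy()
    if df.empty:
        raise CovariateError(f"no tag records within DOY window [{lo}, {hi}]")

    years = df["year"].unique()
    _check_daily_coverage(env, years, int(df["doy"].min()), int(df["doy"].max()))

    day_env = env.daily.set_index(["year", "doy"])
    idx = pd.MultiIndex.from_arrays([df["year"], df["doy"]])
    df["raw_f"] = day_env["flow_kcfs"].reindex(idx).to_numpy()
    df["raw_river_temp"] = day_env["river_temp_c"].reindex(idx).to_numpy()

    rolled = {
        "sst": "sst_c",
        "upwelling": "upwelling",
        "salt": "salt_intrusion_km",
        "plume": "plume_volume_m3",
    }
    for short, column in rolled.items():
        lookup = _rolling_lookup(env, years, column)
        df[f"raw_{short}_roll"] = [lookup[(int(y), int(d))] for y, d in zip(df["year"], df["doy"])]

    df["raw_d"] = df["doy"].astype(float)
    base_d = df["raw_d"].to_numpy()

    residual_fits: dict[str, dict] = {}

    def _resid(name: str, response, predictor, predictor_name: str) -> np.ndarray:
        res, slope, intercept = residualize(response, predictor)
        residual_fits[name] = {
            "predictor": predictor_name,
            "slope": slope,
            "intercept": intercept,
        }
        return res

    df["raw_t"] = _resid("t", df["raw_river_temp"], base_d, "d")
    df["raw_T"] = _resid("T", df["raw_sst_roll"], base_d, "d")
    df["raw_U"] = df["raw_upwelling_roll"]
    df["raw_E"] = _resid("E", df["raw_salt_roll"], df["raw_f"], "f")
    df["raw_V"] = _resid("V", df["raw_plume_roll"], df["raw_f"], "f")

    phase_by_year = {int(y): pdo_binary_index(env.pdo, int(y)) for y in years}
    df["I"] = df["year"].map(phase_by_year)

    standardization: dict[str, tuple[float, float]] = {}
    df["d"], m, s = standardize(base_d)
    standardization["d"] = (m, s)
    quad_base = df["d"].to_numpy() ** 2 if quad_from_standardized else base_d**2
    df["raw_d2"] = quad_base
    for col in ("d2", "t", "f", "T", "U", "E", "V"):
        df[col], m, s = standardize(df[f"raw_{col}"])
        standardization[col] = (m, s)

    if "adult_return" in df.columns:
        df["y"] = df["adult_return"].astype(int)

    keep = [c for c in ("fish_id", "year", "rear_type", "passage_type", "doy", "y") if c in df.columns]
    keep += ["d", "d2", "t", "f", "T", "U", "E", "V", "I"]
    keep += [c for c in df.columns if c.startswith("raw_")]
    return CovariateTable(df[keep], standardization, residual_fits)
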