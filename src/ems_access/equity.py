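"""Population-weighted Theil index of accessibility, with group decomposition.

For districts j nested in groups i (group 1 = central, group 2 =
suburban), let P_ij be district population, Rbar_ij the district's
indicator (a PRT or an EAI coverage rate), and

    Y_ij = P_ij * Rbar_ij,   Y_i = sum_j Y_ij,   Y = sum_i Y_i.

The total Theil index and its exact decomposition are

    T    = sum_ij (Y_ij / Y) ln( (Y_ij / Y) / (P_ij / P) )
    T_i  = sum_j (Y_ij / Y_i) ln( (Y_ij / Y_i) / (P_ij / P_i) )
    T    = sum_i (Y_i / Y) T_i  +  sum_i (Y_i / Y) ln( (Y_i / Y) / (P_i / P) )
         = T_WG + T_BG

with natural logarithms throughout. T is zero iff every district has the
same per-capita value, is invariant to rescaling the indicator, and is
unchanged by splitting a district into identical halves. Districts with a
zero indicator (possible for a strict coverage rate) contribute the
continuous-extension limit Y ln Y -> 0 and trigger a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TheilResult:
    T: float
    T_wg: float
    T_bg: float
    within_group: dict[int, float]  # group id -> T_i
    group_share: dict[int, float]  # group id -> Y_i / Y
    district_terms: pd.DataFrame  # district, group, term of the total sum

    @property
    def T_wg1(self) -> float:
        return self.within_group.get(1, float("nan"))

    @property
    def T_wg2(self) -> float:
        return self.within_group.get(2, float("nan"))


def _xlogx(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """p * ln(p/q) with the continuous extension 0 at p = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz] / q[nz])
    return out


def _validate(population: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    population = np.asarray(population, dtype=float)
    values = np.asarray(values, dtype=float)
    if population.shape != values.shape:
        raise ValueError("population and indicator arrays must align")
    if np.any(population <= 0):
        raise ValueError("district populations must be positive")
    if np.any(values < 0):
        raise ValueError("indicator values must be nonnegative")
    if np.any(values == 0):
        warnings.warn(
            "zero indicator values present; their Theil terms use the Y ln Y -> 0 limit"
        )
    y = population * values
    if not y.sum() > 0:
        raise ValueError("total weighted indicator is zero; Theil index undefined")
    return population, y


def theil_total(population: np.ndarray, values: np.ndarray) -> float:
    """Total population-weighted Theil index over districts."""
    population, y = _validate(population, values)
    s_y = y / y.sum()
    s_p = population / population.sum()
    return float(_xlogx(s_y, s_p).sum())


def theil_decompose(districts: pd.DataFrame) -> TheilResult:
    """Within/between-group decomposition of the Theil index.

    ``districts`` needs columns (district, group, population, value), every
    district in exactly one group and every group non-empty. The identity
    T = T_WG + T_BG holds to numerical tolerance by construction.
    """
    req = {"district", "group", "population", "value"}
    if not req.issubset(districts.columns):
        raise ValueError(f"district table must have columns {sorted(req)}")
    if districts["district"].duplicated().any():
        raise ValueError("each district may appear only once")
    pop, y = _validate(
        districts["population"].to_numpy(), districts["value"].to_numpy()
    )
    groups = districts["group"].to_numpy()
    Y, P = y.sum(), pop.sum()

    terms = _xlogx(y / Y, pop / P)
    total = float(terms.sum())

    within: dict[int, float] = {}
    share: dict[int, float] = {}
    t_bg = 0.0
    for g in sorted(set(int(g) for g in groups)):
        m = groups == g
        if not m.any():
            raise ValueError(f"group {g} is empty")
        Yi, Pi = y[m].sum(), pop[m].sum()
        share[g] = float(Yi / Y)
        within[g] = (
            float(_xlogx(y[m] / Yi, pop[m] / Pi).sum()) if Yi > 0 else 0.0
        )
        if Yi > 0:
            t_bg += (Yi / Y) * np.log((Yi / Y) / (Pi / P))
    t_wg = float(sum(share[g] * within[g] for g in within))
    return TheilResult(
        T=total,
        T_wg=t_wg,
        T_bg=float(t_bg),
        within_group=within,
        group_share=share,
        district_terms=pd.DataFrame(
            {
                "district": districts["district"].to_numpy(),
                "group": groups,
                "term": terms,
            }
        ),
    )


INDICATOR_THRESHOLDS = {"cov9": 9.0, "cov12": 12.0, "cov15": 15.0}


def equity_report(
    prt_table: pd.DataFrame,
    coverage_table: pd.DataFrame,
    district_groups: pd.DataFrame,
    indicators: tuple[str, ...] = ("prt", "cov9", "cov12", "cov15"),
) -> pd.DataFrame:
    """Theil decompositions of PRT and the 9/12/15-min coverage rates.

    The four indicator sets correspond to per-capita accessibility and the
    optimal / standard / basic service-quality rates. Inputs are the
    per-district PRT table (scope, period, prt_minutes, population), the
    per-district coverage table (scope, period, threshold_minutes,
    coverage_rate) and a (district, group) mapping; returns tidy rows
    (period, indicator, T, T_wg1, T_wg2, T_wg, T_bg).
    """
    group_of = dict(zip(district_groups["district"].astype(str), district_groups["group"]))
    rows = []
    periods = sorted(prt_table["period"].unique())
    for period in periods:
        for ind in indicators:
            if ind == "prt":
                sub = prt_table[prt_table["period"] == period]
                table = pd.DataFrame(
                    {
                        "district": sub["scope"].to_numpy(),
                        "population": sub["population"].to_numpy(),
                        "value": sub["prt_minutes"].to_numpy(),
                    }
                )
            elif ind in INDICATOR_THRESHOLDS:
                t = INDICATOR_THRESHOLDS[ind]
                sub = coverage_table[
                    (coverage_table["period"] == period)
                    & np.isclose(coverage_table["threshold_minutes"], t)
                ]
                pops = prt_table[prt_table["period"] == period].set_index("scope")["population"]
                missing = set(sub["scope"]) - set(pops.index)
                if missing:
                    raise ValueError(f"districts missing population data: {sorted(missing)}")
                table = pd.DataFrame(
                    {
                        "district": sub["scope"].to_numpy(),
                        "population": pops.loc[sub["scope"]].to_numpy(),
                        "value": sub["coverage_rate"].to_numpy(),
                    }
                )
            else:
                raise ValueError(f"unknown indicator {ind!r}")
            missing = set(group_of) - set(table["district"].astype(str))
            if missing:
                raise ValueError(
                    f"period {period!r}, indicator {ind!r}: no value for districts {sorted(missing)}"
                )
            table["group"] = [group_of[str(d)] for d in table["district"]]
            res = theil_decompose(table)
            rows.append(
                {
                    "period": period,
                    "indicator": ind,
                    "T": res.T,
                    "T_wg1": res.T_wg1,
                    "T_wg2": res.T_wg2,
                    "T_wg": res.T_wg,
                    "T_bg": res.T_bg,
                }
            )
    return pd.DataFrame(rows)
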