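"""Direct age–sex standardized extrapolation between populations.

Observed counts or costs stratified by sex × age band are converted to
stratum rates against a source population and re-applied to a target
population. This is how provincially observed quantities (acute
discharges excluding Quebec; Ontario-only ambulatory and home-care data)
scale to national totals, and how privately reimbursed drug claims with
partial capture scale to full coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import StratificationError

STRATA = ["sex", "age_band"]


def population_by_stratum(
    population: pd.DataFrame, provinces=None
) -> pd.DataFrame:
    """Aggregate a province × sex × age-band table to sex × age-band.

    ``provinces`` restricts to a subset (e.g. rest-of-Canada or Ontario);
    None keeps every province.
    """
    pop = population
    if provinces is not None:
        pop = pop[pop["province"].isin(list(provinces))]
    out = pop.groupby(STRATA, as_index=False)["count"].sum()
    return out


def extrapolate(
    source: pd.DataFrame,
    source_pop: pd.DataFrame,
    target_pop: pd.DataFrame,
    value_col: str = "value",
) -> pd.DataFrame:
    """Extrapolate stratified values from one population to another.

    ``source`` has columns ``sex``, ``age_band`` and ``value_col``;
    the population frames have ``sex``, ``age_band``, ``count``. For each
    stratum the rate value/population is applied to the target
    population. Strata with zero source value contribute zero regardless
    of population; a non-zero value over a zero population raises a
    :class:`StratificationError` naming the cell.
    """
    merged = source.merge(
        source_pop.rename(columns={"count": "_src_pop"}), on=STRATA, how="left"
    ).merge(
        target_pop.rename(columns={"count": "_tgt_pop"}), on=STRATA, how="left"
    )
    merged["_src_pop"] = merged["_src_pop"].fillna(0.0)
    merged["_tgt_pop"] = merged["_tgt_pop"].fillna(0.0)
    bad = merged[(merged[value_col] != 0) & (merged["_src_pop"] == 0)]
    if len(bad):
        cell = bad.iloc[0]
        raise StratificationError(
            f"stratum (sex={cell['sex']}, age_band={cell['age_band']}) has "
            f"value {cell[value_col]} but zero source population"
        )
    values = merged[value_col].astype(float).to_numpy()
    src = merged["_src_pop"].astype(float).to_numpy()
    rate = np.where(values != 0.0, values / np.where(src == 0.0, 1.0, src), 0.0)
    out = merged[STRATA].copy()
    out[value_col] = rate * merged["_tgt_pop"].astype(float).to_numpy()
    return out


def extrapolated_total(
    source: pd.DataFrame,
    source_pop: pd.DataFrame,
    target_pop: pd.DataFrame,
    value_col: str = "value",
) -> float:
    """Sum of the extrapolated strata."""
    return float(
        extrapolate(source, source_pop, target_pop, value_col)[value_col].sum()
    )


def stratify(
    cases: pd.DataFrame, value: pd.Series | None = None
) -> pd.DataFrame:
    """Attribution-weighted totals of a case table by sex × age band.

    ``value`` is an optional per-case quantity (e.g. cost or days);
    omitted, each case contributes its attribution weight (a weighted
    count).
    """
    if len(cases) == 0:
        return pd.DataFrame(columns=STRATA + ["value"])
    contrib = cases["attribution_weight"] if value is None else (
        value * cases["attribution_weight"]
    )
    out = (
        contrib.groupby([cases["sex"], cases["age_band"]])
        .sum()
        .rename("value")
        .reset_index()
    )
    out.columns = STRATA + ["value"]
    return out


def scale_private_drug_claims(observed_private: float, coverage: float = 0.65) -> float:
    """Scale observed private drug spend to full coverage (observed/coverage)."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    if observed_private < 0:
        raise ValueError("observed private spend must be >= 0")
    return observed_private / coverage
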