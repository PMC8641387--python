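"""Panel assembly: homogenization, orientation/normalization, merging.

The country x indicator panel of retained trends is sparse and misaligned:
not every country has every indicator. Before regression the panel is pruned
to a complete block in three fixed-order steps:

1. drop countries holding fewer than half the indicators (``N_indicators <
   ceil(fraction * total)``);
2. drop indicators whose retained wildlife-population total, summed over the
   remaining countries that hold them, falls below a threshold;
3. drop remaining countries lacking any retained indicator (complete cases).

The fixed-order pass is repeated until nothing changes: step 2's population
totals are computed over the current country set, so a single pass is not
idempotent in edge cases where the complete-case step shrinks the panel
below an indicator's population threshold.  Iterating to the fixpoint keeps
the documented step order while guaranteeing that re-applying the pruning
to its own output is a no-op.

Retained indicator trends are then oriented (optionally multiplied by -1 so
greater values always mean progress) and z-scored across countries within
each indicator, and merged with wildlife trends into per-taxon modelling
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class HomogenizationError(ValueError):
    """Raised when the three-step pruning empties the panel."""


@dataclass(frozen=True)
class HomogenizationParams:
    min_indicator_fraction: float = 0.5
    min_populations_per_indicator: int = 160
    enforce_complete_cases: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_indicator_fraction <= 1):
            raise ValueError("min_indicator_fraction must be in (0, 1]")
        if self.min_populations_per_indicator < 1:
            raise ValueError("min_populations_per_indicator must be >= 1")


@dataclass
class HomogenizationResult:
    countries: List[str]
    indicators: List[str]
    audit: pd.DataFrame


def homogenize(
    availability: pd.DataFrame,
    population_counts: Mapping[str, int],
    params: HomogenizationParams = HomogenizationParams(),
) -> HomogenizationResult:
    """Prune a boolean country x indicator availability table to a complete
    block using the three fixed-order steps described in the module docstring.

    ``availability`` is indexed by country with one boolean column per
    indicator; ``population_counts`` gives the number of retained wildlife
    populations per country.  Every removal is recorded in the audit frame
    with its step and the metric that triggered it.
    """
    remaining = availability.astype(bool)
    audit_rows: List[dict] = []
    if remaining.shape[1] == 0 or remaining.shape[0] == 0:
        raise HomogenizationError("empty availability table")

    def _pass(block: pd.DataFrame, pass_no: int) -> pd.DataFrame:
        # Step 1: very data-poor countries.
        need = math.ceil(params.min_indicator_fraction * block.shape[1])
        counts = block.sum(axis=1)
        drop1 = counts[counts < need].index
        for c in drop1:
            audit_rows.append(
                {
                    "pass": pass_no,
                    "step": 1,
                    "entity_type": "country",
                    "entity": c,
                    "reason": "too_few_indicators",
                    "metric": int(counts[c]),
                    "threshold": need,
                }
            )
        block = block.drop(index=drop1)
        if block.empty:
            raise HomogenizationError(
                f"homogenization emptied panel at step 1: no country holds >= {need} indicators"
            )

        # Step 2: very data-poor indicators, by associated wildlife populations.
        pops = pd.Series({c: int(population_counts.get(c, 0)) for c in block.index})
        assoc = block.mul(pops, axis=0).sum(axis=0)
        drop2 = assoc[assoc < params.min_populations_per_indicator].index
        for ind in drop2:
            audit_rows.append(
                {
                    "pass": pass_no,
                    "step": 2,
                    "entity_type": "indicator",
                    "entity": ind,
                    "reason": "too_few_populations",
                    "metric": int(assoc[ind]),
                    "threshold": params.min_populations_per_indicator,
                }
            )
        block = block.drop(columns=drop2)
        if block.shape[1] == 0:
            raise HomogenizationError(
                "homogenization emptied panel at step 2: no indicator reaches "
                f"{params.min_populations_per_indicator} associated populations"
            )

        # Step 3: complete cases across the final indicator set.
        if params.enforce_complete_cases:
            complete = block.all(axis=1)
            drop3 = complete[~complete].index
            for c in drop3:
                audit_rows.append(
                    {
                        "pass": pass_no,
                        "step": 3,
                        "entity_type": "country",
                        "entity": c,
                        "reason": "incomplete_indicator_set",
                        "metric": int(block.loc[c].sum()),
                        "threshold": block.shape[1],
                    }
                )
            block = block.loc[complete]
            if block.empty:
                raise HomogenizationError(
                    "homogenization emptied panel at step 3: no country has the complete final indicator set"
                )
        return block

    pass_no = 0
    while True:
        pass_no += 1
        pruned = _pass(remaining, pass_no)
        if pruned.shape == remaining.shape:
            remaining = pruned
            break
        remaining = pruned

    audit = pd.DataFrame(
        audit_rows,
        columns=["pass", "step", "entity_type", "entity", "reason", "metric", "threshold"],
    )
    return HomogenizationResult(
        countries=list(remaining.index), indicators=list(remaining.columns), audit=audit
    )


def availability_table(indicator_trends: pd.DataFrame) -> pd.DataFrame:
    """Pivot retained indicator trends into a boolean country x indicator table."""
    retained = indicator_trends[indicator_trends["retained"]]
    if retained.empty:
        return pd.DataFrame()
    table = (
        retained.assign(present=True)
        .pivot_table(
            index="country",
            columns="indicator_code",
            values="present",
            aggfunc="any",
            fill_value=False,
        )
        .astype(bool)
    )
    table = table.sort_index()
    return table[sorted(table.columns)]


def normalize_and_orient(
    indicator_trends: pd.DataFrame,
    invert_flags: Optional[Mapping[str, bool]] = None,
    *,
    ddof: int = 1,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Orient then z-score retained indicator trends across countries.

    Orientation (multiplication by -1 where flagged) is applied before
    normalization, so flipping a flag exactly negates the z-scores.  The SD
    uses the sample convention (``ddof=1``) by default.  Indicators whose
    cross-country SD is zero are excluded with a logged reason.

    Returns (oriented frame with a ``z`` column, exclusion audit).
    """
    retained = indicator_trends[indicator_trends["retained"]].copy()
    rows = []
    excluded = []
    for code, grp in retained.groupby("indicator_code", sort=True):
        invert = (
            bool(invert_flags.get(code, False))
            if invert_flags is not None
            else bool(grp["invert"].iloc[0]) if "invert" in grp else False
        )
        oriented = grp["mean_trend"].to_numpy(dtype=float) * (-1.0 if invert else 1.0)
        if len(oriented) < 2:
            excluded.append({"indicator_code": code, "reason": "fewer_than_two_countries"})
            continue
        sd = float(np.std(oriented, ddof=ddof))
        if sd == 0 or not np.isfinite(sd):
            excluded.append({"indicator_code": code, "reason": "zero_cross_country_sd"})
            continue
        z = (oriented - oriented.mean()) / sd
        for country, zi, oi in zip(grp["country"], z, oriented):
            rows.append(
                {
                    "country": country,
                    "indicator_code": code,
                    "oriented_trend": float(oi),
                    "z": float(zi),
                    "inverted": invert,
                }
            )
    frame = pd.DataFrame(rows, columns=["country", "indicator_code", "oriented_trend", "z", "inverted"])
    return frame, pd.DataFrame(excluded, columns=["indicator_code", "reason"])


def default_taxon_of_order(order: str) -> str:
    """Map a taxonomic-order label to 'bird' or 'mammal'.

    Recognizes the synthetic generator's 'aves_*' / 'mamm_*' labels and a
    small set of real order names; anything unrecognized raises so callers
    supply an explicit mapping for custom data.
    """
    low = order.lower()
    if low.startswith(("aves", "bird")):
        return "bird"
    if low.startswith(("mamm", "rodent", "carnivora", "primates", "artiodactyla", "chiroptera")):
        return "mammal"
    raise KeyError(f"cannot infer taxon class for order {order!r}; supply taxon_of_order")


def assemble(
    wildlife: pd.DataFrame,
    oriented: pd.DataFrame,
    country_meta: pd.DataFrame,
    *,
    taxon_of_order: Callable[[str], str] = default_taxon_of_order,
    income_classes: Sequence[str] = ("low", "lower_middle"),
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Cross-join retained wildlife trends with their country's oriented
    indicator trends into per-taxon modelling tables.

    ``wildlife`` needs columns population_id, species, order, region,
    country, mean_trend (retained fits only).  ``country_meta`` needs
    country, land_area_km2, hpd_1996, income_class_1995.  Populations in
    countries outside the homogenized set or outside the income filter are
    dropped with an audit entry.  Covariates are log10-transformed.
    """
    meta = country_meta.set_index("country")
    audit_rows = []
    rows = []
    indicator_countries = set(oriented["country"])
    by_country = {c: g for c, g in oriented.groupby("country")}
    for rec in wildlife.itertuples(index=False):
        if rec.country not in meta.index:
            audit_rows.append(
                {"population_id": rec.population_id, "country": rec.country, "reason": "no_country_metadata"}
            )
            continue
        if str(meta.loc[rec.country, "income_class_1995"]) not in income_classes:
            audit_rows.append(
                {"population_id": rec.population_id, "country": rec.country, "reason": "income_class_excluded"}
            )
            continue
        if rec.country not in indicator_countries:
            audit_rows.append(
                {"population_id": rec.population_id, "country": rec.country, "reason": "country_not_homogenized"}
            )
            continue
        taxon = taxon_of_order(rec.order)
        land = math.log10(float(meta.loc[rec.country, "land_area_km2"]))
        hpd = math.log10(float(meta.loc[rec.country, "hpd_1996"]))
        for ind in by_country[rec.country].itertuples(index=False):
            rows.append(
                {
                    "population_id": rec.population_id,
                    "species": rec.species,
                    "order": rec.order,
                    "region": rec.region,
                    "country": rec.country,
                    "taxon_class": taxon,
                    "response": float(rec.mean_trend),
                    "indicator_code": ind.indicator_code,
                    "x": float(ind.z),
                    "inverted": bool(ind.inverted),
                    "log_land_area": land,
                    "log_hpd_1996": hpd,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "population_id",
            "species",
            "order",
            "region",
            "country",
            "taxon_class",
            "response",
            "indicator_code",
            "x",
            "inverted",
            "log_land_area",
            "log_hpd_1996",
        ],
    )
    audit = pd.DataFrame(audit_rows, columns=["population_id", "country", "reason"])
    if frame.empty:
        return {}, audit
    return {taxon: grp.reset_index(drop=True) for taxon, grp in frame.groupby("taxon_class")}, audit


def correlations(oriented: pd.DataFrame, *, min_n: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations between indicators' oriented trends.

    Uses pairwise-complete country overlap; pairs with fewer than ``min_n``
    shared countries are reported with NaN r and p.  Returns a long-format
    symmetric table (both orderings plus the unit diagonal).
    """
    wide = oriented.pivot(index="country", columns="indicator_code", values="oriented_trend")
    codes = sorted(wide.columns)
    rows = []
    for i, a in enumerate(codes):
        for b in codes[i:]:
            sub = wide[[a, b]].dropna()
            n = len(sub)
            if a == b:
                r, p = 1.0, 0.0
            elif n >= min_n:
                r, p = stats.pearsonr(sub[a], sub[b])
                r, p = float(r), float(p)
            else:
                r, p = float("nan"), float("nan")
            rows.append({"indicator_a": a, "indicator_b": b, "r": r, "n": n, "p_value": p})
            if a != b:
                rows.append({"indicator_a": b, "indicator_b": a, "r": r, "n": n, "p_value": p})
    return pd.DataFrame(rows, columns=["indicator_a", "indicator_b", "r", "n", "p_value"])
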