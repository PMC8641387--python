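"""Synthetic abundance panels and SDG indicator panels with known truth.

The generator emulates the two data sources the analysis consumes:

* short, noisy, strictly positive wildlife abundance series with gap years
  and heterogeneous lengths, one per population, labelled with species,
  taxonomic order, region and country;
* country-level indicator series with per-country linear drifts, some in
  monetary/population units (emitted as powers of ten so the pipeline's log
  transform recovers a linear series), some governance-index style series
  that can go negative, and some flagged for inversion.

A planted cross-country association links the two: each population's true
log10-abundance slope is

    s_p = sum_j beta_j * z_cj + u_species + u_order + u_region + e_p,

where z_cj is the oriented, z-scored true drift of indicator j in the
population's country, the u's are random intercepts drawn once per level,
and e_p is idiosyncratic population-level trend variation.  Everything needed to check recovery (betas, intercepts, per-country
indicator trends, per-population slopes) is stored in the truth mapping and
serialized next to the data.

The generator makes no attempt to mimic the real Living Planet Database's
taxonomic composition or real World Bank value distributions.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .series import AbundanceSeries, IndicatorSeries

# code, log_required, invert, negative-capable (governance-index style)
DEFAULT_INDICATOR_TABLE: Tuple[Tuple[str, bool, bool, bool], ...] = (
    ("3.2.", False, True, False),   # under-5 mortality per 1000 (lower is progress)
    ("8.1.", True, False, False),   # GDP per capita, PPP (monetary -> log)
    ("9.3.", False, False, False),  # internet users per 100 people
    ("11.1.", False, True, False),  # population living in slums, % (inverted)
    ("16.3.", False, False, True),  # control of corruption index (can be negative)
    ("HPD", True, True, False),     # human population density (log, inverted)
)

DEFAULT_BETA_TRUE: Dict[str, float] = {"8.1.": 0.5, "HPD": 0.4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic panel.

    Scales mirror the cross-national study: ~30 low/lower-middle-income
    countries, ~10 monitored populations each, a handful of indicators over
    a 1996-2015 window.  ``beta_true`` maps indicator code to the true
    cross-country effect in response-trend units per 1 SD of oriented
    indicator trend; codes absent from the mapping have effect zero.
    """

    n_countries: int = 30
    n_populations_per_country: int = 10
    n_indicators: int = 6
    study_start: int = 1996
    study_end: int = 2015
    series_length_range: Tuple[int, int] = (10, 20)
    missing_prob: float = 0.1
    obs_noise_sd: float = 0.15
    indicator_noise_sd: float = 0.05
    indicator_drift_mean: float = 0.0
    indicator_drift_sd: float = 0.05
    indicator_mask_prob: float = 0.05
    beta_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_TRUE))
    sigma_species: float = 0.15
    sigma_order: float = 0.05
    sigma_region: float = 0.05
    sigma_population: float = 0.3
    populations_per_species: int = 3
    species_scope: str = "country"  # or "global": species pooled across countries
    n_orders: int = 12
    n_regions: int = 5
    bird_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        lo, hi = self.series_length_range
        if lo < 2:
            raise ValueError("series_length_range must not allow series shorter than 2 years")
        if lo > hi:
            raise ValueError("series_length_range must be (lo, hi) with lo <= hi")
        if hi > self.study_end - self.study_start + 1:
            raise ValueError("series_length_range exceeds the study window")
        for name in ("missing_prob", "indicator_mask_prob", "bird_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "obs_noise_sd",
            "indicator_noise_sd",
            "indicator_drift_sd",
            "sigma_species",
            "sigma_order",
            "sigma_region",
            "sigma_population",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.species_scope not in ("country", "global"):
            raise ValueError("species_scope must be 'country' or 'global'")
        if min(self.n_countries, self.n_populations_per_country, self.n_indicators) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticDataset:
    abundance: List[AbundanceSeries]
    indicators: List[IndicatorSeries]
    country_meta: pd.DataFrame
    truth: dict


def _indicator_defs(cfg: SyntheticConfig) -> List[Tuple[str, bool, bool, bool]]:
    defs = list(DEFAULT_INDICATOR_TABLE[: cfg.n_indicators])
    for i in range(len(defs), cfg.n_indicators):
        defs.append((f"X{i + 1}.", False, False, False))
    return defs


def simulate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate one complete synthetic dataset; fully determined by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    years_all = np.arange(cfg.study_start, cfg.study_end + 1)
    countries = [f"C{i + 1:03d}" for i in range(cfg.n_countries)]
    regions = [f"region_{i % cfg.n_regions + 1}" for i in range(cfg.n_countries)]
    defs = _indicator_defs(cfg)
    codes = [d[0] for d in defs]

    # --- country metadata -------------------------------------------------
    land_area = 10.0 ** rng.normal(5.0, 0.7, cfg.n_countries)
    hpd_1996 = 10.0 ** rng.normal(1.6, 0.4, cfg.n_countries)
    income = ["low" if i % 2 == 0 else "lower_middle" for i in range(cfg.n_countries)]
    meta = pd.DataFrame(
        {
            "country": countries,
            "region": regions,
            "land_area_km2": land_area,
            "hpd_1996": hpd_1996,
            "income_class_1995": income,
        }
    )

    # --- true indicator drifts and their oriented z-scores -----------------
    drifts = rng.normal(cfg.indicator_drift_mean, cfg.indicator_drift_sd, (cfg.n_countries, len(defs)))
    z = np.empty_like(drifts)
    for j, (_, _, invert, _) in enumerate(defs):
        oriented = drifts[:, j] * (-1.0 if invert else 1.0)
        sd = oriented.std(ddof=1)
        z[:, j] = (oriented - oriented.mean()) / sd if sd > 0 else 0.0

    # --- taxonomy ----------------------------------------------------------
    n_bird_orders = int(round(cfg.n_orders * cfg.bird_fraction))
    order_names = [f"aves_{i + 1}" for i in range(n_bird_orders)] + [
        f"mamm_{i + 1}" for i in range(cfg.n_orders - n_bird_orders)
    ]
    total_pops = cfg.n_countries * cfg.n_populations_per_country
    pop_country_idx = np.repeat(np.arange(cfg.n_countries), cfg.n_populations_per_country)
    if cfg.species_scope == "country":
        species_of_pop = [
            f"sp_{countries[c]}_{k // cfg.populations_per_species + 1}"
            for c in range(cfg.n_countries)
            for k in range(cfg.n_populations_per_country)
        ]
    else:
        n_species = math.ceil(total_pops / cfg.populations_per_species)
        assignment = rng.permutation(total_pops) % n_species
        species_of_pop = [f"sp_{assignment[i] + 1:04d}" for i in range(total_pops)]

    species_levels = sorted(set(species_of_pop))
    order_of_species = {
        sp: order_names[int(rng.integers(len(order_names)))] for sp in species_levels
    }
    u_species = {sp: float(rng.normal(0.0, cfg.sigma_species)) for sp in species_levels}
    u_order = {o: float(rng.normal(0.0, cfg.sigma_order)) for o in order_names}
    region_levels = sorted(set(regions))
    u_region = {r: float(rng.normal(0.0, cfg.sigma_region)) for r in region_levels}

    beta_vec = np.array([float(cfg.beta_true.get(code, 0.0)) for code in codes])

    # --- abundance series ---------------------------------------------------
    abundance: List[AbundanceSeries] = []
    pop_truth: Dict[str, float] = {}
    pop_meta: Dict[str, dict] = {}
    for p in range(total_pops):
        c = int(pop_country_idx[p])
        sp = species_of_pop[p]
        order = order_of_species[sp]
        region = regions[c]
        slope = float(
            z[c] @ beta_vec
            + u_species[sp]
            + u_order[order]
            + u_region[region]
            + rng.normal(0.0, cfg.sigma_population)
        )
        length = int(rng.integers(cfg.series_length_range[0], cfg.series_length_range[1] + 1))
        start = int(rng.integers(cfg.study_start, cfg.study_end - length + 2))
        yrs = np.arange(start, start + length)
        keep = np.ones(length, dtype=bool)
        if length > 2:
            # gap years only in the interior, so the span is preserved
            keep[1:-1] = rng.random(length - 2) >= cfg.missing_prob
        intercept = rng.normal(1.5, 0.5)
        noise = rng.normal(0.0, cfg.obs_noise_sd, length) if cfg.obs_noise_sd > 0 else np.zeros(length)
        log_abund = intercept + slope * (yrs - cfg.study_start) + noise
        pid = f"pop_{p + 1:05d}"
        abundance.append(
            AbundanceSeries(
                population_id=pid,
                species=sp,
                order=order,
                region=region,
                country=countries[c],
                years=tuple(int(t) for t in yrs[keep]),
                values=tuple(float(v) for v in 10.0 ** log_abund[keep]),
            )
        )
        pop_truth[pid] = slope
        pop_meta[pid] = {
            "species": sp,
            "order": order,
            "region": region,
            "country": countries[c],
            "taxon_class": "bird" if order.startswith("aves") else "mammal",
        }

    # --- indicator series ---------------------------------------------------
    masked = rng.random((cfg.n_countries, len(defs))) < cfg.indicator_mask_prob
    indicators: List[IndicatorSeries] = []
    for c in range(cfg.n_countries):
        for j, (code, log_required, invert, negative_capable) in enumerate(defs):
            if masked[c, j]:
                continue
            if log_required:
                base = rng.normal(3.0, 0.5)  # log10 scale; emitted as 10**series
            elif negative_capable:
                base = rng.normal(-0.5, 1.0)
            else:
                base = rng.normal(50.0, 10.0)
            noise = (
                rng.normal(0.0, cfg.indicator_noise_sd, len(years_all))
                if cfg.indicator_noise_sd > 0
                else np.zeros(len(years_all))
            )
            linear = base + drifts[c, j] * (years_all - cfg.study_start) + noise
            values = 10.0 ** linear if log_required else linear
            indicators.append(
                IndicatorSeries(
                    country=countries[c],
                    indicator_code=code,
                    years=tuple(int(t) for t in years_all),
                    values=tuple(float(v) for v in values),
                    log_required=log_required,
                    invert=invert,
                )
            )

    truth = {
        "beta_true": {code: float(cfg.beta_true.get(code, 0.0)) for code in codes},
        "indicator_flags": {
            code: {"log_required": lg, "invert": inv, "negative_capable": neg}
            for code, lg, inv, neg in defs
        },
        "country_indicator_trends": {
            code: {countries[c]: float(drifts[c, j]) for c in range(cfg.n_countries)}
            for j, code in enumerate(codes)
        },
        "oriented_z": {
            code: {countries[c]: float(z[c, j]) for c in range(cfg.n_countries)}
            for j, code in enumerate(codes)
        },
        "random_intercepts": {
            "species": u_species,
            "order": u_order,
            "region": u_region,
        },
        "population_trends": pop_truth,
        "population_meta": pop_meta,
        "config": dataclasses.asdict(cfg),
    }
    return SyntheticDataset(
        abundance=abundance, indicators=indicators, country_meta=meta, truth=truth
    )


def generate_abundance_panel(cfg: SyntheticConfig) -> Tuple[List[AbundanceSeries], dict]:
    """Abundance series plus the ground truth that generated them."""
    ds = simulate(cfg)
    return ds.abundance, ds.truth


def generate_indicator_panel(cfg: SyntheticConfig) -> List[IndicatorSeries]:
    return simulate(cfg).indicators


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ab_rows = [
        {
            "population_id": s.population_id,
            "binomial": s.species,
            "order": s.order,
            "region": s.region,
            "country": s.country,
            "year": y,
            "value": v,
        }
        for s in ds.abundance
        for y, v in zip(s.years, s.values)
    ]
    pd.DataFrame(ab_rows).to_csv(out / "abundance.csv", index=False)
    ind_rows = [
        {"country": s.country, "indicator_code": s.indicator_code, "year": y, "value": v}
        for s in ds.indicators
        for y, v in zip(s.years, s.values)
    ]
    pd.DataFrame(ind_rows).to_csv(out / "indicators.csv", index=False)
    flags = sorted(
        {(s.indicator_code, s.log_required, s.invert) for s in ds.indicators}
    )
    pd.DataFrame(flags, columns=["indicator_code", "log_required", "invert"]).to_csv(
        out / "indicator_flags.csv", index=False
    )
    ds.country_meta.to_csv(out / "country_meta.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)


def load_dataset(data_dir) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset` (or user-supplied files
    of the same schema).  Series violating the type invariants (too short a
    span, negative abundance) are skipped here and surface later as absent
    populations; truth.json is optional."""
    data = Path(data_dir)
    ab = pd.read_csv(data / "abundance.csv")
    flags_path = data / "indicator_flags.csv"
    if flags_path.exists():
        flags = pd.read_csv(flags_path).set_index("indicator_code")
    else:
        flags = pd.DataFrame(
            [(c, lg, inv) for c, lg, inv, _ in DEFAULT_INDICATOR_TABLE],
            columns=["indicator_code", "log_required", "invert"],
        ).set_index("indicator_code")
    ind = pd.read_csv(data / "indicators.csv")
    meta = pd.read_csv(data / "country_meta.csv")
    truth_path = data / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}

    abundance = []
    for pid, grp in ab.groupby("population_id", sort=True):
        grp = grp.sort_values("year")
        try:
            abundance.append(
                AbundanceSeries(
                    population_id=str(pid),
                    species=str(grp["binomial"].iloc[0]),
                    order=str(grp["order"].iloc[0]),
                    region=str(grp["region"].iloc[0]),
                    country=str(grp["country"].iloc[0]),
                    years=tuple(grp["year"]),
                    values=tuple(grp["value"]),
                )
            )
        except ValueError:
            continue
    indicators = []
    for (country, code), grp in ind.groupby(["country", "indicator_code"], sort=True):
        grp = grp.sort_values("year")
        lg = bool(flags.loc[code, "log_required"]) if code in flags.index else False
        inv = bool(flags.loc[code, "invert"]) if code in flags.index else False
        try:
            indicators.append(
                IndicatorSeries(
                    country=str(country),
                    indicator_code=str(code),
                    years=tuple(grp["year"]),
                    values=tuple(grp["value"]),
                    log_required=lg,
                    invert=inv,
                )
            )
        except ValueError:
            continue
    return SyntheticDataset(
        abundance=abundance, indicators=indicators, country_meta=meta, truth=truth
    )
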