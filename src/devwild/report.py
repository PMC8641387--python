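"""Pipeline orchestration, ground-truth recovery reports and result tables.

``run_pipeline`` executes the full chain in memory (trends -> homogenize ->
normalize/orient -> assemble -> per-indicator Bayesian fits) on a dataset;
``run_all`` wraps it with simulation/loading, stage CSVs and a manifest that
records every filter decision count and output digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import PosteriorSummary, fit_all, posterior_table
from .panel import (
    HomogenizationError,
    HomogenizationParams,
    assemble,
    availability_table,
    correlations,
    default_taxon_of_order,
    homogenize,
    normalize_and_orient,
)
from .series import StudyWindow
from .synthdata import SyntheticConfig, SyntheticDataset, load_dataset, simulate, write_dataset
from .trends import TrendParams, indicator_trends, trend_table, wildlife_trends

logger = logging.getLogger("devwild")


class PipelineError(RuntimeError):
    """A stage produced an empty or unusable result; message names the stage."""


@dataclass
class PipelineConfig:
    """Flat, serializable configuration for a full run.

    Every threshold of the analysis is a named key with the study's value as
    default: the 5-year minimum span, two-observation minimum, the n<6
    linear/GAM switch, R^2 > 0.5 retention, the half-the-indicators and
    minimum-population homogenization cuts, the 1996-2015 window and the
    N(0, 1000) fixed-effect prior.  ``homogenization`` defaults to a
    50-population step-2 cut sized for the default synthetic panel (~150
    populations per taxon, of which roughly half the countries survive the
    complete-case step); the cross-national study's own 160 cut is the
    :class:`HomogenizationParams` default.
    """

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    window: StudyWindow = field(default_factory=StudyWindow)
    trend: TrendParams = field(default_factory=TrendParams)
    homogenization: HomogenizationParams = field(
        default_factory=lambda: HomogenizationParams(min_populations_per_indicator=50)
    )
    model: Dict = field(default_factory=dict)
    income_classes: Tuple[str, ...] = ("low", "lower_middle")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["income_classes"] = list(self.income_classes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "series_length_range" in syn:
                syn["series_length_range"] = tuple(syn["series_length_range"])
            if "beta_true" in syn and syn["beta_true"] is not None:
                syn["beta_true"] = dict(syn["beta_true"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "window" in d:
            d["window"] = StudyWindow(**d["window"])
        if "trend" in d:
            d["trend"] = TrendParams(**d["trend"])
        if "homogenization" in d:
            d["homogenization"] = HomogenizationParams(**d["homogenization"])
        if "income_classes" in d:
            d["income_classes"] = tuple(d["income_classes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


@dataclass
class TaxonResult:
    taxon_class: str
    homogenized_countries: List[str]
    homogenized_indicators: List[str]
    homogenization_audit: pd.DataFrame
    oriented: pd.DataFrame
    assembled: pd.DataFrame
    correlation_table: pd.DataFrame
    posteriors: List[PosteriorSummary]
    fit_failures: pd.DataFrame


@dataclass
class PipelineResult:
    wildlife_table: pd.DataFrame
    wildlife_audit: pd.DataFrame
    indicator_table: pd.DataFrame
    taxa: Dict[str, TaxonResult]
    counts: Dict[str, int]


def run_pipeline(ds: SyntheticDataset, cfg: PipelineConfig) -> PipelineResult:
    """Execute trends -> homogenization -> assembly -> fits on a dataset."""
    eligible = set(
        ds.country_meta.loc[
            ds.country_meta["income_class_1995"].isin(cfg.income_classes), "country"
        ]
    )
    abundance = [s for s in ds.abundance if s.country in eligible]
    indicators = [s for s in ds.indicators if s.country in eligible]
    counts: Dict[str, int] = {
        "abundance_series_in": len(ds.abundance),
        "abundance_series_eligible": len(abundance),
        "indicator_series_in": len(ds.indicators),
        "indicator_series_eligible": len(indicators),
    }

    fits, wl_audit = wildlife_trends(abundance, cfg.window, cfg.trend)
    by_id = {s.population_id: s for s in abundance}
    wl_rows = []
    for f in fits:
        s = by_id.get(f.series_id)
        if s is None or not f.retained:
            continue
        wl_rows.append(
            {
                "population_id": s.population_id,
                "species": s.species,
                "order": s.order,
                "region": s.region,
                "country": s.country,
                "taxon_class": default_taxon_of_order(s.order),
                "mean_trend": f.mean_trend,
            }
        )
    wildlife = pd.DataFrame(
        wl_rows,
        columns=[
            "population_id",
            "species",
            "order",
            "region",
            "country",
            "taxon_class",
            "mean_trend",
        ],
    )
    counts["wildlife_trends_retained"] = len(wildlife)
    if wildlife.empty:
        raise PipelineError(
            "no wildlife trends retained: every series failed the R^2 "
            f"(> {cfg.trend.r2_min}) or {cfg.trend.min_span}-year window filters"
        )

    ind_table, _ = indicator_trends(indicators, cfg.window, cfg.trend)
    counts["indicator_trends_retained"] = int(ind_table["retained"].sum())
    if counts["indicator_trends_retained"] == 0:
        raise PipelineError("no indicator trends retained after quality filters")

    taxa: Dict[str, TaxonResult] = {}
    for taxon, wl_taxon in wildlife.groupby("taxon_class", sort=True):
        avail = availability_table(ind_table)
        pop_counts = wl_taxon.groupby("country").size().to_dict()
        # countries with no retained populations for this taxon cannot
        # contribute rows; restrict the availability table accordingly
        avail = avail.loc[[c for c in avail.index if pop_counts.get(c, 0) > 0]]
        if avail.empty:
            logger.warning("no indicator availability overlaps %s populations", taxon)
            continue
        try:
            hom = homogenize(avail, pop_counts, cfg.homogenization)
        except HomogenizationError as err:
            logger.warning("homogenization emptied the %s panel: %s", taxon, err)
            continue
        kept = ind_table[
            ind_table["country"].isin(hom.countries)
            & ind_table["indicator_code"].isin(hom.indicators)
        ]
        oriented, norm_audit = normalize_and_orient(kept)
        assembled_by_taxon, asm_audit = assemble(
            wl_taxon,
            oriented,
            ds.country_meta,
            income_classes=cfg.income_classes,
        )
        assembled = assembled_by_taxon.get(taxon, pd.DataFrame())
        if assembled.empty:
            logger.warning("assembly produced no %s rows", taxon)
            continue
        corr = correlations(oriented)
        posteriors, failures = fit_all(
            assembled, seed=cfg.seed, model_params=cfg.model
        )
        taxa[taxon] = TaxonResult(
            taxon_class=taxon,
            homogenized_countries=hom.countries,
            homogenized_indicators=hom.indicators,
            homogenization_audit=hom.audit,
            oriented=oriented,
            assembled=assembled,
            correlation_table=corr,
            posteriors=posteriors,
            fit_failures=failures,
        )
        counts[f"{taxon}_countries"] = len(hom.countries)
        counts[f"{taxon}_indicators"] = len(hom.indicators)
        counts[f"{taxon}_populations"] = int(assembled["population_id"].nunique())
        counts[f"{taxon}_rows_assembled"] = len(assembled)
        counts[f"{taxon}_fits"] = len(posteriors)
        counts[f"{taxon}_fits_converged"] = sum(p.converged for p in posteriors)
        counts[f"{taxon}_supported"] = sum(p.support for p in posteriors)
        logger.info(
            "%s: trends for %d populations, in %d countries, with %d indicators",
            taxon,
            counts[f"{taxon}_populations"],
            len(hom.countries),
            len(hom.indicators),
        )
    if not taxa:
        raise PipelineError("assembly produced no modelling rows for any taxon class")

    return PipelineResult(
        wildlife_table=wildlife,
        wildlife_audit=wl_audit,
        indicator_table=ind_table,
        taxa=taxa,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# ground-truth recovery
# ---------------------------------------------------------------------------

def recovery_report(
    posteriors: Sequence[PosteriorSummary], truth: Mapping
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Compare fitted posteriors with the generator's planted effects.

    ``covered``: the 95% credible interval contains the planted beta.
    ``sign_correct``: for nonzero planted effects, the posterior mean has
    the planted sign; for planted zeros, the fit (correctly) shows no
    support.  Indicators fitted but absent from the truth are listed with
    NaN truth and excluded from the aggregates.
    """
    beta_true = truth.get("beta_true", {})
    rows = []
    for p in posteriors:
        bt = beta_true.get(p.indicator_code)
        row = {
            "indicator_code": p.indicator_code,
            "taxon_class": p.taxon_class,
            "beta_true": np.nan if bt is None else float(bt),
            "beta_mean": p.beta_mean,
            "ci_low": p.ci_low,
            "ci_high": p.ci_high,
            "support": p.support,
            "in_truth": bt is not None,
        }
        if bt is not None:
            row["covered"] = bool(p.ci_low <= bt <= p.ci_high)
            row["sign_correct"] = (
                bool(np.sign(p.beta_mean) == np.sign(bt)) if bt != 0 else not p.support
            )
        else:
            row["covered"] = None
            row["sign_correct"] = None
        rows.append(row)
    frame = pd.DataFrame(rows)
    scored = frame[frame["in_truth"]] if not frame.empty else frame
    aggregates = {
        "n_scored": int(len(scored)),
        "coverage_fraction": float(scored["covered"].mean()) if len(scored) else float("nan"),
        "sign_accuracy": float(scored["sign_correct"].mean()) if len(scored) else float("nan"),
    }
    return frame, aggregates


def forest_table(posteriors: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Per-indicator proportional-change effect table, grouped by SDG.

    Effects are oriented so that positive change always signifies desirable
    progress; inverted indicators carry an orientation note mirroring the
    asterisk convention of forest plots.
    """
    if not len(posteriors):
        raise ValueError("forest_table needs at least one fitted posterior")
    rows = []
    for p in posteriors:
        code = p.indicator_code
        sdg = code.split(".")[0] if "." in code else code
        rows.append(
            {
                "sdg": sdg,
                "indicator_code": code,
                "taxon_class": p.taxon_class,
                "prop_change_mean": p.prop_change_mean,
                "prop_change_low": p.prop_change_low,
                "prop_change_high": p.prop_change_high,
                "support": p.support,
                "orientation_note": "inverted (multiplied by -1)" if p.inverted else "",
            }
        )
    frame = pd.DataFrame(rows).sort_values(["sdg", "indicator_code"], kind="stable")
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# full run with artifacts
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, digests: Dict[str, str]) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False)
    tmp.replace(path)
    digests[path.name] = _digest(path)


def run_all(
    cfg: PipelineConfig,
    out_dir,
    *,
    data_dir: Optional[str] = None,
) -> dict:
    """Simulate (or load), run the pipeline, write every stage artifact and
    return the run manifest (also written as manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: Dict[str, str] = {}

    if data_dir is None:
        ds = simulate(cfg.synthetic)
        write_dataset(ds, out)
        for name in ("abundance.csv", "indicators.csv", "indicator_flags.csv", "country_meta.csv", "truth.json"):
            digests[name] = _digest(out / name)
    else:
        ds = load_dataset(data_dir)

    result = run_pipeline(ds, cfg)

    _write_csv(result.wildlife_audit, out / "trends_wildlife.csv", digests)
    ind = result.indicator_table.copy()
    ind.insert(0, "series_id", ind["country"] + ":" + ind["indicator_code"])
    _write_csv(ind, out / "trends_indicators.csv", digests)

    recovery_frames = []
    hom_audits = []
    corr_tables = []
    for taxon, tr in sorted(result.taxa.items()):
        hom_audits.append(tr.homogenization_audit.assign(taxon_class=taxon))
        corr_tables.append(tr.correlation_table.assign(taxon_class=taxon))
        _write_csv(tr.assembled, out / f"assembled_{taxon}s.csv", digests)
        _write_csv(posterior_table(tr.posteriors), out / f"posteriors_{taxon}.csv", digests)
        if tr.posteriors:
            _write_csv(forest_table(tr.posteriors), out / f"forest_{taxon}.csv", digests)
        if ds.truth:
            frame, agg = recovery_report(tr.posteriors, ds.truth)
            recovery_frames.append(frame)
            result.counts[f"{taxon}_recovery_coverage"] = agg["coverage_fraction"]
    _write_csv(pd.concat(hom_audits, ignore_index=True), out / "homogenization_audit.csv", digests)
    _write_csv(pd.concat(corr_tables, ignore_index=True), out / "correlations.csv", digests)
    if recovery_frames:
        _write_csv(pd.concat(recovery_frames, ignore_index=True), out / "recovery.csv", digests)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "counts": result.counts,
        "digests": digests,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=float))
    return manifest
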