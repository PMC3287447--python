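"""End-to-end orchestration: screen, fit, optimize, score, rank.

``fit_bip`` runs the construction pipeline on a working table plus a
country-level response table (one column per dimension), producing a
``BipModel`` that can be serialized to JSON and later applied to any working
table — including countries that took no part in the fitting — by
``score_countries``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composer import (
    DimensionModel,
    bip_score,
    compute_rrs,
    dimension_score,
    generation_hosting_coordinates,
    merge_dat_grf,
    optimize_driver_weights,
    rank_countries,
)
from .config import DIMENSIONS, DRIVERS, BipConfig
from .dataset import WorkingTable
from .modelfit import DriverModel, driver_score, fit_driver
from .screening import ScreeningResult, rank_normalize, spearman_screen

logger = logging.getLogger(__name__)


@dataclass
class BipModel:
    """Everything fitted: screens, driver regressions, optimized weights."""

    config: BipConfig
    screening: dict[str, ScreeningResult]
    driver_models: dict[str, dict[str, DriverModel]]   # dimension -> driver -> model
    dimension_models: dict[str, DimensionModel]
    manifest: dict = field(default_factory=dict)

    @property
    def all_driver_models(self) -> list[DriverModel]:
        return [m for per_dim in self.driver_models.values() for m in per_dim.values()]

    @property
    def variables(self) -> list[str]:
        out: set[str] = set()
        for m in self.all_driver_models:
            out.update(m.variables)
        return sorted(out)

    def coefficients_table(self, normalized: bool = False) -> pd.DataFrame:
        """Dimension x driver grid of optimized weights f_dk (zeros where absent)."""
        rows = {}
        for dim in DIMENSIONS:
            dm = self.dimension_models.get(dim)
            weights = (dm.normalized_weights() if normalized else dm.weights) if dm else {}
            rows[dim] = {drv: float(weights.get(drv, 0.0)) for drv in DRIVERS}
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(DRIVERS))

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": self.config.to_dict(),
            "screening": {
                dim: res.to_frame().to_dict(orient="records")
                for dim, res in self.screening.items()
            },
            "driver_models": {
                dim: {drv: m.to_dict() for drv, m in per_dim.items()}
                for dim, per_dim in self.driver_models.items()
            },
            "dimension_models": {
                dim: dm.to_dict() for dim, dm in self.dimension_models.items()
            },
            "manifest": self.manifest,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "BipModel":
        with open(path) as fh:
            doc = json.load(fh)
        from .screening import VariableScreen

        screening = {}
        for dim, rows in doc["screening"].items():
            res = ScreeningResult(dimension=dim)
            for r in rows:
                res.screens.append(VariableScreen(
                    variable=r["variable"], rho=r["rho"], p_value=r["p"],
                    n_pairs=int(r["n_pairs"]), retained=bool(r["retained"]),
                    reason=r.get("reason", ""),
                ))
            screening[dim] = res
        return cls(
            config=BipConfig.from_dict(doc["config"]),
            screening=screening,
            driver_models={
                dim: {drv: DriverModel.from_dict(md) for drv, md in per_dim.items()}
                for dim, per_dim in doc["driver_models"].items()
            },
            dimension_models={
                dim: DimensionModel.from_dict(dd)
                for dim, dd in doc["dimension_models"].items()
            },
            manifest=doc.get("manifest", {}),
        )


def _normalize_columns(table: WorkingTable, variables: list[str]) -> pd.DataFrame:
    """Rank-normalize each requested column; columns too sparse are dropped."""
    cols = {}
    for var in variables:
        try:
            cols[var] = rank_normalize(table.values[var])
        except ValueError as exc:
            logger.warning("variable %s excluded from normalization: %s", var, exc)
    return pd.DataFrame(cols, index=table.values.index)


def _seed_weights(D: pd.DataFrame, y: pd.Series) -> dict[str, float]:
    """Nonnegative-clamped OLS coefficients of the response on driver scores."""
    cols = list(D.columns)
    rows = D.notna().all(axis=1) & y.notna()
    if int(rows.sum()) < len(cols) + 2:
        return {k: 1.0 for k in cols}
    design = sm.add_constant(D[rows].astype(float), has_constant="add")
    try:
        fit = sm.OLS(y[rows].astype(float), design).fit()
    except Exception:  # singular design etc.
        return {k: 1.0 for k in cols}
    w = {k: max(0.0, float(fit.params.get(k, 0.0))) for k in cols}
    if sum(w.values()) == 0:
        w = {k: 1.0 for k in cols}
    return w


def fit_bip(
    table: WorkingTable,
    responses: pd.DataFrame,
    config: BipConfig | None = None,
    *,
    rng_seed: int = 0,
) -> BipModel:
    """Construct the full index model from a working table and responses.

    Per dimension: Spearman-screen every variable against the response
    ranks, fit one stepwise regression per driver on the screened
    normalized-rank columns (with VIF/PCA collinearity handling), then
    optimize the driver weights by Monte-Carlo hill climb. The manifest
    records stage-by-stage variable counts and the number of initial
    stepwise fits executed.
    """
    config = config or BipConfig()
    config.validate()
    missing_dims = [d for d in DIMENSIONS if d not in responses.columns]
    if missing_dims:
        raise ValueError(f"responses lack dimension columns {missing_dims}")

    child_seeds = np.random.SeedSequence(rng_seed).generate_state(len(DIMENSIONS))
    normalized_all = _normalize_columns(table, table.variables)

    screening: dict[str, ScreeningResult] = {}
    driver_models: dict[str, dict[str, DriverModel]] = {}
    dimension_models: dict[str, DimensionModel] = {}
    manifest: dict = {
        "rng_seed": rng_seed,
        "n_countries": len(table.countries),
        "n_variables": len(table.variables),
        "initial_stepwise_fits": 0,
        "stages": {},
    }

    for i, dim in enumerate(DIMENSIONS):
        y = rank_normalize(responses[dim].reindex(table.countries))
        screen = spearman_screen(
            table, y, alpha=config.alpha, rho_min=config.rho_min,
            min_pairs=config.min_pairs, mode=config.rho_mode, dimension=dim,
        )
        screening[dim] = screen
        retained = [v for v in screen.retained if v in normalized_all.columns]

        per_dim: dict[str, DriverModel] = {}
        for driver in DRIVERS:
            candidates = [v for v in retained if table.drivers.get(v, "") == driver]
            if not candidates:
                logger.info("dimension %s: driver %s has no screened variables", dim, driver)
                continue
            manifest["initial_stepwise_fits"] += 1
            model = fit_driver(driver, dim, normalized_all[candidates], y, config)
            if model is not None:
                per_dim[driver] = model
        driver_models[dim] = per_dim

        if not per_dim:
            logger.warning("dimension %s has no fitted drivers; skipped", dim)
            manifest["stages"][dim] = {
                "screened": len(retained), "drivers_fitted": 0,
            }
            continue

        D = pd.DataFrame(
            {drv: driver_score(m, normalized_all) for drv, m in per_dim.items()},
            index=table.values.index,
        )
        seeds = _seed_weights(D, y)
        dm = optimize_driver_weights(
            D, y, seeds, mc=config.mc, rng_seed=int(child_seeds[i]), dimension=dim,
        )
        dimension_models[dim] = dm
        manifest["stages"][dim] = {
            "screened": len(retained),
            "drivers_fitted": len(per_dim),
            "objective": dm.objective,
            "seed_objective": dm.seed_objective,
        }

    return BipModel(
        config=config,
        screening=screening,
        driver_models=driver_models,
        dimension_models=dimension_models,
        manifest=manifest,
    )


def score_countries(model: BipModel, table: WorkingTable) -> pd.DataFrame:
    """Apply a fitted model to a working table and rank the countries.

    Model variables are rank-normalized over the scored set (the pipeline is
    rank-based end to end, so scoring transfers to countries outside the
    fitting set). Output columns: M_<dim> per dimension, M_DATGRF (merged
    generation score), BIP, RRS, eligible, rank, plus the generation/hosting
    plot coordinates.
    """
    config = model.config
    usable = [v for v in model.variables if v in table.values.columns]
    absent = set(model.variables) - set(usable)
    if absent:
        logger.warning("%d model variables absent from the scoring table", len(absent))
    # absent model variables become all-missing columns: flexible indexing
    # and the RRS gate absorb them rather than crashing the scorer
    normalized = _normalize_columns(table, usable).reindex(columns=model.variables)

    M = {}
    for dim, dm in model.dimension_models.items():
        per_dim = model.driver_models.get(dim, {})
        scoreable = {
            drv: m for drv, m in per_dim.items()
            if any(v in usable for v in m.variables)
        }
        if not scoreable:
            continue
        D = pd.DataFrame(
            {drv: driver_score(m, normalized) for drv, m in scoreable.items()},
            index=table.values.index,
        )
        M[dim] = dimension_score(dm, D)
    if not M:
        raise ValueError("no dimension could be scored")
    Mf = pd.DataFrame(M, index=table.values.index)

    out = pd.DataFrame(index=table.values.index)
    for dim in DIMENSIONS:
        out[f"M_{dim}"] = Mf[dim] if dim in Mf.columns else np.nan
    out["M_DATGRF"] = merge_dat_grf(
        out["M_DAT"], out["M_GRF"],
        weights=(config.e_weights.get("DAT", 0.0), config.e_weights.get("GRF", 0.0)),
    )
    out["BIP"] = bip_score(Mf, config.e_weights)
    out["RRS"] = compute_rrs(table.values, model.all_driver_models)
    ranked = rank_countries(out, rrs_min=config.rrs_min)
    coords = generation_hosting_coordinates(ranked, config.e_weights)
    ranked["generation"] = coords["generation"]
    ranked["hosting"] = coords["hosting"]
    return ranked


def ranking_table(scores: pd.DataFrame, names: dict[str, str] | None = None) -> pd.DataFrame:
    """Ranking report: Rank, Country, ISO, BIP Index, RRS (%)."""
    names = names or {}
    rows = []
    for iso, row in scores.iterrows():
        rows.append({
            "Rank": "" if pd.isna(row["rank"]) else int(row["rank"]),
            "Country": names.get(iso, iso),
            "ISO": iso,
            "BIP Index": "" if pd.isna(row["BIP"]) else round(float(row["BIP"]), 4),
            "RRS (%)": "" if pd.isna(row["RRS"]) else round(float(row["RRS"]), 1),
        })
    return pd.DataFrame(rows)
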