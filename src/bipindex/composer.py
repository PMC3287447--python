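"""Driver-weight optimization and the final composite country score.

Within each response dimension the fitted driver scores D_dk are combined
with nonnegative weights f_dk, chosen by a Monte-Carlo random walk that
maximizes the Spearman correlation between the weighted (flexibly averaged)
combination and the dimension's response ranks. The four dimension scores
M_d are rank-normalized to [0, 1] and combined into the final score

    BIP = sqrt( sum_d (e_d * M_d)^2 )

the Euclidean length of the country's position in the dimension space after
each axis is stretched by its expert-judgment importance weight e_d
(defaults DAT 0.1, GRF 0.2, HOST 0.4, SPCS 0.3). Countries lacking data for
more than 25% of the model's variables (relative reliability score,
RRS < 75) are reported but not ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import BipConfig
from .modelfit import DriverModel
from .screening import rank_normalize

logger = logging.getLogger(__name__)


@dataclass
class DimensionModel:
    """Optimized driver weights f_dk for one dimension."""

    dimension: str
    weights: dict[str, float]           # driver -> f_dk >= 0
    objective: float                    # achieved Spearman with the response
    seed_objective: float
    n_iterations: int
    n_improvements: int
    rng_seed: int
    trace: list[float] = field(default_factory=list)  # objective after each acceptance

    def normalized_weights(self) -> dict[str, float]:
        """Weights rescaled to sum to 1 (for cross-dimension comparison)."""
        total = sum(self.weights.values())
        if total == 0:
            return dict(self.weights)
        return {k: v / total for k, v in self.weights.items()}

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "weights": self.weights,
            "objective": self.objective,
            "seed_objective": self.seed_objective,
            "n_iterations": self.n_iterations,
            "n_improvements": self.n_improvements,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DimensionModel":
        return cls(**d)


def flexible_combination(driver_scores: pd.DataFrame, weights: dict[str, float]) -> pd.Series:
    """sum_k f_k * D_k over available drivers / count of available f_k > 0 drivers.

    Countries with no available positively-weighted driver come out missing.
    """
    drivers = [k for k in driver_scores.columns if weights.get(k, 0.0) > 0]
    if not drivers:
        return pd.Series(np.nan, index=driver_scores.index)
    sub = driver_scores[drivers]
    w = np.array([weights[k] for k in drivers])
    avail = sub.notna().to_numpy()
    vals = np.nan_to_num(sub.to_numpy(dtype=float), nan=0.0)
    num = vals @ w
    cnt = avail.sum(axis=1)
    out = np.divide(num, cnt, out=np.full(len(num), np.nan), where=cnt > 0)
    return pd.Series(out, index=driver_scores.index)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return np.nan
    return float((ra @ rb) / denom)


def optimize_driver_weights(
    driver_scores: pd.DataFrame,
    response: pd.Series,
    seed_weights: dict[str, float] | None = None,
    *,
    mc=None,
    rng_seed: int = 0,
    dimension: str = "",
) -> DimensionModel:
    """Hill-climbing random walk over nonnegative driver weights.

    The objective is the Spearman correlation between the flexible weighted
    combination of driver scores and the response, over countries where both
    exist. One weight is perturbed per iteration (Gaussian step, standard
    deviation ``step_scale * (weight + step_floor)``, clamped at zero); a
    proposal is kept only if the objective strictly improves, so the
    objective trace is non-decreasing. Stops after ``patience`` consecutive
    rejections or ``max_iterations`` proposals. Reproducible from
    ``rng_seed``.
    """
    mc = mc or BipConfig().mc
    cols = [c for c in driver_scores.columns if driver_scores[c].notna().any()]
    if not cols:
        raise ValueError("all driver scores are missing")
    D = driver_scores[cols]
    y = response.reindex(D.index)

    def objective(wdict: dict[str, float]) -> float:
        comb = flexible_combination(D, wdict)
        ok = comb.notna() & y.notna()
        if int(ok.sum()) < 3:
            return np.nan
        yy = y[ok].to_numpy(dtype=float)
        if np.all(yy == yy[0]):
            return np.nan
        return _spearman(comb[ok].to_numpy(dtype=float), yy)

    if seed_weights is None:
        weights = {k: 1.0 for k in cols}
    else:
        weights = {k: max(0.0, float(seed_weights.get(k, 0.0))) for k in cols}
        if sum(weights.values()) == 0:
            weights = {k: 1.0 for k in cols}

    best = objective(weights)
    if np.isnan(best):
        raise ValueError("objective undefined at the seed weights "
                         "(degenerate response or too few complete countries)")
    seed_obj = best
    trace = [best]

    if len(cols) == 1:
        return DimensionModel(dimension, {cols[0]: 1.0}, best, seed_obj, 0, 0,
                              rng_seed, trace)

    rng = np.random.default_rng(rng_seed)
    no_improve = 0
    n_improve = 0
    it = 0
    keys = sorted(cols)
    while it < mc.max_iterations and no_improve < mc.patience:
        it += 1
        k = keys[rng.integers(len(keys))]
        prop = dict(weights)
        step = rng.normal(0.0, mc.step_scale * (weights[k] + mc.step_floor))
        prop[k] = max(0.0, weights[k] + step)
        obj = objective(prop)
        if not np.isnan(obj) and obj > best:
            weights, best = prop, obj
            trace.append(best)
            n_improve += 1
            no_improve = 0
        else:
            no_improve += 1

    return DimensionModel(
        dimension=dimension,
        weights=weights,
        objective=best,
        seed_objective=seed_obj,
        n_iterations=it,
        n_improvements=n_improve,
        rng_seed=rng_seed,
        trace=trace,
    )


def dimension_score(model: DimensionModel, driver_scores: pd.DataFrame) -> pd.Series:
    """M_d per country: flexible weighted driver average, rank-normalized to [0, 1]."""
    raw = flexible_combination(driver_scores, model.weights)
    if raw.notna().sum() < 2:
        raise ValueError(f"dimension {model.dimension}: fewer than 2 scored countries")
    out = rank_normalize(raw)
    out.name = model.dimension
    return out


def merge_dat_grf(
    m_dat: pd.Series,
    m_grf: pd.Series,
    weights: tuple[float, float] = (0.1, 0.2),
) -> pd.Series:
    """Weighted average of the two data-generation dimensions.

    Weights are proportional to (e_DAT, e_GRF); a country missing one of the
    two passes the other through; missing both stays missing.
    """
    w_dat, w_grf = weights
    if w_dat < 0 or w_grf < 0 or w_dat + w_grf == 0:
        raise ValueError("merge weights must be nonnegative with a positive sum")
    num = m_dat.fillna(0.0) * w_dat + m_grf.fillna(0.0) * w_grf
    den = m_dat.notna() * w_dat + m_grf.notna() * w_grf
    out = num / den.where(den > 0)
    out.name = "DAT-GRF"
    return out


def bip_score(M: pd.DataFrame, e_weights: dict[str, float]) -> pd.Series:
    """Weighted Euclidean distance to the origin over available dimensions.

    BIP = sqrt(sum_d (e_d * M_d)^2); dimensions missing for a country are
    excluded from its sum (they also depress the country's RRS). Countries
    missing every dimension come out missing.
    """
    dims = [d for d in M.columns if d in e_weights]
    if not dims:
        raise ValueError("no dimension columns match the e_weights")
    acc = pd.Series(0.0, index=M.index)
    any_avail = pd.Series(False, index=M.index)
    for d in dims:
        term = (e_weights[d] * M[d]) ** 2
        acc += term.fillna(0.0)
        any_avail |= M[d].notna()
    out = np.sqrt(acc).where(any_avail)
    out.name = "BIP"
    return out


def compute_rrs(table_values: pd.DataFrame, models: list[DriverModel]) -> pd.Series:
    """Percent of the index's model variables with data, per country.

    The denominator is the union of raw variables over every fitted driver
    model (all dimensions); the numerator counts those present for the
    country.
    """
    union: set[str] = set()
    for m in models:
        union.update(m.variables)
    if not union:
        raise ValueError("no fitted model variables: RRS undefined")
    cols = sorted(union & set(table_values.columns))
    missing_cols = len(union) - len(cols)
    present = table_values[cols].notna().sum(axis=1)
    out = 100.0 * present / len(union)
    if missing_cols:
        logger.warning("%d model variables absent from the scoring table", missing_cols)
    out.name = "RRS"
    return out


def rank_countries(scores: pd.DataFrame, *, rrs_min: float = 75.0) -> pd.DataFrame:
    """Gate by RRS and rank eligible countries by descending BIP.

    Ties break by higher RRS, then lexicographic ISO code. Ineligible
    countries (RRS < rrs_min or missing BIP) keep their rows with an empty
    rank. Expects columns ``BIP`` and ``RRS`` indexed by ISO code.
    """
    out = scores.copy()
    out["eligible"] = (out["RRS"] >= rrs_min) & out["BIP"].notna()
    # descending BIP, ties by RRS, then deterministic ISO tie-break
    out = (
        out.reset_index(names="ISO")
        .sort_values(by=["eligible", "BIP", "RRS", "ISO"],
                     ascending=[False, False, False, True], kind="stable")
        .set_index("ISO")
    )
    ranks = np.full(len(out), np.nan)
    ranks[: int(out["eligible"].sum())] = np.arange(1, int(out["eligible"].sum()) + 1)
    out["rank"] = ranks
    return out


def generation_hosting_coordinates(
    scores: pd.DataFrame, e_weights: dict[str, float]
) -> pd.DataFrame:
    """Plot-ready (generation, hosting) coordinates per country.

    x combines the merged DAT-GRF score with SPCS, weighted proportionally
    to (e_DAT + e_GRF) : e_SPCS; y is the HOST dimension score. Countries
    missing every generation component get a missing x.
    """
    w_gen = e_weights.get("DAT", 0.0) + e_weights.get("GRF", 0.0)
    w_spcs = e_weights.get("SPCS", 0.0)
    datgrf = scores["M_DATGRF"]
    spcs = scores["M_SPCS"]
    num = datgrf.fillna(0.0) * w_gen + spcs.fillna(0.0) * w_spcs
    den = datgrf.notna() * w_gen + spcs.notna() * w_spcs
    x = num / den.where(den > 0)
    return pd.DataFrame({"generation": x, "hosting": scores["M_HOST"]})
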