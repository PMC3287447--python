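"""Driver x dimension regression models with collinearity substitution.

For each of the nine drivers against each of the four response dimensions a
stepwise multiple regression is fitted on standardized ranks (forward
selection with backward elimination). Retained terms are checked for
collinearity by variance inflation factor; sets of mutually correlated
high-VIF terms are replaced by the first principal component of their
correlation matrix, and the regression is re-run with the surviving direct
terms plus the composites. The fitted driver score for a country is

    D_dk = [ sum_i c_i * x_i  +  sum_j c_j * (sum_a z_aj * w_aj) ] / m

where x_i are the s directly retained variables, w_aj the members of the
j-th principal-component composite with loadings z_aj, c_i and c_j the
regression coefficients, and m the number of components (direct terms plus
composites) for which the country has any data — the flexible-indexing rule
that tolerates missing values without imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import BipConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Final term set of a forward/backward stepwise OLS fit."""

    terms: list[str]
    coefs: dict[str, float]
    betas: dict[str, float]          # standardized coefficients
    pvalues: dict[str, float]
    intercept: float
    r2: float
    n_obs: int
    skipped: list[str] = field(default_factory=list)  # candidates with too few rows


def _ols(X: pd.DataFrame, y: pd.Series, terms: list[str]):
    """OLS of y on terms over rows complete for those terms and y."""
    cols = X[terms] if terms else pd.DataFrame(index=X.index)
    rows = y.notna() if not terms else (cols.notna().all(axis=1) & y.notna())
    design = sm.add_constant(cols[rows], has_constant="add")
    model = sm.OLS(y[rows].astype(float), design.astype(float))
    return model.fit(), rows


def stepwise_mra(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseResult:
    """Forward selection with backward elimination on OLS p-values.

    Each forward step adds the candidate with the smallest t-test p-value if
    it clears ``alpha_enter`` (ties broken by variable id); each backward
    pass removes terms whose p-value exceeds ``alpha_remove``. Fitting is
    listwise over the terms currently considered. Candidates with fewer
    complete rows than terms + 2 are skipped with a warning. Deterministic
    given column order.
    """
    if X.shape[1] == 0:
        raise ValueError("stepwise_mra needs at least one candidate predictor")
    yv = y.dropna()
    if yv.nunique() < 2:
        raise ValueError("response is constant; nothing to fit")

    current: list[str] = []
    skipped: set[str] = set()
    candidates = sorted(X.columns)

    while True:
        changed = False
        # forward step
        best_var, best_p = None, np.inf
        for cand in candidates:
            if cand in current:
                continue
            trial = current + [cand]
            rows = X[trial].notna().all(axis=1) & y.notna()
            if int(rows.sum()) < len(trial) + 2:
                if cand not in skipped:
                    skipped.add(cand)
                    logger.warning("candidate %s skipped: only %d complete rows",
                                   cand, int(rows.sum()))
                continue
            fit, _ = _ols(X, y, trial)
            p = float(fit.pvalues.get(cand, np.nan))
            if np.isnan(p):
                continue  # candidate collinear with current terms
            if p < best_p:
                best_var, best_p = cand, p
        if best_var is not None and best_p <= alpha_enter:
            current.append(best_var)
            current.sort()
            changed = True
        # backward pass
        while len(current) >= 1:
            fit, _ = _ols(X, y, current)
            pv = fit.pvalues.drop("const", errors="ignore")
            worst = pv.sort_index().sort_values(kind="stable").index[-1] if len(pv) else None
            if worst is None or float(pv[worst]) <= alpha_remove:
                break
            current.remove(worst)
            changed = True
        if not changed:
            break

    if not current:
        logger.warning("stepwise selection retained no terms")
        return StepwiseResult([], {}, {}, {}, float(yv.mean()), 0.0,
                              int(y.notna().sum()), sorted(skipped))

    fit, rows = _ols(X, y, current)
    n = int(rows.sum())
    sd_y = float(y[rows].std(ddof=1))
    betas = {}
    for t in current:
        sd_x = float(X.loc[rows, t].std(ddof=1))
        betas[t] = float(fit.params[t]) * (sd_x / sd_y if sd_y > 0 else np.nan)
    return StepwiseResult(
        terms=list(current),
        coefs={t: float(fit.params[t]) for t in current},
        betas=betas,
        pvalues={t: float(fit.pvalues[t]) for t in current},
        intercept=float(fit.params["const"]),
        r2=float(fit.rsquared),
        n_obs=n,
        skipped=sorted(skipped),
    )


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2) for each column.

    R^2_i regresses column i on the remaining columns (with intercept) over
    rows complete for all columns. Perfect collinearity reports +inf.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two terms")
    complete = design.dropna()
    if len(complete) < design.shape[1] + 1:
        raise ValueError("too few complete rows to assess collinearity")
    arr = complete.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        raise ValueError("constant column over complete rows; VIF undefined")
    out = {}
    n = arr.shape[1]
    for i in range(n):
        yi = arr[:, i]
        Xi = np.column_stack([np.ones(len(arr)), np.delete(arr, i, axis=1)])
        coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yi - yi.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[design.columns[i]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class CollinearitySet:
    """Mutually correlated high-VIF terms slated for PC substitution."""

    members: list[str]
    vifs: dict[str, float]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a collinearity set needs >= 2 members")


def find_collinear_sets(
    design: pd.DataFrame,
    vifs: pd.Series,
    *,
    vif_max: float = 4.0,
    collinear_r: float = 0.7,
) -> list[CollinearitySet]:
    """Group VIF violators into connected components of the |r| >= threshold graph.

    Only terms with VIF > ``vif_max`` participate; pairs among them with
    absolute Pearson correlation >= ``collinear_r`` (over complete rows) are
    linked, and each connected component of size >= 2 becomes one set.
    High-VIF terms with no strong pairwise partner are left in place (logged).
    """
    hot = [t for t in design.columns if vifs[t] > vif_max]
    if len(hot) < 2:
        if hot:
            logger.info("term %s has VIF %.2f but no collinear partner", hot[0], vifs[hot[0]])
        return []
    sub = design[hot].dropna()
    corr = sub.corr().abs()
    # union-find over the correlation graph
    parent = {t: t for t in hot}

    def root(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(hot):
        for b in hot[i + 1:]:
            if corr.loc[a, b] >= collinear_r:
                parent[root(a)] = root(b)

    groups: dict[str, list[str]] = {}
    for t in hot:
        groups.setdefault(root(t), []).append(t)
    sets = []
    for members in groups.values():
        if len(members) >= 2:
            sets.append(CollinearitySet(sorted(members), {m: float(vifs[m]) for m in members}))
        else:
            logger.info("term %s has VIF %.2f but no collinear partner",
                        members[0], vifs[members[0]])
    sets.sort(key=lambda s: s.members[0])
    return sets


# ---------------------------------------------------------------------------
# principal-component substitution
# ---------------------------------------------------------------------------

@dataclass
class PCComposite:
    """First-PC replacement of a collinear variable set.

    The composite value for a country is sum_a z_a * w_a over the members
    available for that country, where w_a is the member standardized by the
    mean/sd stored at fit time and z_a the first-component loading. The sign
    is oriented at fit time so the composite correlates positively with the
    response.
    """

    name: str
    members: list[str]
    loadings: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    explained_ratio: float

    def transform(self, table: pd.DataFrame) -> pd.Series:
        """Composite values with flexible handling of missing members."""
        acc = pd.Series(0.0, index=table.index)
        any_avail = pd.Series(False, index=table.index)
        for m in self.members:
            std = (table[m] - self.means[m]) / self.sds[m]
            avail = std.notna()
            acc = acc.add(std.fillna(0.0) * self.loadings[m])
            any_avail |= avail
        out = acc.where(any_avail)
        out.name = self.name
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "members": self.members,
            "loadings": self.loadings,
            "means": self.means,
            "sds": self.sds,
            "explained_ratio": self.explained_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCComposite":
        return cls(**d)


def pca_substitute(
    members: pd.DataFrame,
    response: pd.Series | None = None,
    name: str = "PC1",
) -> PCComposite:
    """Collapse a collinear set to its first principal component.

    The PCA is run on the correlation matrix of the member columns over
    complete rows (members are re-standardized to zero mean, unit variance).
    The loading sign is flipped, if needed, so the composite correlates
    positively with ``response`` (falling back to a positive loading sum
    when no response is given or the correlation vanishes).
    """
    if members.shape[1] < 2:
        raise ValueError("PCA substitution needs >= 2 member variables")
    complete = members.dropna()
    if len(complete) < 3:
        raise ValueError(
            f"only {len(complete)} complete rows for {list(members.columns)}: "
            "cannot extract a principal component"
        )
    arr = complete.to_numpy(dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant member column; correlation-matrix PCA undefined")
    std = (arr - means) / sds
    corr = np.corrcoef(std, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    first = eigvecs[:, -1]
    explained = float(eigvals[-1] / eigvals.sum())

    comp_fit = std @ first
    flip = False
    if response is not None:
        resp = response.reindex(complete.index).to_numpy(dtype=float)
        ok = ~np.isnan(resp)
        if ok.sum() >= 3 and np.std(resp[ok]) > 0 and np.std(comp_fit[ok]) > 0:
            r = float(np.corrcoef(comp_fit[ok], resp[ok])[0, 1])
            flip = r < 0
        else:
            flip = first.sum() < 0
    else:
        flip = first.sum() < 0
    if flip:
        first = -first

    cols = list(members.columns)
    return PCComposite(
        name=name,
        members=cols,
        loadings={c: float(z) for c, z in zip(cols, first)},
        means={c: float(m) for c, m in zip(cols, means)},
        sds={c: float(s) for c, s in zip(cols, sds)},
        explained_ratio=explained,
    )


# ---------------------------------------------------------------------------
# the driver model
# ---------------------------------------------------------------------------

@dataclass
class DriverModel:
    """Fitted regression of one driver against one dimension."""

    driver: str
    dimension: str
    direct_terms: list[tuple[str, float]]            # (variable, coefficient c_i)
    pc_terms: list[tuple[PCComposite, float]]        # (composite, coefficient c_j)
    fit_stats: dict
    n_stepwise_fits: int = 1                         # initial fit + any refits

    @property
    def n_components(self) -> int:
        return len(self.direct_terms) + len(self.pc_terms)

    @property
    def variables(self) -> list[str]:
        """All raw variables behind the model (direct plus composite members)."""
        out = [v for v, _ in self.direct_terms]
        for comp, _ in self.pc_terms:
            out.extend(comp.members)
        return sorted(set(out))

    def to_dict(self) -> dict:
        return {
            "driver": self.driver,
            "dimension": self.dimension,
            "direct_terms": [[v, c] for v, c in self.direct_terms],
            "pc_terms": [[comp.to_dict(), c] for comp, c in self.pc_terms],
            "fit_stats": self.fit_stats,
            "n_stepwise_fits": self.n_stepwise_fits,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriverModel":
        return cls(
            driver=d["driver"],
            dimension=d["dimension"],
            direct_terms=[(v, float(c)) for v, c in d["direct_terms"]],
            pc_terms=[(PCComposite.from_dict(cd), float(c)) for cd, c in d["pc_terms"]],
            fit_stats=d["fit_stats"],
            n_stepwise_fits=int(d.get("n_stepwise_fits", 1)),
        )


def _term_columns(
    X: pd.DataFrame,
    terms: list[str],
    composites: dict[str, PCComposite],
) -> pd.DataFrame:
    cols = {}
    for t in terms:
        cols[t] = composites[t].transform(X) if t in composites else X[t]
    return pd.DataFrame(cols, index=X.index)


def fit_driver(
    driver: str,
    dimension: str,
    X: pd.DataFrame,
    response: pd.Series,
    config: BipConfig | None = None,
    *,
    max_rounds: int = 5,
) -> DriverModel | None:
    """Full fitting pipeline for one driver x dimension cell.

    stepwise selection -> VIF check -> PCA substitution of collinear sets ->
    stepwise refit with direct survivors plus composites, iterated until no
    VIF violation remains (composites that turn collinear with a direct term
    are merged back to raw members and re-extracted). Returns None when the
    screened pool is empty or selection retains nothing — an absent driver
    is a legal outcome reported as zeros downstream.
    """
    config = config or BipConfig()
    if X.shape[1] == 0:
        logger.info("driver %s has no screened variables for %s", driver, dimension)
        return None

    result = stepwise_mra(
        X, response, alpha_enter=config.alpha_enter, alpha_remove=config.alpha_remove
    )
    n_fits = 1
    if not result.terms:
        logger.info("driver %s retained no terms for %s", driver, dimension)
        return None

    composites: dict[str, PCComposite] = {}
    pc_counter = 0

    for _round in range(max_rounds):
        terms = result.terms
        if len(terms) < 2:
            break
        design = _term_columns(X, terms, composites)
        try:
            vifs = compute_vif(design)
        except ValueError as exc:
            logger.warning("VIF check skipped for %s/%s: %s", driver, dimension, exc)
            break
        sets = find_collinear_sets(
            design, vifs, vif_max=config.vif_max, collinear_r=config.collinear_r
        )
        if not sets:
            break
        substituted_raw: set[str] = set()
        new_names: list[str] = []
        for cset in sets:
            raw: set[str] = set()
            for m in cset.members:
                raw.update(composites[m].members if m in composites else [m])
            pc_counter += 1
            name = f"PC{pc_counter}_{driver}_{dimension}"
            try:
                comp = pca_substitute(X[sorted(raw)], response=response, name=name)
            except ValueError as exc:
                logger.warning("set %s left unsubstituted: %s", cset.members, exc)
                continue
            composites[name] = comp
            new_names.append(name)
            substituted_raw.update(cset.members)
        if not new_names:
            break
        survivors = [t for t in terms if t not in substituted_raw]
        pool = survivors + new_names
        pool_cols = _term_columns(X, pool, composites)
        result = stepwise_mra(
            pool_cols, response,
            alpha_enter=config.alpha_enter, alpha_remove=config.alpha_remove,
        )
        n_fits += 1
        if not result.terms:
            logger.warning("refit after substitution emptied %s/%s", driver, dimension)
            return None
    else:
        logger.warning("collinearity loop hit max_rounds for %s/%s", driver, dimension)

    direct = [(t, result.coefs[t]) for t in result.terms if t not in composites]
    pcs = [(composites[t], result.coefs[t]) for t in result.terms if t in composites]
    return DriverModel(
        driver=driver,
        dimension=dimension,
        direct_terms=direct,
        pc_terms=pcs,
        fit_stats={
            "r2": result.r2,
            "n_obs": result.n_obs,
            "pvalues": result.pvalues,
            "betas": result.betas,
            "intercept": result.intercept,
        },
        n_stepwise_fits=n_fits,
    )


def driver_score(model: DriverModel, table: pd.DataFrame) -> pd.Series:
    """Score every country of ``table`` (normalized-rank columns) with one model.

    Each component (direct term or composite) contributes coefficient x value
    where the country has data; the sum is divided by the number of
    components with any data — flexible indexing. Countries with no data for
    any component score missing.
    """
    if model.n_components < 1:
        raise ValueError("model has no components")
    total = pd.Series(0.0, index=table.index)
    n_avail = pd.Series(0, index=table.index)
    for var, coef in model.direct_terms:
        x = table[var]
        avail = x.notna()
        total += (coef * x).fillna(0.0)
        n_avail += avail.astype(int)
    for comp, coef in model.pc_terms:
        val = comp.transform(table)
        avail = val.notna()
        total += (coef * val).fillna(0.0)
        n_avail += avail.astype(int)
    out = total.where(n_avail > 0) / n_avail.where(n_avail > 0)
    out.name = f"{model.dimension}:{model.driver}"
    return out
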