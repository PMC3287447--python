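"""Spearman screening of candidate predictors and rank normalization.

Country-level indicator variables are mostly non-normal, so association with
each response dimension is measured by Spearman's rank correlation on all
complete (predictor, response) pairs. Variables that are not significantly
correlated, or whose coefficient falls below a threshold (default 0.5,
applied to |rho|), are discarded. Survivors are replaced by their midranks
and min-max rescaled to [0, 1]:

    x(n) = [X - X(min)] / [X(max) - X(min)]

applied to the ranks, so 0 is the lowest rank of the set and 1 the highest.
Every downstream stage operates on these standardized ranks, which makes the
whole pipeline invariant to strictly increasing transforms of raw inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import WorkingTable

logger = logging.getLogger(__name__)


@dataclass
class VariableScreen:
    """Screening outcome for one candidate predictor."""

    variable: str
    rho: float          # NaN when undefined (constant input or too few pairs)
    p_value: float      # NaN likewise
    n_pairs: int
    retained: bool
    reason: str = ""    # why not retained, "" if retained


@dataclass
class ScreeningResult:
    """Per-dimension attrition audit of the candidate pool."""

    dimension: str
    screens: list[VariableScreen] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [s.variable for s in self.screens if s.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dimension": self.dimension,
                    "variable": s.variable,
                    "rho": s.rho,
                    "p": s.p_value,
                    "n_pairs": s.n_pairs,
                    "retained": s.retained,
                    "reason": s.reason,
                }
                for s in self.screens
            ]
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_normalize(values: pd.Series) -> pd.Series:
    """Replace values by midranks, then min-max rescale to [0, 1].

    Missing entries pass through as missing. With all non-missing values
    equal the output is 0.5 everywhere (mid-scale) with a warning; fewer
    than two non-missing values is an error.
    """
    mask = values.notna()
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"rank_normalize needs >= 2 non-missing values, got {n}")
    out = pd.Series(np.nan, index=values.index, dtype=float, name=values.name)
    x = values[mask].to_numpy(dtype=float)
    ranks = stats.rankdata(x, method="average")
    lo, hi = ranks.min(), ranks.max()
    if hi == lo:
        logger.warning("constant vector %r: rank-normalized to 0.5", values.name)
        out[mask] = 0.5
        return out
    out[mask] = (ranks - lo) / (hi - lo)
    return out


def _screen_one(
    x: pd.Series,
    y: pd.Series,
    alpha: float,
    rho_min: float,
    min_pairs: int,
    mode: str,
) -> VariableScreen:
    pair = x.notna() & y.notna()
    n_pairs = int(pair.sum())
    name = str(x.name)
    if n_pairs < min_pairs:
        return VariableScreen(name, np.nan, np.nan, n_pairs, False,
                              f"only {n_pairs} complete pairs (< {min_pairs})")
    xv = x[pair].to_numpy(dtype=float)
    yv = y[pair].to_numpy(dtype=float)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return VariableScreen(name, np.nan, np.nan, n_pairs, False,
                              "constant over the pair set; rho undefined")
    res = stats.spearmanr(xv, yv)
    rho, p = float(res.statistic), float(res.pvalue)
    if np.isnan(rho):
        return VariableScreen(name, rho, p, n_pairs, False, "rho undefined")
    effect = abs(rho) if mode == "absolute" else rho
    if p > alpha:
        return VariableScreen(name, rho, p, n_pairs, False, f"p={p:.3g} > alpha")
    if effect < rho_min:
        return VariableScreen(name, rho, p, n_pairs, False,
                              f"low-response: {'|rho|' if mode == 'absolute' else 'rho'}"
                              f"={effect:.3f} < {rho_min}")
    return VariableScreen(name, rho, p, n_pairs, True)


def spearman_screen(
    table: WorkingTable,
    response: pd.Series,
    *,
    alpha: float = 0.05,
    rho_min: float = 0.5,
    min_pairs: int = 10,
    mode: str = "absolute",
    dimension: str = "",
) -> ScreeningResult:
    """Screen every table column against one response dimension.

    Correlations are pair-wise: each predictor uses all countries where both
    that predictor and the response are present. Retention requires
    p <= alpha and effect >= rho_min (effect is |rho| in ``absolute`` mode,
    signed rho in ``signed`` mode). Constant vectors and under-sampled
    screens are flagged, never fatal.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    y = response.reindex(table.countries)
    if y.notna().sum() < min_pairs:
        raise ValueError(
            f"response has {int(y.notna().sum())} non-missing entries (< {min_pairs})"
        )
    result = ScreeningResult(dimension=dimension)
    for var in table.variables:
        result.screens.append(
            _screen_one(table.values[var], y, alpha, rho_min, min_pairs, mode)
        )
    return result
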