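"""Synthetic country x variable fixtures with known ground truth.

The generator plants two latent country capacities — data *generation* g and
data *hosting* h, independent uniform(0, 1) by default — and emits a long
record file in which every predictor is a noisy, strictly monotone transform
of its driver's latent: biological/environmental/intrinsic drivers (BIO,
ENV, GEO, POP) load on g, infrastructure/power drivers (ICT, PWR, PWF) on h,
and the development drivers (DVE, DVH) on an even mixture. Response proxies
mimic heavy-tailed indexed record counts: DAT grows exponentially in g, GRF
is a g-dependent geo-referenced fraction of DAT (so GRF <= DAT always),
SPCS scales linearly with g, and HOST grows exponentially in h. Cells are
masked missing completely at random at a configurable rate (an optional
mode concentrates missingness in low-capacity countries to stress the
reliability gate). Everything is reproducible from one integer seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .config import DRIVER_CATEGORY, DRIVERS
from .dataset import VariableRecord

#: Which latent each driver's variables reflect: weight on g (rest on h).
DEFAULT_LATENT_MAP = {
    "BIO": 1.0, "ENV": 1.0, "GEO": 1.0, "POP": 1.0,
    "ICT": 0.0, "PWR": 0.0, "PWF": 0.0,
    "DVE": 0.5, "DVH": 0.5,
}

# strictly increasing links applied on the noisy latent scale, cycled per variable
_LINKS = {
    "identity": lambda t: t,
    "exp": np.exp,
    "cube": lambda t: t ** 3,
    "arctan": np.arctan,
}
_LINK_CYCLE = ("identity", "exp", "cube", "arctan")

# rounding granularity for the count-like responses; fine enough that the
# rounded counts stay strictly monotone in the latent at zero noise
_COUNT_SCALE = 1e6


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_countries: int = 150
    variables_per_driver: int = 4
    noise_sd: float = 0.1
    missing_rate: float = 0.1
    rng_seed: int = 0
    latent_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LATENT_MAP))
    #: fraction of variables given a negative loading (sign-handling exercise)
    negative_fraction: float = 0.25
    #: "mcar" or "capacity" (missingness concentrates in low-capacity countries)
    missing_mode: str = "mcar"
    #: fraction of (country, variable) cells that also carry an earlier-year decoy
    earlier_year_fraction: float = 0.3
    latest_year: int = 2008
    earlier_year: int = 2000

    def validate(self) -> None:
        if self.n_countries < 10:
            raise ValueError("n_countries must be >= 10")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.variables_per_driver < 1:
            raise ValueError("variables_per_driver must be >= 1")
        if self.missing_mode not in ("mcar", "capacity"):
            raise ValueError("missing_mode must be 'mcar' or 'capacity'")
        if not 0 <= self.negative_fraction <= 1:
            raise ValueError("negative_fraction must lie in [0, 1]")
        unknown = set(self.latent_map) - set(DRIVERS)
        if unknown:
            raise ValueError(f"latent_map names unknown drivers {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Latents, loadings and response values behind a synthetic dataset."""

    countries: list[str]
    g: pd.Series                      # generation capacity per country
    h: pd.Series                      # hosting capacity per country
    loadings: dict[str, float]        # variable -> signed weight on its latent mix
    latent_weights: dict[str, float]  # variable -> weight on g (rest on h)
    responses: pd.DataFrame           # columns DAT, GRF, HOST, SPCS

    def composite_latent(self, e_weights: dict[str, float]) -> pd.Series:
        """The true analog of the final score: weighted Euclidean mix of g and h.

        Each dimension's true score is the rank-normalized latent it is
        monotone in (g for DAT/GRF/SPCS, h for HOST), combined exactly as
        the estimated composite combines its dimension scores.
        """
        from .screening import rank_normalize

        rg = rank_normalize(self.g)
        rh = rank_normalize(self.h)
        acc = pd.Series(0.0, index=rg.index)
        for dim, w in e_weights.items():
            m = rh if dim == "HOST" else rg
            acc += (w * m) ** 2
        return np.sqrt(acc)

    def write(self, path) -> None:
        frame = pd.concat(
            [self.g.rename("g"), self.h.rename("h"), self.responses], axis=1
        )
        frame.to_csv(path, index_label="country")


def country_codes(n: int) -> list[str]:
    """Deterministic ISO-alpha-3-shaped codes: AAA, AAB, AAC, ..."""
    codes = []
    for combo in product(string.ascii_uppercase, repeat=3):
        codes.append("".join(combo))
        if len(codes) == n:
            return codes
    raise ValueError("too many countries requested")


def _responses(g: np.ndarray, h: np.ndarray) -> dict[str, np.ndarray]:
    dat = np.round(np.exp(6.0 * g) * _COUNT_SCALE)
    geo_fraction = 0.3 + 0.7 * g          # in (0.3, 1]: GRF <= DAT by construction
    grf = np.round(dat * geo_fraction)
    spcs = np.round(20.0 * g * _COUNT_SCALE)
    host = np.round(np.exp(5.0 * h) * _COUNT_SCALE)
    return {"DAT": dat, "GRF": grf, "HOST": host, "SPCS": spcs}


def generate(spec: SyntheticSpec) -> tuple[list[VariableRecord], GroundTruth]:
    """Draw one dataset: long-format records plus its ground truth.

    Each variable carries records in the latest year; a random subset of
    (country, variable) cells also carries an earlier-year decoy value, so
    latest-available logic is exercised. Missing cells have *all* their
    years removed, making the cell genuinely absent from the working table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    countries = country_codes(spec.n_countries)
    g = rng.uniform(0.0, 1.0, spec.n_countries)
    h = rng.uniform(0.0, 1.0, spec.n_countries)

    records: list[VariableRecord] = []
    loadings: dict[str, float] = {}
    latent_weights: dict[str, float] = {}

    var_index = 0
    for driver in DRIVERS:
        wg = spec.latent_map.get(driver, 0.0)
        latent = wg * g + (1.0 - wg) * h
        neg_period = round(1 / spec.negative_fraction) if spec.negative_fraction > 0 else 0
        for i in range(spec.variables_per_driver):
            var = f"{driver}_v{i + 1}"
            sign = -1.0 if (neg_period and var_index % neg_period == 0) else 1.0
            link = _LINKS[_LINK_CYCLE[var_index % len(_LINK_CYCLE)]]
            var_index += 1
            loadings[var] = sign
            latent_weights[var] = wg

            noise = rng.normal(0.0, spec.noise_sd, spec.n_countries)
            values = link(sign * latent + noise)

            if spec.missing_mode == "mcar":
                drop = rng.uniform(size=spec.n_countries) < spec.missing_rate
            else:
                # missingness concentrates where combined capacity is low;
                # calibrated so the mean rate stays ~missing_rate
                capacity = (g + h) / 2.0
                p = np.clip(2.0 * spec.missing_rate * (1.0 - capacity), 0.0, 0.95)
                drop = rng.uniform(size=spec.n_countries) < p
            earlier = rng.uniform(size=spec.n_countries) < spec.earlier_year_fraction
            decoy = values + rng.normal(0.0, max(spec.noise_sd, 0.05), spec.n_countries)

            for c_idx, country in enumerate(countries):
                if drop[c_idx]:
                    continue
                if earlier[c_idx]:
                    records.append(VariableRecord(
                        source="synthetic", category=DRIVER_CATEGORY[driver],
                        driver=driver, variable=var, year=spec.earlier_year,
                        country=country, value=float(decoy[c_idx]),
                    ))
                records.append(VariableRecord(
                    source="synthetic", category=DRIVER_CATEGORY[driver],
                    driver=driver, variable=var, year=spec.latest_year,
                    country=country, value=float(values[c_idx]),
                ))

    resp = _responses(g, h)
    truth = GroundTruth(
        countries=countries,
        g=pd.Series(g, index=countries, name="g"),
        h=pd.Series(h, index=countries, name="h"),
        loadings=loadings,
        latent_weights=latent_weights,
        responses=pd.DataFrame(resp, index=countries),
    )
    return records, truth


def records_to_csv(records: list[VariableRecord], path) -> None:
    """Emit the same long-format CSV the dataset module consumes."""
    pd.DataFrame(
        {
            "source": [r.source for r in records],
            "category": [r.category for r in records],
            "driver": [r.driver for r in records],
            "variable": [r.variable for r in records],
            "year": [r.year if r.year is not None else "" for r in records],
            "country": [r.country for r in records],
            "value": [r.value if r.value is not None else "" for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# worked toy fixture
# ---------------------------------------------------------------------------

def make_worked_toy() -> tuple[list[VariableRecord], pd.DataFrame]:
    """A tiny fixed fixture with hand-computable scores.

    Six countries, two drivers (BIO loading on generation, PWR on hosting),
    three variables each. Country AAA tops every variable; FFF is entirely
    missing, so it must fall under any reliability gate (RRS = 0). The
    responses are consistent monotone functions of the same ordering, so
    fitted models are degenerate-clean and ranks are predictable by hand.
    Regenerated output is byte-identical: the fixture is a constant.
    """
    countries = ["AAA", "BBB", "CCC", "DDD", "EEE", "FFF"]
    # each row: values for AAA..EEE (FFF missing everywhere), descending in rank
    base = {
        ("BIO", "BIO_v1"): [10.0, 8.0, 6.0, 4.0, 2.0],
        ("BIO", "BIO_v2"): [50.0, 40.0, 30.0, 20.0, 10.0],
        ("BIO", "BIO_v3"): [5.0, 4.0, 3.0, 2.0, 1.0],
        ("PWR", "PWR_v1"): [100.0, 80.0, 60.0, 40.0, 20.0],
        ("PWR", "PWR_v2"): [9.0, 7.0, 5.0, 3.0, 1.0],
        ("PWR", "PWR_v3"): [0.9, 0.7, 0.5, 0.3, 0.1],
    }
    records = []
    for (driver, var), vals in base.items():
        for country, val in zip(countries[:5], vals):
            records.append(VariableRecord(
                source="toy", category=DRIVER_CATEGORY[driver], driver=driver,
                variable=var, year=2008, country=country, value=val,
            ))
        # FFF carries explicit missing records so it keeps a (fully missing)
        # row in the working table and must fail the reliability gate
        records.append(VariableRecord(
            source="toy", category=DRIVER_CATEGORY[driver], driver=driver,
            variable=var, year=2008, country="FFF", value=None,
        ))
    responses = pd.DataFrame(
        {
            "DAT": [1000.0, 800.0, 600.0, 400.0, 200.0, np.nan],
            "GRF": [900.0, 700.0, 500.0, 300.0, 100.0, np.nan],
            "HOST": [500.0, 400.0, 300.0, 200.0, 100.0, np.nan],
            "SPCS": [250.0, 200.0, 150.0, 100.0, 50.0, np.nan],
        },
        index=countries,
    )
    return records, responses
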