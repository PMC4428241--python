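"""Core/accessory classification and accessory-fraction extrapolation.

Genes present in every individual of the cohort are *core*, genes present
in some but not all are *accessory*, and reference genes seen in no
individual are *unobserved*.  The fraction of accessory genes in an
infinitely large cohort is extrapolated by rarefaction: for each subset
size k the mean fraction of genes missing in at least one subset member is
computed, and a saturating regression model fitted to the means supplies
the asymptote.

Denominator convention: subsample fractions are taken over the fixed
*universe* of genes observed in at least one of the full cohort's
individuals.  Under this convention the expected fraction is provably
non-decreasing in k (a gene missing in >=1 of a subset is missing in >=1
of any superset) and the k = n point equals the cohort's accessory
fraction among observed genes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .datatypes import PresenceMatrix

LABELS = ("core", "accessory", "unobserved")
MODELS = ("exponential", "power_law", "negative_exponential", "spline")
DEFAULT_MAX_COMBINATIONS = 500
DEFAULT_EXTRAPOLATION_HORIZON = 100


@dataclass
class GeneLabelVector:
    """Per-gene core/accessory/unobserved labels plus summary counts."""

    species_id: str
    labels: pd.Series  # index gene_id, values in LABELS
    counts: dict[str, int]


def classify_genes(matrix: PresenceMatrix) -> GeneLabelVector:
    """Label every reference gene core / accessory / unobserved."""
    if matrix.n_individuals < 2:
        raise ValueError("classification requires at least 2 individuals")
    present_counts = matrix.presence.sum(axis=1)
    n = matrix.n_individuals
    labels = pd.Series("accessory", index=matrix.presence.index, name="label")
    labels[present_counts == n] = "core"
    labels[present_counts == 0] = "unobserved"
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    return GeneLabelVector(species_id=matrix.species_id, labels=labels, counts=counts)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionTable:
    """Subsample-size -> accessory-fraction curve.

    ``table`` has one row per subset size k with the number of
    combinations used, the per-combination fractions, and their mean and
    median.  ``universe_size`` is the fixed denominator (genes observed in
    >=1 cohort individual).
    """

    species_id: str
    table: pd.DataFrame  # columns: k, n_combinations, mean_fraction, median_fraction, fractions
    universe_size: int
    exhaustive: bool

    @property
    def sizes(self) -> np.ndarray:
        return self.table["k"].to_numpy()

    def means(self, use_median: bool = False) -> np.ndarray:
        col = "median_fraction" if use_median else "mean_fraction"
        return self.table[col].to_numpy()


def _distinct_random_combinations(
    n: int, k: int, count: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """``count`` distinct k-subsets of range(n), by rejection."""
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < count:
        combo = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out


def subsample_fractions(
    matrix: PresenceMatrix,
    sizes: Optional[Sequence[int]] = None,
    max_combinations: Optional[int] = None,
    seed: Optional[int] = None,
) -> RarefactionTable:
    """Accessory fraction of random individual subsets, per subset size.

    For each k, the fraction for one subset is the number of universe
    genes absent in at least one subset member divided by the universe
    size.  All C(n, k) combinations are used when ``max_combinations`` is
    None; otherwise min(C(n, k), max_combinations) distinct random
    combinations (seeded).
    """
    n = matrix.n_individuals
    if sizes is None:
        sizes = range(2, n + 1)
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes:
        raise ValueError("no subset sizes requested")
    if sizes[0] < 1 or sizes[-1] > n:
        raise ValueError(f"subset sizes must lie in 1..{n}, got {sizes[0]}..{sizes[-1]}")

    pres = matrix.presence.to_numpy()
    universe = pres.any(axis=1)
    universe_size = int(universe.sum())
    if universe_size == 0:
        raise ValueError("empty universe: no gene observed in any individual")
    pres_u = pres[universe]  # universe genes only
    rng = np.random.default_rng(seed)

    rows = []
    exhaustive = True
    for k in sizes:
        n_comb = _n_choose_k(n, k)
        if max_combinations is None or n_comb <= max_combinations:
            combos: Sequence[tuple[int, ...]] = list(itertools.combinations(range(n), k))
        else:
            combos = _distinct_random_combinations(n, k, max_combinations, rng)
            exhaustive = False
        fracs = np.empty(len(combos))
        for i, combo in enumerate(combos):
            present_in_all = pres_u[:, combo].all(axis=1)
            fracs[i] = (universe_size - int(present_in_all.sum())) / universe_size
        rows.append(
            {
                "k": k,
                "n_combinations": len(combos),
                "mean_fraction": float(fracs.mean()),
                "median_fraction": float(np.median(fracs)),
                "fractions": fracs,
            }
        )
    table = pd.DataFrame(rows)
    result = RarefactionTable(
        species_id=matrix.species_id,
        table=table,
        universe_size=universe_size,
        exhaustive=exhaustive,
    )
    _check_monotone(result)
    return result


def _n_choose_k(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


def _check_monotone(table: RarefactionTable) -> None:
    """The expected fraction is provably non-decreasing in k under the
    fixed-universe denominator; exact (exhaustive) means must respect it.
    Randomly sampled means may fluctuate within sampling noise."""
    means = table.means()
    diffs = np.diff(means)
    if table.exhaustive:
        if np.any(diffs < -1e-12):
            raise RuntimeError(
                "exhaustive rarefaction means decreased with subset size - "
                "this indicates an implementation defect"
            )
    elif np.any(diffs < -0.02):
        warnings.warn(
            "sampled rarefaction means decreased by more than sampling noise",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class AccessoryModelFit:
    """A regression model fitted to the rarefaction means.

    ``asymptote`` is the k -> infinity limit for the exponential and
    negative-exponential forms; None for power law (unbounded when the
    exponent is positive) and spline, for which ``horizon_value`` (the
    model value at ``extrapolation_horizon``) is reported instead.
    """

    model_name: str
    parameters: dict[str, float]
    asymptote: Optional[float]
    rss: float
    predict: Callable[[np.ndarray], np.ndarray]
    extrapolation_horizon: int = DEFAULT_EXTRAPOLATION_HORIZON
    horizon_value: Optional[float] = None
    mean_deviation: Optional[float] = None
    warnings: list[str] = field(default_factory=list)


def _exponential(k, a, b, c):
    return a - b * np.exp(-k / c)


def _power_law(k, a, b):
    return a * np.power(k, b)


def _negative_exponential(k, a, b):
    return a * (1.0 - np.exp(-b * k))


def _fit_curve(
    f, k, y, p0_list, bounds
) -> tuple[np.ndarray, float]:
    best = None
    best_rss = np.inf
    last_err: Optional[Exception] = None
    for p0 in p0_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    f, k, y, p0=p0, bounds=bounds, maxfev=20000
                )
            rss = float(np.sum((f(k, *popt) - y) ** 2))
            if rss < best_rss:
                best, best_rss = popt, rss
        except (RuntimeError, ValueError) as err:  # non-convergence for this start
            last_err = err
    if best is None:
        raise RuntimeError(
            f"model fit failed to converge from any start ({last_err})"
        )
    return best, best_rss


def fit_accessory_model(
    table: RarefactionTable,
    model_name: str = "exponential",
    use_median: bool = False,
    extrapolation_horizon: int = DEFAULT_EXTRAPOLATION_HORIZON,
    n_restarts: int = 20,
    seed: int = 0,
) -> AccessoryModelFit:
    """Least-squares fit of a saturation model to the per-size fractions.

    Models: ``exponential`` f(k) = a - b exp(-k/c) (asymptote a);
    ``power_law`` f(k) = a k^b; ``negative_exponential``
    f(k) = a (1 - exp(-b k)) (asymptote a); ``spline`` = monotone cubic
    (PCHIP) through the means, no asymptote.
    """
    if model_name not in MODELS:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODELS}")
    k = table.sizes.astype(float)
    y = table.means(use_median=use_median)
    finite = np.isfinite(y)
    k, y = k[finite], y[finite]
    if model_name != "spline" and len(k) < 3:
        raise ValueError("need at least 3 subset sizes with finite means to fit")
    rng = np.random.default_rng(seed)
    notes: list[str] = []

    if model_name == "spline":
        if len(k) < 2:
            raise ValueError("spline needs at least 2 points")
        pch = interpolate.PchipInterpolator(k, y, extrapolate=True)
        predict = lambda kk: np.asarray(pch(np.asarray(kk, dtype=float)))
        rss = float(np.sum((predict(k) - y) ** 2))
        return AccessoryModelFit(
            model_name="spline",
            parameters={},
            asymptote=None,
            rss=rss,
            predict=predict,
            extrapolation_horizon=extrapolation_horizon,
            horizon_value=float(predict(np.array([extrapolation_horizon]))[0]),
            warnings=["monotone spline has no asymptote; use horizon_value"],
        )

    y_last = float(y[-1])
    y_spread = max(float(y[-1] - y[0]), 1e-6)

    if model_name == "exponential":
        # init from a log-linear fit of the residuals a0 - y = b exp(-k/c)
        a0 = y_last + 0.05
        resid = np.clip(a0 - y, 1e-9, None)
        slope, intercept = np.polyfit(k, np.log(resid), 1)
        c0 = -1.0 / slope if slope < 0 else 2.0
        c0 = float(np.clip(c0, 0.1, 100.0))
        b0 = float(np.exp(intercept))
        p0_list = [[a0, b0, c0]]
        for _ in range(n_restarts):
            p0_list.append(
                [
                    y_last + rng.uniform(0.0, 0.3),
                    y_spread * rng.uniform(0.2, 5.0),
                    rng.uniform(0.3, 20.0),
                ]
            )
        bounds = ([0.0, 1e-12, 1e-3], [1.5, 10.0, 1e3])
        popt, rss = _fit_curve(_exponential, k, y, p0_list, bounds)
        a, b, c = (float(v) for v in popt)
        if a < y_last - 1e-6:
            notes.append("asymptote below last observed mean (within fit tolerance)")
        predict = lambda kk: _exponential(np.asarray(kk, dtype=float), a, b, c)
        return AccessoryModelFit(
            "exponential", {"a": a, "b": b, "c": c}, a, rss, predict,
            extrapolation_horizon, float(predict([extrapolation_horizon])[0]),
            warnings=notes,
        )

    if model_name == "power_law":
        pos = (k > 0) & (y > 0)
        if pos.sum() >= 2:
            bb, la = np.polyfit(np.log(k[pos]), np.log(y[pos]), 1)
            p0_list = [[float(np.exp(la)), float(bb)]]
        else:
            p0_list = [[max(y_last, 1e-3), 0.1]]
        for _ in range(n_restarts):
            p0_list.append([max(y_last, 1e-3) * rng.uniform(0.3, 2.0), rng.uniform(-1, 1)])
        bounds = ([1e-12, -5.0], [10.0, 5.0])
        popt, rss = _fit_curve(_power_law, k, y, p0_list, bounds)
        a, b = (float(v) for v in popt)
        if b > 0:
            notes.append(
                "power law with positive exponent has no finite asymptote; "
                "reporting value at the extrapolation horizon"
            )
        predict = lambda kk: _power_law(np.asarray(kk, dtype=float), a, b)
        return AccessoryModelFit(
            "power_law", {"a": a, "b": b}, None, rss, predict,
            extrapolation_horizon, float(predict([extrapolation_horizon])[0]),
            warnings=notes,
        )

    # negative exponential
    p0_list = [[max(y_last, 1e-3), 0.5]]
    for _ in range(n_restarts):
        p0_list.append([max(y_last, 1e-3) * rng.uniform(0.5, 2.0), rng.uniform(0.05, 2.0)])
    bounds = ([0.0, 1e-6], [1.5, 50.0])
    popt, rss = _fit_curve(_negative_exponential, k, y, p0_list, bounds)
    a, b = (float(v) for v in popt)
    predict = lambda kk: _negative_exponential(np.asarray(kk, dtype=float), a, b)
    return AccessoryModelFit(
        "negative_exponential", {"a": a, "b": b}, a, rss, predict,
        extrapolation_horizon, float(predict([extrapolation_horizon])[0]),
        warnings=notes,
    )


def estimate_accessory_percent(fit: AccessoryModelFit) -> float:
    """Percentage of accessory genes predicted by the model asymptote.

    The exponential family tends to underestimate, so this is a lower
    bound.  For a power law with positive exponent the value at the
    extrapolation horizon is returned (flagged in ``fit.warnings``); a
    spline fit has no asymptote and raises.
    """
    if fit.model_name == "spline":
        raise ValueError(
            "spline fit has no asymptote; use fit.horizon_value for a "
            "non-asymptotic extrapolation"
        )
    if fit.asymptote is not None:
        return 100.0 * fit.asymptote
    return 100.0 * float(fit.horizon_value)


def model_deviation(fit: AccessoryModelFit, expected_table: RarefactionTable,
                    use_median: bool = False) -> float:
    """Mean absolute deviation (percentage points) between the model curve
    and the expected fractions computed from the full individual pool."""
    k = expected_table.sizes.astype(float)
    if len(k) == 0:
        raise ValueError("expected-fraction table is empty")
    observed = expected_table.means(use_median=use_median)
    predicted = fit.predict(k)
    return float(np.mean(np.abs(predicted - observed)) * 100.0)


def fit_report(fit: AccessoryModelFit) -> dict:
    """JSON-serializable summary of a model fit."""
    return {
        "model": fit.model_name,
        "parameters": fit.parameters,
        "asymptote": fit.asymptote,
        "rss": fit.rss,
        "extrapolation_horizon": fit.extrapolation_horizon,
        "horizon_value": fit.horizon_value,
        "mean_deviation_pp": fit.mean_deviation,
        "warnings": fit.warnings,
    }


def write_rarefaction_tsv(table: RarefactionTable, path) -> None:
    out = table.table.drop(columns="fractions")
    out.to_csv(path, sep="\t", index=False)
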