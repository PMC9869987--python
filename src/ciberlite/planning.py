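"""Accuracy-in-parameter-estimation (AIPE) sample-size planning.

AIPE planning sizes a study so that a confidence interval is narrow
enough, rather than so that a test is powerful enough. For a
correlation the interval is the Fisher-z interval, which is asymmetric
on the r scale; "half-width" here means half the total interval width
by default (the alternative ``max_arm`` convention uses the longer
arm). For a standard deviation the interval is the chi-square interval
at an assumed point estimate.

Also includes light design bookkeeping for full-factorial
within-subjects studies: term enumeration and Bonferroni alpha
division across outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "AipeQuery",
    "DesignSpec",
    "AipeResult",
    "aipe_n_correlation",
    "aipe_n_sd",
    "bonferroni_alpha",
    "enumerate_design_terms",
    "correlation_halfwidth",
    "sd_halfwidth",
]

_CONVENTIONS = ("half_total", "max_arm")


@dataclass(frozen=True)
class AipeQuery:
    target: str  # "correlation" | "sd"
    assumed_value: float
    halfwidth: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.target not in ("correlation", "sd"):
            raise ValueError(f"unknown AIPE target {self.target!r}")
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if self.target == "correlation" and abs(self.assumed_value) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.target == "sd" and self.assumed_value <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class AipeResult:
    n: int
    halfwidth_at_n: float
    query: AipeQuery
    at_boundary: bool = False  # bound already satisfied at the minimum feasible n


@dataclass(frozen=True)
class DesignSpec:
    """Bookkeeping for a full-factorial within-subjects design."""

    n_within_factors: int
    n_outcomes: int
    base_alpha: float = 0.005

    def __post_init__(self) -> None:
        if self.n_within_factors < 1 or self.n_outcomes < 1:
            raise ValueError("factor and outcome counts must be >= 1")
        if not (0 < self.base_alpha < 1):
            raise ValueError("base_alpha must be in (0, 1)")

    @property
    def adjusted_alpha(self) -> float:
        return bonferroni_alpha(self.base_alpha, self.n_outcomes)

    @property
    def terms_per_outcome(self) -> int:
        return 2**self.n_within_factors - 1

    @property
    def total_terms(self) -> int:
        return self.terms_per_outcome * self.n_outcomes


def correlation_halfwidth(
    rho: float, n: int, level: float = 0.95, convention: str = "half_total"
) -> float:
    """Half-width of the Fisher-z CI for a correlation at sample size n."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    z = np.arctanh(rho)
    c = stats.norm.ppf((1 + level) / 2) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - c), np.tanh(z + c)
    if convention == "half_total":
        return float((hi - lo) / 2)
    return float(max(hi - rho, rho - lo))


def sd_halfwidth(
    sigma: float, n: int, level: float = 0.95, convention: str = "half_total"
) -> float:
    """Half-width of the chi-square SD interval at an assumed s = sigma."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    a = (1 - level) / 2
    lo = sigma * np.sqrt((n - 1) / stats.chi2.ppf(1 - a, n - 1))
    hi = sigma * np.sqrt((n - 1) / stats.chi2.ppf(a, n - 1))
    if convention == "half_total":
        return float((hi - lo) / 2)
    return float(max(hi - sigma, sigma - lo))


def aipe_n_correlation(
    rho: float,
    halfwidth: float,
    level: float = 0.95,
    convention: str = "half_total",
    n_max: int = 10_000_000,
) -> AipeResult:
    """Smallest n whose Fisher-z interval for rho is narrower than ``halfwidth``.

    Linear scan upward from n = 4 (the smallest size with a defined
    interval); the returned n satisfies the bound while n - 1 does not,
    unless the bound already holds at n = 4, which is flagged.
    """
    query = AipeQuery("correlation", rho, halfwidth, level)
    n = 4
    if correlation_halfwidth(rho, n, level, convention) <= halfwidth:
        return AipeResult(n, correlation_halfwidth(rho, n, level, convention), query, at_boundary=True)
    while n < n_max:
        n += 1
        hw = correlation_halfwidth(rho, n, level, convention)
        if hw <= halfwidth:
            return AipeResult(n, hw, query)
    raise ValueError(f"half-width {halfwidth} not attainable within n <= {n_max}")


def aipe_n_sd(
    sigma: float,
    halfwidth: float,
    level: float = 0.95,
    convention: str = "half_total",
    n_max: int = 10_000_000,
) -> AipeResult:
    """Smallest n whose chi-square SD interval at s = sigma is narrow enough.

    Note that SD intervals widen as the point estimate grows, so a plan
    at an assumed sigma understates the width if the observed SD comes
    out larger (and the lower bound rises along with it).
    """
    query = AipeQuery("sd", sigma, halfwidth, level)
    n = 2
    if sd_halfwidth(sigma, n, level, convention) <= halfwidth:
        return AipeResult(n, sd_halfwidth(sigma, n, level, convention), query, at_boundary=True)
    while n < n_max:
        n += 1
        hw = sd_halfwidth(sigma, n, level, convention)
        if hw <= halfwidth:
            return AipeResult(n, hw, query)
    raise ValueError(f"half-width {halfwidth} not attainable within n <= {n_max}")


def bonferroni_alpha(base_alpha: float, k: int) -> float:
    """Divide an overall alpha over k outcomes/tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < base_alpha < 1):
        raise ValueError("base_alpha must be in (0, 1)")
    return base_alpha / k


def enumerate_design_terms(
    n_factors: int, n_outcomes: int, factor_names: list[str] | None = None
) -> tuple[list[str], int]:
    """All main effects and interactions of a full-factorial design.

    Returns the per-outcome term labels (every non-empty subset of the
    factors, 2^f - 1 of them) and the total count across outcomes.
    """
    if n_factors < 1 or n_outcomes < 1:
        raise ValueError("n_factors and n_outcomes must be >= 1")
    names = factor_names or [f"F{i + 1}" for i in range(n_factors)]
    if len(names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    terms = [
        ":".join(combo)
        for size in range(1, n_factors + 1)
        for combo in combinations(names, size)
    ]
    return terms, len(terms) * n_outcomes
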