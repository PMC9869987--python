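"""Interval estimators, reliability and correlation-comparison statistics.

Everything a lean determinant study needs: t-based mean intervals,
Fisher-z confidence intervals for Pearson correlations, Cohen's Q for
comparing correlations from independent samples, McDonald's omega and
the Spearman-Brown coefficient for internal consistency, an eigenvalue
screen for dimensionality, and chi-square intervals for standard
deviations. Point estimates come with confidence intervals throughout:
the approach reports accuracy of estimation, not significance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FactorAnalysis

from .datamodel import (
    DeterminantBlock,
    DeterminantSummary,
    ExpertEstimateSet,
    InstrumentSpec,
    ResponseDataset,
    reverse_code,
    score_composite,
)

__all__ = [
    "IntervalEstimate",
    "CorrelationResult",
    "QComparison",
    "ReliabilityResult",
    "EigenScreen",
    "ExpertAggregate",
    "mean_ci",
    "fisher_z",
    "inverse_fisher",
    "correlation_ci",
    "spearman_brown",
    "mcdonald_omega",
    "eigen_screen",
    "cohens_q",
    "sd_ci",
    "summarize_determinants",
    "compare_correlation_matrices",
    "aggregate_expert_estimates",
    "results_table",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a confidence interval.

    ``degenerate`` flags intervals of zero width produced by
    zero-variance input (still well defined, but uninformative).
    """

    point: float
    lower: float
    upper: float
    level: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")
        if not (self.lower <= self.point <= self.upper):
            raise ValueError(
                f"interval must bracket the point: {self.lower} <= {self.point} <= {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its Fisher-z confidence interval."""

    r: float
    z: float
    ci: IntervalEstimate
    n: int


@dataclass(frozen=True)
class QComparison:
    """Cohen's Q: difference of Fisher-z values from two independent samples."""

    q: float
    ci: IntervalEstimate
    r1: float
    r2: float
    n1: int
    n2: int
    labels: tuple[str, str] | None = None

    @property
    def includes_zero(self) -> bool:
        return self.ci.contains(0.0)


@dataclass(frozen=True)
class ReliabilityResult:
    method: str  # "omega" | "spearman_brown"
    estimate: float
    k: int
    ci: IntervalEstimate | None = None
    converged: bool = True
    extraction: str | None = None  # omega only: "ml" or "principal_axis"


@dataclass(frozen=True)
class EigenScreen:
    """Eigenvalues of the item correlation matrix, with the Kaiser count."""

    eigenvalues: tuple[float, ...]
    n_factors_kaiser: int


# ---------------------------------------------------------------------------
# Core intervals


def mean_ci(values: Sequence[float], level: float = 0.95) -> IntervalEstimate:
    """t-based confidence interval for a mean: m +/- t_{(1+level)/2, n-1} * s/sqrt(n)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("mean_ci needs at least 2 observations")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        return IntervalEstimate(m, m, m, level, n, degenerate=True)
    h = stats.t.ppf((1 + level) / 2, n - 1) * s / np.sqrt(n)
    return IntervalEstimate(m, m - h, m + h, level, n)


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r)."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def inverse_fisher(z: float) -> float:
    return float(np.tanh(z))


def correlation_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> CorrelationResult:
    """Pearson r with the Fisher-z interval tanh(atanh(r) +/- z_c / sqrt(n-3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("correlation_ci needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    # floating-point round-off can push |r| a hair past 1 for collinear input
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        ci = IntervalEstimate(r, r, r, level, n, degenerate=True)
        return CorrelationResult(r=r, z=float(np.sign(r) * np.inf), ci=ci, n=n)
    z = np.arctanh(r)
    c = stats.norm.ppf((1 + level) / 2) / np.sqrt(n - 3)
    ci = IntervalEstimate(r, float(np.tanh(z - c)), float(np.tanh(z + c)), level, n)
    return CorrelationResult(r=r, z=float(z), ci=ci, n=n)


def cohens_q(
    r1: float, n1: int, r2: float, n2: int, level: float = 0.99
) -> QComparison:
    """Compare two correlations from independent samples on the Fisher-z scale.

    q = atanh(r1) - atanh(r2), with normal-theory interval
    q +/- z_c * sqrt(1/(n1-3) + 1/(n2-3)). The default 99% level follows
    the convention of using a stricter level for key estimates when many
    intervals are reported.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("cohens_q needs n1, n2 >= 4")
    q = fisher_z(r1) - fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    h = stats.norm.ppf((1 + level) / 2) * se
    ci = IntervalEstimate(q, q - h, q + h, level, min(n1, n2))
    return QComparison(q=q, ci=ci, r1=float(r1), r2=float(r2), n1=n1, n2=n2)


def sd_ci(sd: float, n: int, level: float = 0.95) -> IntervalEstimate:
    """Chi-square confidence interval for a standard deviation.

    [ s * sqrt((n-1)/chi2_{(1+level)/2, n-1}),
      s * sqrt((n-1)/chi2_{(1-level)/2, n-1}) ]
    """
    if n < 2:
        raise ValueError("sd_ci needs n >= 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return IntervalEstimate(0.0, 0.0, 0.0, level, n, degenerate=True)
    a = (1 - level) / 2
    lower = sd * np.sqrt((n - 1) / stats.chi2.ppf(1 - a, n - 1))
    upper = sd * np.sqrt((n - 1) / stats.chi2.ppf(a, n - 1))
    return IntervalEstimate(float(sd), float(lower), float(upper), level, n)


# ---------------------------------------------------------------------------
# Reliability and dimensionality


def spearman_brown(item1: Sequence[float], item2: Sequence[float]) -> ReliabilityResult:
    """Two-item reliability: 2r / (1 + r) for the inter-item correlation r."""
    x = np.asarray(item1, dtype=float)
    y = np.asarray(item2, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_brown undefined for constant items")
    r = float(np.corrcoef(x, y)[0, 1])
    if r <= -1.0:
        raise ValueError("spearman_brown undefined at r = -1")
    return ReliabilityResult(method="spearman_brown", estimate=2 * r / (1 + r), k=2)


def _omega_from_matrix(items: np.ndarray) -> tuple[float, bool, str]:
    """Single-factor omega for one respondent-by-item matrix.

    Maximum-likelihood one-factor fit; a Heywood case or non-convergence
    falls back to principal-axis extraction on the correlation matrix.
    Returns (omega, converged, extraction).
    """
    n, k = items.shape
    sds = items.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("omega undefined with a constant item")
    std = (items - items.mean(axis=0)) / sds

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = FactorAnalysis(n_components=1, svd_method="lapack")
        try:
            fa.fit(std)
            loadings = fa.components_.ravel()
            theta = fa.noise_variance_
            ml_ok = np.all(np.isfinite(loadings)) and np.all(theta > 1e-8)
            heywood = np.any(np.abs(loadings) > 1.0 + 1e-6)
        except Exception:
            ml_ok, heywood = False, False

    if ml_ok and not heywood:
        if loadings.sum() < 0:
            loadings = -loadings
        s = loadings.sum()
        return float(s**2 / (s**2 + theta.sum())), True, "ml"

    # principal-axis fallback: iterate communalities on the correlation matrix
    corr = np.corrcoef(std, rowvar=False)
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))  # SMC start
    for _ in range(200):
        red = corr.copy()
        np.fill_diagonal(red, h2)
        vals, vecs = np.linalg.eigh(red)
        lam = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        new_h2 = np.clip(lam**2, 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < 1e-8:
            h2 = new_h2
            break
        h2 = new_h2
    if lam.sum() < 0:
        lam = -lam
    s = lam.sum()
    theta_sum = np.sum(1.0 - np.clip(lam**2, 0.0, 1.0))
    return float(s**2 / (s**2 + theta_sum)), False, "principal_axis"


def mcdonald_omega(
    items: np.ndarray,
    level: float = 0.95,
    bootstrap_reps: int = 2000,
    seed: int | None = None,
) -> ReliabilityResult:
    """McDonald's omega from a single-factor model.

    omega = (sum lambda)^2 / [(sum lambda)^2 + sum theta] with loadings
    lambda and uniquenesses theta. The interval is a nonparametric
    percentile bootstrap over respondents; pass ``bootstrap_reps=0`` to
    skip it.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 3:
        raise ValueError("mcdonald_omega needs a respondent x item matrix with >= 3 items")
    n, k = items.shape
    if n < 10 * k:
        warnings.warn(
            f"omega with n={n} < 10k={10 * k} respondents may be unstable",
            stacklevel=2,
        )
    om, converged, extraction = _omega_from_matrix(items)

    ci = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(bootstrap_reps)
        for b in range(bootstrap_reps):
            idx = rng.integers(0, n, size=n)
            try:
                boot[b], _, _ = _omega_from_matrix(items[idx])
            except ValueError:  # resample drew a constant item
                boot[b] = np.nan
        boot = boot[np.isfinite(boot)]
        a = (1 - level) / 2
        lo, hi = np.quantile(boot, [a, 1 - a])
        ci = IntervalEstimate(om, min(float(lo), om), max(float(hi), om), level, n)
    return ReliabilityResult(
        method="omega", estimate=om, k=k, ci=ci, converged=converged, extraction=extraction
    )


def eigen_screen(items: np.ndarray) -> EigenScreen:
    """Eigenvalues of the item correlation matrix and the Kaiser count (> 1)."""
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("eigen_screen needs a respondent x item matrix with >= 2 items")
    if np.any(items.std(axis=0) == 0):
        raise ValueError("eigen_screen undefined with a constant item")
    corr = np.corrcoef(items, rowvar=False)
    vals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return EigenScreen(
        eigenvalues=tuple(float(v) for v in vals),
        n_factors_kaiser=int(np.sum(vals > 1.0)),
    )


# ---------------------------------------------------------------------------
# Dataset-level wrappers


def _composite(dataset: ResponseDataset, spec: InstrumentSpec, items) -> np.ndarray:
    """Composite over ItemSpecs, honoring per-item reverse-code flags."""
    cols = []
    for it in items:
        col = dataset.column(it.item_id).astype(float)
        if it.reverse_coded:
            col = reverse_code(col, spec.scale)
        cols.append(col)
    return np.column_stack(cols).mean(axis=1)


def summarize_determinants(
    dataset: ResponseDataset, spec: InstrumentSpec, level: float = 0.95
) -> DeterminantSummary:
    """Build the CIBERlite data contract for one behavior.

    Per generic determinant: the unweighted composite mean, each
    subdeterminant item mean, and the Fisher-z CI for the Pearson
    correlation between the composite and the target item.
    """
    target_scores = dataset.column(spec.target.item_id).astype(float)
    blocks = []
    for label, items in spec.determinants:
        comp = _composite(dataset, spec, items)
        corr = correlation_ci(comp, target_scores, level=level)
        item_means = tuple(
            (
                it.subdeterminant,
                float(
                    (
                        reverse_code(dataset.column(it.item_id), spec.scale)
                        if it.reverse_coded
                        else dataset.column(it.item_id)
                    ).mean()
                ),
            )
            for it in items
        )
        blocks.append(
            DeterminantBlock(
                label=label,
                generic_mean=float(comp.mean()),
                item_means=item_means,
                correlation=corr,
            )
        )
    return DeterminantSummary(
        behavior_label=spec.behavior_label,
        scale=spec.scale,
        blocks=tuple(blocks),
        n=dataset.n,
    )


def compare_correlation_matrices(
    dataset_full: ResponseDataset,
    dataset_short: ResponseDataset,
    spec: InstrumentSpec,
    level: float = 0.99,
    spec_short: InstrumentSpec | None = None,
) -> list[QComparison]:
    """Cohen's Q for every construct pair, across two independent samples.

    Constructs are the target plus each generic-determinant composite.
    For k constructs this yields C(k, 2) comparisons. The two datasets
    must come from different respondents; passing the same data twice
    yields all-zero Q and triggers a warning.
    """
    spec_b = spec_short or spec
    if [l for l, _ in spec.determinants] != [l for l, _ in spec_b.determinants]:
        raise ValueError("determinant structure differs between the two instruments")

    def construct_scores(ds: ResponseDataset, sp: InstrumentSpec) -> dict[str, np.ndarray]:
        out = {sp.target.item_id: ds.column(sp.target.item_id).astype(float)}
        for label, items in sp.determinants:
            out[label] = _composite(ds, sp, items)
        return out

    a = construct_scores(dataset_full, spec)
    b = construct_scores(dataset_short, spec_b)
    names_a = list(a)
    names_b = list(b)

    if dataset_full.n == dataset_short.n and np.array_equal(
        dataset_full.scores, dataset_short.scores
    ):
        warnings.warn(
            "identical datasets passed twice: Q assumes independent samples",
            stacklevel=2,
        )

    out = []
    for (na, nb) in combinations(range(len(names_a)), 2):
        r1 = float(np.corrcoef(a[names_a[na]], a[names_a[nb]])[0, 1])
        r2 = float(np.corrcoef(b[names_b[na]], b[names_b[nb]])[0, 1])
        qc = cohens_q(r1, dataset_full.n, r2, dataset_short.n, level=level)
        out.append(
            QComparison(
                q=qc.q,
                ci=qc.ci,
                r1=r1,
                r2=r2,
                n1=dataset_full.n,
                n2=dataset_short.n,
                labels=(names_a[na], names_a[nb]),
            )
        )
    return out


@dataclass(frozen=True)
class ExpertAggregate:
    """Per-parameter mean and SD intervals over an expert panel."""

    table: pd.DataFrame  # behavior, determinant, n, mean interval, sd interval
    mean_of_sds: float
    level: float

    @property
    def n_cells(self) -> int:
        return len(self.table)


def aggregate_expert_estimates(
    estimates: ExpertEstimateSet, level: float = 0.95
) -> ExpertAggregate:
    """Mean (t interval) and SD (chi-square interval) per estimated parameter.

    Also reports the grand mean of the per-parameter SDs, the headline
    heterogeneity figure of an expert-estimation study.
    """
    if estimates.n_experts < 2:
        raise ValueError("need at least 2 experts")
    rows = []
    for j, (behavior, determinant) in enumerate(estimates.cells):
        col = estimates.values[:, j].astype(float)
        m = mean_ci(col, level=level)
        s = sd_ci(float(col.std(ddof=1)), col.size, level=level)
        rows.append(
            {
                "behavior": behavior,
                "determinant": determinant,
                "n": col.size,
                "mean": m.point,
                "mean_lower": m.lower,
                "mean_upper": m.upper,
                "sd": s.point,
                "sd_lower": s.lower,
                "sd_upper": s.upper,
            }
        )
    table = pd.DataFrame(rows)
    return ExpertAggregate(
        table=table, mean_of_sds=float(table["sd"].mean()), level=level
    )


# ---------------------------------------------------------------------------
# Serialization


def results_table(results: Sequence[object]) -> pd.DataFrame:
    """Flatten interval-bearing results into (statistic, point, lower, upper, level, n)."""
    rows = []
    for res in results:
        if isinstance(res, CorrelationResult):
            rows.append(("r", res.r, res.ci.lower, res.ci.upper, res.ci.level, res.n))
        elif isinstance(res, QComparison):
            name = "q" if res.labels is None else f"q[{res.labels[0]}-{res.labels[1]}]"
            rows.append((name, res.q, res.ci.lower, res.ci.upper, res.ci.level, min(res.n1, res.n2)))
        elif isinstance(res, ReliabilityResult):
            lo = res.ci.lower if res.ci else np.nan
            hi = res.ci.upper if res.ci else np.nan
            lvl = res.ci.level if res.ci else np.nan
            n = res.ci.n if res.ci else np.nan
            rows.append((res.method, res.estimate, lo, hi, lvl, n))
        elif isinstance(res, IntervalEstimate):
            rows.append(("estimate", res.point, res.lower, res.upper, res.level, res.n))
        else:
            raise TypeError(f"cannot serialize {type(res).__name__}")
    return pd.DataFrame(
        rows, columns=["statistic", "point", "lower", "upper", "level", "n"]
    )
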