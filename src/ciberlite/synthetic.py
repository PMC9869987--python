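"""Seed-controlled generators emulating lean determinant-study data.

Likert responses are generated from a latent multivariate normal: unit
standard deviation, a user-specified correlation matrix over the items
(determinant items plus the target), and per-item latent means
calibrated so that the *discretized* item means converge to the
requested targets. Discretization rounds to the nearest scale point
(fixed cut-points at half-integer boundaries) and attenuates
correlations; the attenuation is quantified by simulation rather than
corrected.

Expert estimates are normal draws per parameter, rounded and clamped
to the 1-5 response columns of an array question.

The coverage harness replays any of the package's four interval types
over thousands of seeded replicates and reports empirical coverage —
the backbone check that the interval machinery is trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .datamodel import ExpertEstimateSet, InstrumentSpec, LikertScale, ResponseDataset
from .estimators import correlation_ci, cohens_q, fisher_z, mean_ci, sd_ci

__all__ = [
    "BehaviorCondition",
    "SyntheticResponseSpec",
    "SyntheticExpertSpec",
    "CoverageResult",
    "raa_latent_corr",
    "simulate_responses",
    "simulate_expert_estimates",
    "coverage_experiment",
    "study_conditions_response_spec",
]


@dataclass(frozen=True)
class BehaviorCondition:
    """Latent generating model for one behavior's items.

    ``item_means`` maps every item id of the instrument (including the
    target) to a target mean in scale units; ``latent_corr`` is the
    correlation matrix over those items in instrument order.
    """

    label: str
    item_means: Mapping[str, float]
    latent_corr: np.ndarray


@dataclass(frozen=True)
class SyntheticResponseSpec:
    n_respondents: int
    instrument: InstrumentSpec
    behaviors: tuple[BehaviorCondition, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not self.behaviors:
            raise ValueError("need at least one behavior condition")


@dataclass(frozen=True)
class SyntheticExpertSpec:
    """Generating model for an expert-estimation panel."""

    n_experts: int
    cells: tuple[tuple[str, str], ...]  # (behavior, determinant)
    true_means: tuple[float, ...]
    sds: tuple[float, ...]
    seed: int = 0
    scale: LikertScale = field(default_factory=LikertScale)

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not (len(self.cells) == len(self.true_means) == len(self.sds)):
            raise ValueError("cells, true_means and sds must align")
        for m in self.true_means:
            if not self.scale.contains(m):
                raise ValueError(f"true mean {m} outside scale bounds")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be non-negative")


@dataclass(frozen=True)
class CoverageResult:
    statistic: str
    coverage: float
    mc_se: float  # binomial Monte-Carlo standard error
    replications: int
    level: float


# ---------------------------------------------------------------------------
# Latent-normal Likert responses


def _expected_discretized_mean(mu: float, scale: LikertScale) -> float:
    """Mean of clamp(round(N(mu, 1))) on the integer scale."""
    points = np.arange(scale.minimum, scale.maximum + 1)
    cuts = points[:-1] + 0.5
    cdf = stats.norm.cdf(cuts, loc=mu)
    probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    return float(points @ probs)


def _calibrate_latent_mean(target: float, scale: LikertScale) -> float:
    """Latent mean whose discretized expectation equals ``target``.

    Targets at (or numerically against) the scale bounds are infeasible:
    the discretized mean approaches the bound only as mu -> +/- inf.
    """
    eps = 1e-9
    if target <= scale.minimum + eps or target >= scale.maximum - eps:
        raise ValueError(
            f"target mean {target} infeasible at scale bound "
            f"[{scale.minimum}, {scale.maximum}] under a latent normal with sd 1"
        )
    lo, hi = scale.minimum - 10.0, scale.maximum + 10.0
    return float(brentq(lambda m: _expected_discretized_mean(m, scale) - target, lo, hi))


def _check_corr(matrix: np.ndarray, k: int) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (k, k):
        raise ValueError(f"latent correlation matrix must be {k}x{k}, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError("latent correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("latent correlation matrix must have unit diagonal")
    smallest = float(np.linalg.eigvalsh(m)[0])
    if smallest < -1e-10:
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {smallest:.3e})"
        )
    return m


def raa_latent_corr(
    instrument: InstrumentSpec,
    det_target_r: Mapping[str, float] | float = 0.4,
    within_det_r: float = 0.6,
    between_det_r: float = 0.2,
) -> np.ndarray:
    """Structured latent correlation matrix over an instrument's items.

    Items of the same determinant correlate at ``within_det_r``, items
    of different determinants at ``between_det_r``, and every
    determinant item with the target at that determinant's entry of
    ``det_target_r`` (a scalar applies to all determinants).
    """
    labels = []
    for det_label, items in instrument.determinants:
        labels.extend([(det_label, it.item_id) for it in items])
    k = len(labels) + 1
    m = np.full((k, k), between_det_r)
    for i, (di, _) in enumerate(labels):
        for j, (dj, _) in enumerate(labels):
            if i != j and di == dj:
                m[i, j] = within_det_r
    for i, (di, _) in enumerate(labels):
        r = det_target_r if np.isscalar(det_target_r) else det_target_r[di]
        m[i, -1] = m[-1, i] = r
    np.fill_diagonal(m, 1.0)
    return m


def simulate_responses(spec: SyntheticResponseSpec) -> ResponseDataset:
    """Draw a validated Likert dataset from the latent-normal model.

    One column per item per behavior; with a single behavior the
    columns are the bare item ids, otherwise ``{behavior}_{item}``.
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    item_ids = spec.instrument.item_ids
    k = len(item_ids)
    scale = spec.instrument.scale
    multi = len(spec.behaviors) > 1

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for cond in spec.behaviors:
        missing = [i for i in item_ids if i not in cond.item_means]
        if missing:
            raise ValueError(f"behavior {cond.label!r}: no target mean for {missing}")
        corr = _check_corr(cond.latent_corr, k)
        mus = np.array([_calibrate_latent_mean(cond.item_means[i], scale) for i in item_ids])
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        latent = rng.standard_normal((spec.n_respondents, k)) @ chol.T + mus
        scores = np.clip(np.rint(latent), scale.minimum, scale.maximum).astype(np.int64)
        blocks.append(scores)
        prefix = f"{cond.label}_" if multi else ""
        columns.extend(prefix + i for i in item_ids)

    return ResponseDataset(
        respondent_ids=[f"r{i + 1}" for i in range(spec.n_respondents)],
        columns=columns,
        scores=np.hstack(blocks),
        scale=scale,
    )


def study_conditions_response_spec(
    instrument: InstrumentSpec,
    n_respondents: int = 415,
    behaviors: Sequence[str] | None = None,
    low_mean: float = 2.0,
    high_mean: float = 4.0,
    target_mean: float = 3.0,
    det_target_r: float = 0.4,
    seed: int = 0,
) -> SyntheticResponseSpec:
    """A full 2x2x2 hi/lo design over eight behaviors.

    Each behavior sets each of the three determinants' item means to
    ``low_mean`` or ``high_mean`` according to its cell in the factorial
    layout — the structure of a proof-of-concept study crossing expected
    attitude, perceived norm, and perceived behavioral control.
    """
    det_labels = instrument.determinant_labels
    if len(det_labels) != 3:
        raise ValueError("the 2x2x2 layout needs exactly 3 determinants")
    cells = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    if behaviors is None:
        behaviors = [
            "".join(f"{d}{'hi' if bit else 'lo'}" for d, bit in zip(("att", "pn", "pbc"), cell))
            for cell in cells
        ]
    if len(behaviors) != 8:
        raise ValueError("need exactly 8 behavior labels for the 2x2x2 layout")
    corr = raa_latent_corr(instrument, det_target_r=det_target_r)
    conds = []
    for label, cell in zip(behaviors, cells):
        means = {}
        for det_label, bit in zip(det_labels, cell):
            for it in instrument.items_of(det_label):
                means[it.item_id] = high_mean if bit else low_mean
        means[instrument.target.item_id] = target_mean
        conds.append(BehaviorCondition(label=label, item_means=means, latent_corr=corr))
    return SyntheticResponseSpec(
        n_respondents=n_respondents,
        instrument=instrument,
        behaviors=tuple(conds),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Expert estimates


def simulate_expert_estimates(spec: SyntheticExpertSpec) -> ExpertEstimateSet:
    """Normal draws per parameter, rounded and clamped to the integer scale."""
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(
        loc=np.asarray(spec.true_means),
        scale=np.asarray(spec.sds),
        size=(spec.n_experts, len(spec.cells)),
    )
    values = np.clip(np.rint(raw), spec.scale.minimum, spec.scale.maximum).astype(np.int64)
    return ExpertEstimateSet(
        expert_ids=[f"e{i + 1}" for i in range(spec.n_experts)],
        cells=list(spec.cells),
        values=values,
        scale=spec.scale,
    )


# ---------------------------------------------------------------------------
# Coverage harness


def coverage_experiment(
    statistic: str,
    params: Mapping[str, float],
    level: float = 0.95,
    replications: int = 10_000,
    seed: int = 0,
) -> CoverageResult:
    """Empirical coverage of an interval estimator over seeded replicates.

    ``statistic`` is one of ``mean``, ``correlation``, ``sd``, ``q``;
    ``params`` carries the generating truth (``mu``/``sigma``/``n`` for
    mean and sd, ``rho``/``n`` for correlation, ``rho1``/``rho2``/
    ``n1``/``n2`` for q, which checks coverage of the true Fisher-z
    difference — zero under equal population correlations).
    """
    if replications < 1000:
        raise ValueError("coverage_experiment needs >= 1000 replications")
    rng = np.random.default_rng(seed)
    hits = 0

    if statistic == "mean":
        mu, sigma, n = params["mu"], params["sigma"], int(params["n"])
        for _ in range(replications):
            x = rng.normal(mu, sigma, size=n)
            hits += mean_ci(x, level=level).contains(mu)
    elif statistic == "sd":
        sigma, n = params["sigma"], int(params["n"])
        for _ in range(replications):
            x = rng.normal(0.0, sigma, size=n)
            hits += sd_ci(float(x.std(ddof=1)), n, level=level).contains(sigma)
    elif statistic == "correlation":
        rho, n = params["rho"], int(params["n"])
        mix = np.sqrt(1 - rho**2)
        for _ in range(replications):
            x = rng.standard_normal(n)
            y = rho * x + mix * rng.standard_normal(n)
            hits += correlation_ci(x, y, level=level).ci.contains(rho)
    elif statistic == "q":
        rho1, rho2 = params["rho1"], params["rho2"]
        n1, n2 = int(params["n1"]), int(params["n2"])
        truth = fisher_z(rho1) - fisher_z(rho2)
        mix1, mix2 = np.sqrt(1 - rho1**2), np.sqrt(1 - rho2**2)
        for _ in range(replications):
            x1 = rng.standard_normal(n1)
            y1 = rho1 * x1 + mix1 * rng.standard_normal(n1)
            x2 = rng.standard_normal(n2)
            y2 = rho2 * x2 + mix2 * rng.standard_normal(n2)
            r1 = float(np.corrcoef(x1, y1)[0, 1])
            r2 = float(np.corrcoef(x2, y2)[0, 1])
            hits += cohens_q(r1, n1, r2, n2, level=level).ci.contains(truth)
    else:
        raise ValueError(
            f"unknown statistic {statistic!r}; expected mean, correlation, sd or q"
        )

    p = hits / replications
    return CoverageResult(
        statistic=statistic,
        coverage=p,
        mc_se=float(np.sqrt(level * (1 - level) / replications)),
        replications=replications,
        level=level,
    )
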