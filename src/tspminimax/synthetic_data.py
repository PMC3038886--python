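"""Synthetic inputs: planted-pair expression cohorts and kernel-smooth truths.

Two generators:

* :func:`generate_cohort` builds an expression matrix with a handful of
  planted gene pairs whose intensity ordering flips between classes plus
  uninformative noise genes — an end-to-end pipeline fixture.
* :func:`generate_pk_alpha` builds a probability function of the form
  ``f(x) = alpha + (1 - alpha) f1(x) - alpha f2(x)`` with each ``f_l`` a
  positive Gaussian-kernel sum centered at the query and bounded in (0, 1),
  i.e. a member of the estimator's model class on every candidate
  neighborhood ball.  Bernoulli labels drawn from ``f`` feed bound-validity
  and interval-coverage simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionDataset
from .local_minimax import bandwidth_from_query, gaussian_kernel

_BASELINE = 100.0
_MARGIN_SD_MULTIPLE = 6.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted-pair cohort."""

    n_samples: int  # per class
    n_genes: int
    n_informative_pairs: int
    separation: float  # P(informative ordering holds in its favored class)
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one sample per class")
        if self.n_genes < 2 * self.n_informative_pairs:
            raise ValueError(
                "n_genes must be at least twice n_informative_pairs"
            )
        if not 0.5 < self.separation <= 1.0:
            raise ValueError("separation must lie in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionDataset, list[tuple[str, str]]]:
    """Generate a labeled cohort; returns (dataset, planted oriented pairs).

    Planted pair (a, b): ``P(a < b | class 0) = separation`` and
    ``P(a < b | class 1) = 1 - separation`` in expectation, realized by a
    margin well above the noise scale.  Remaining genes are i.i.d. noise
    around gene-specific baselines.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.n_samples
    N = 2 * n_per
    G = spec.n_genes
    labels = np.array([0] * n_per + [1] * n_per, dtype=int)
    margin = max(_MARGIN_SD_MULTIPLE * spec.noise_sd, 1.0)

    values = np.empty((G, N))
    baselines = rng.uniform(0.5 * _BASELINE, 1.5 * _BASELINE, size=G)
    for g in range(G):
        values[g] = baselines[g] + rng.normal(0.0, max(spec.noise_sd, 1e-12), size=N)

    planted: list[tuple[str, str]] = []
    gene_ids = [f"g{g:04d}" for g in range(G)]
    for p in range(spec.n_informative_pairs):
        ia, ib = 2 * p, 2 * p + 1
        planted.append((gene_ids[ia], gene_ids[ib]))
        base = baselines[ia]
        for j in range(N):
            favored = spec.separation if labels[j] == 0 else 1.0 - spec.separation
            a_below = rng.random() < favored
            # large shared shift keeps each gene individually uninformative;
            # only the within-pair ordering carries class signal
            shared = rng.normal(0.0, 8.0 * margin)
            lo = base + shared - margin + rng.normal(0.0, spec.noise_sd)
            hi = base + shared + margin + rng.normal(0.0, spec.noise_sd)
            if a_below:
                values[ia, j], values[ib, j] = lo, hi
            else:
                values[ia, j], values[ib, j] = hi, lo

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=[f"s{j:04d}" for j in range(N)],
        values=values,
        labels=labels,
    )
    return dataset, planted


@dataclass(frozen=True)
class ProbabilityScenario:
    """A synthetic truth inside the estimator's model class.

    ``f(x) = alpha + (1 - alpha) f1(x) - alpha f2(x)``, with
    ``f_l(x) = a_l K(query, x)`` (single kernel center at the query), so
    ``f`` lies in the class for every ball about the query, and
    ``f(query) = alpha + (1 - alpha) a1 - alpha a2``.
    """

    train_features: np.ndarray
    query: np.ndarray
    alpha: float
    sigma: float
    f1_coefficients: tuple[float, ...]
    f2_coefficients: tuple[float, ...]
    true_probability_at_query: float
    f_train: np.ndarray  # f evaluated at each training point
    seed: int

    def f(self, x) -> float:
        """Evaluate the truth at an arbitrary point."""
        kq = gaussian_kernel(self.query, x, self.sigma)
        f1 = sum(self.f1_coefficients) * kq
        f2 = sum(self.f2_coefficients) * kq
        return self.alpha + (1.0 - self.alpha) * f1 - self.alpha * f2

    @property
    def rkhs_norm_from_alpha(self) -> float:
        """RKHS norm of f - alpha, exact for single-center sums."""
        a = sum(self.f1_coefficients)
        b = sum(self.f2_coefficients)
        al = self.alpha
        sq = (1 - al) ** 2 * a**2 + al**2 * b**2 - 2 * al * (1 - al) * a * b
        return math.sqrt(max(sq, 0.0))


def generate_pk_alpha(
    n_train: int,
    k_dims: int,
    alpha: float,
    sigma_fraction: float,
    seed: int,
    coefficients: tuple[float, float] | None = None,
) -> ProbabilityScenario:
    """Sample geometry and a class-member truth tied to the estimator's sigma.

    The bandwidth is derived from the same fraction-of-furthest-distance rule
    the estimator applies, so the truth lives in the reproducing-kernel space
    the estimator assumes.  ``coefficients`` optionally pins the kernel-sum
    amplitudes (each must lie in (0, 1); zero is allowed and collapses that
    component, making ``f`` closer to the constant ``alpha``).
    """
    if n_train < 1:
        raise ValueError("n_train must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train = rng.normal(0.0, 1.0, size=(n_train, k_dims))
    query = rng.normal(0.0, 1.0, size=k_dims)
    sigma = bandwidth_from_query(query, train, sigma_fraction)
    if coefficients is None:
        a1, a2 = rng.uniform(0.05, 0.95, size=2)
    else:
        a1, a2 = coefficients
        if not (0 <= a1 < 1 and 0 <= a2 < 1):
            raise ValueError("coefficients must lie in [0, 1)")
    f0 = alpha + (1.0 - alpha) * a1 - alpha * a2
    scenario = ProbabilityScenario(
        train_features=train,
        query=query,
        alpha=float(alpha),
        sigma=float(sigma),
        f1_coefficients=(float(a1),),
        f2_coefficients=(float(a2),),
        true_probability_at_query=float(f0),
        f_train=np.empty(0),
        seed=seed,
    )
    f_train = np.array([scenario.f(x) for x in train])
    object.__setattr__(scenario, "f_train", f_train)
    if not ((0.0 <= f_train) & (f_train <= 1.0)).all():
        raise AssertionError("generated truth left [0, 1]")  # pragma: no cover
    return scenario


def simulate_labels(
    scenario: ProbabilityScenario, n_replicates: int, seed: int
) -> np.ndarray:
    """Independent Bernoulli(f(x_j)) label draws, (n_replicates x N)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    rng = np.random.default_rng(seed)
    probs = np.asarray(scenario.f_train, dtype=float)
    u = rng.random(size=(n_replicates, probs.shape[0]))
    return (u < probs[None, :]).astype(int)
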