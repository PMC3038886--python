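"""k-Top-Scoring-Pairs feature selection and the pair-difference transform.

A gene pair is scored by the between-class difference of the relative
frequency that one gene's intensity falls below the other's (the delta
score); ties are broken by a rank-based score (gamma) and then
lexicographically by gene ids.  The selected model maps a sample to the
vector of intensity differences over its k disjoint pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .expression_io import ExpressionDataset


class SelectionError(ValueError):
    """Raised when feature selection preconditions fail."""


@dataclass(frozen=True)
class GenePair:
    """An oriented gene pair with its scores.

    ``p0``/``p1`` are the relative frequencies of ``value_a < value_b``
    within class 0 / class 1; ``delta = |p0 - p1|``.  The stored orientation
    maximizes ``p0 - p1`` so the feature ``a - b`` tends to be larger in
    class 1.
    """

    gene_a: str
    gene_b: str
    delta: float
    gamma: float
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a pair must use two distinct genes")


@dataclass(frozen=True)
class TSPModel:
    """An ordered list of k disjoint, oriented gene pairs."""

    pairs: tuple[GenePair, ...]

    def __post_init__(self) -> None:
        used: set[str] = set()
        for pair in self.pairs:
            if pair.gene_a in used or pair.gene_b in used:
                raise ValueError("pairs must be gene-disjoint")
            used.update((pair.gene_a, pair.gene_b))

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for pair in self.pairs:
            out.extend((pair.gene_a, pair.gene_b))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "pairs": [
                    {
                        "gene_a": p.gene_a,
                        "gene_b": p.gene_b,
                        "delta": p.delta,
                        "gamma": p.gamma,
                        "p0": p.p0,
                        "p1": p.p1,
                    }
                    for p in self.pairs
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TSPModel":
        doc = json.loads(text)
        pairs = tuple(GenePair(**entry) for entry in doc["pairs"])
        if doc.get("k") is not None and doc["k"] != len(pairs):
            raise ValueError("declared k does not match pair count")
        return cls(pairs=pairs)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-sample pair-difference features (N samples x k pairs)."""

    sample_ids: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample ids")


def _class_masks(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    if dataset.labels is None:
        raise SelectionError("dataset has no labels; join labels first")
    mask0 = dataset.labels == 0
    mask1 = dataset.labels == 1
    if not mask0.any() or not mask1.any():
        raise SelectionError("both classes must be present for selection")
    return mask0, mask1


def pair_score(
    dataset: ExpressionDataset, gene_a: str, gene_b: str
) -> tuple[float, float, float]:
    """Return ``(delta, p0, p1)`` for the oriented pair ``(gene_a, gene_b)``.

    ``p_c`` counts strict inequalities ``value_a < value_b`` within class
    ``c``; equal values count as "not less".
    """
    mask0, mask1 = _class_masks(dataset)
    a = dataset.values[dataset.gene_index(gene_a)]
    b = dataset.values[dataset.gene_index(gene_b)]
    less = a < b
    p0 = float(less[mask0].mean())
    p1 = float(less[mask1].mean())
    return abs(p0 - p1), p0, p1


def rank_tiebreak_score(
    dataset: ExpressionDataset, gene_a: str, gene_b: str
) -> float:
    """Gamma: between-class absolute difference of mean rank differences.

    Each gene's N intensities are replaced by their ranks across the N
    patients (average ranks on ties); ``d = rank_a - rank_b`` per patient.
    """
    mask0, mask1 = _class_masks(dataset)
    # doubled average ranks are exact integers; the score is a ratio of
    # integers, so equal scores compare equal and ties break reproducibly
    ra2 = np.rint(2.0 * rankdata(dataset.values[dataset.gene_index(gene_a)])).astype(np.int64)
    rb2 = np.rint(2.0 * rankdata(dataset.values[dataset.gene_index(gene_b)])).astype(np.int64)
    d = ra2 - rb2
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    num = abs(int(d[mask0].sum()) * n1 - int(d[mask1].sum()) * n0)
    return num / (2.0 * n0 * n1)


def _score_all_pairs(dataset: ExpressionDataset):
    """Score every unordered pair; yields oriented candidate tuples.

    Returns a list sorted by (delta desc, gamma desc, (gene_a, gene_b) asc).
    """
    mask0, mask1 = _class_masks(dataset)
    X = dataset.values
    G = dataset.n_genes
    # integer-exact rank scores: gamma(a, b) = |T_a - T_b| / (2 n0 n1) with
    # T_g an integer, so ties are exact and the sort is reproducible
    ranks2 = np.rint(2.0 * np.apply_along_axis(rankdata, 1, X)).astype(np.int64)
    n0, n1 = int(mask0.sum()), int(mask1.sum())
    T = ranks2[:, mask0].sum(axis=1) * n1 - ranks2[:, mask1].sum(axis=1) * n0

    # C_c[i, j] = count of samples in class c with value_i < value_j
    C0 = np.empty((G, G), dtype=np.int64)
    C1 = np.empty((G, G), dtype=np.int64)
    block = 128
    for start in range(0, G, block):
        stop = min(start + block, G)
        less = X[start:stop, None, :] < X[None, :, :]  # (block, G, N)
        C0[start:stop] = less[:, :, mask0].sum(axis=2)
        C1[start:stop] = less[:, :, mask1].sum(axis=2)

    candidates = []
    for i in range(G):
        for j in range(i + 1, G):
            # orientation maximizing p0 - p1, compared in exact integers
            fwd = int(C0[i, j]) * n1 - int(C1[i, j]) * n0
            rev = int(C0[j, i]) * n1 - int(C1[j, i]) * n0
            if fwd > rev:
                a, b = i, j
            elif rev > fwd:
                a, b = j, i
            else:  # orientation tie: deterministic lexicographic choice
                a, b = sorted((i, j), key=lambda g: dataset.gene_ids[g])
            p0 = int(C0[a, b]) / n0
            p1 = int(C1[a, b]) / n1
            # sort keys are integers (delta and gamma numerators over the
            # common denominators), so equal scores tie exactly
            delta_key = abs(int(C0[a, b]) * n1 - int(C1[a, b]) * n0)
            gamma_key = abs(int(T[a]) - int(T[b]))
            candidates.append(
                (
                    delta_key,
                    gamma_key,
                    dataset.gene_ids[a],
                    dataset.gene_ids[b],
                    p0,
                    p1,
                )
            )
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    denom = 2.0 * n0 * n1
    return [
        (abs(p0 - p1), gk / denom, ga, gb, p0, p1)
        for dk, gk, ga, gb, p0, p1 in candidates
    ]


def select_top_k_disjoint(dataset: ExpressionDataset, k: int) -> TSPModel:
    """Select the top k gene-disjoint pairs by (delta, gamma, lexicographic).

    Greedy scan over the fully sorted candidate list: a pair is taken iff
    neither of its genes already appears in an accepted pair.
    """
    if k < 1:
        raise SelectionError("k must be at least 1")
    if dataset.n_genes < 2 * k:
        raise SelectionError(
            f"need at least {2 * k} genes for {k} disjoint pairs, "
            f"have {dataset.n_genes}"
        )
    candidates = _score_all_pairs(dataset)
    chosen: list[GenePair] = []
    used: set[str] = set()
    for delta, gamma, ga, gb, p0, p1 in candidates:
        if ga in used or gb in used:
            continue
        chosen.append(
            GenePair(gene_a=ga, gene_b=gb, delta=float(delta),
                     gamma=float(gamma), p0=p0, p1=p1)
        )
        used.update((ga, gb))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise SelectionError(
            f"only {len(chosen)} disjoint pairs available, {k} requested"
        )
    return TSPModel(pairs=tuple(chosen))


def transform(
    sample_values: Mapping[str, float], model: TSPModel
) -> np.ndarray:
    """Map one sample to its length-k pair-difference feature vector."""
    out = np.empty(model.k, dtype=float)
    for t, pair in enumerate(model.pairs):
        for gene in (pair.gene_a, pair.gene_b):
            if gene not in sample_values:
                raise KeyError(f"sample lacks gene {gene!r} required by the model")
        out[t] = sample_values[pair.gene_a] - sample_values[pair.gene_b]
    return out


def feature_matrix(dataset: ExpressionDataset, model: TSPModel) -> FeatureMatrix:
    """Apply the pair-difference transform to every sample of a dataset."""
    idx_a = [dataset.gene_index(p.gene_a) for p in model.pairs]
    idx_b = [dataset.gene_index(p.gene_b) for p in model.pairs]
    vectors = (dataset.values[idx_a, :] - dataset.values[idx_b, :]).T
    return FeatureMatrix(sample_ids=tuple(dataset.sample_ids), vectors=vectors)
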