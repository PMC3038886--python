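"""3-nearest-neighbor baseline with an asymptotic confident-predictability rule.

The call is the majority label of the nearest neighbors in the pair-difference
feature space; the prediction is flagged confidently predictable only when all
neighbors agree.  The rule's justification is asymptotic and assumes the true
probability of cancer is at most 0.30 or at least 0.70 for every patient; this
is documented, not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KnnPrediction:
    class_call: int
    cp_flag: bool
    neighbor_labels: tuple[int, ...]


def knn_predict(query, train_features, train_labels, n_neighbors: int = 3) -> KnnPrediction:
    """Majority vote of the nearest ``n_neighbors``; CP iff unanimous.

    ``n_neighbors`` must be odd so the majority is always defined; distance
    ties are broken by the lowest training index.
    """
    if n_neighbors % 2 == 0:
        raise ValueError("n_neighbors must be odd")
    query = np.asarray(query, dtype=float)
    train = np.atleast_2d(np.asarray(train_features, dtype=float))
    labels = np.asarray(train_labels, dtype=int)
    if train.shape[0] < n_neighbors:
        raise ValueError(
            f"need at least {n_neighbors} training points, have {train.shape[0]}"
        )
    dists = np.linalg.norm(train - query, axis=1)
    order = np.argsort(dists, kind="stable")[:n_neighbors]
    votes = labels[order]
    call = int(votes.sum() * 2 > n_neighbors)
    return KnnPrediction(
        class_call=call,
        cp_flag=bool((votes == votes[0]).all()),
        neighbor_labels=tuple(int(v) for v in votes),
    )
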