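"""Independent pure-Python reference implementations used only by tests."""

from __future__ import annotations


def _average_ranks(row):
    """Ranks 1..N across the row, average ranks on ties."""
    n = len(row)
    order = sorted(range(n), key=lambda j: row[j])
    ranks = [0.0] * n
    j = 0
    while j < n:
        m = j
        while m + 1 < n and row[order[m + 1]] == row[order[j]]:
            m += 1
        shared = (j + m) / 2.0 + 1.0
        for t in range(j, m + 1):
            ranks[order[t]] = shared
        j = m + 1
    return ranks


def brute_force_ktsp(gene_ids, values, labels, k):
    """Exhaustive pair scoring + greedy disjoint selection, loops only.

    Returns the ordered selected list of
    (gene_a, gene_b, delta, gamma, p0, p1) tuples, mirroring the documented
    conventions: strict-inequality frequencies, per-gene ranks across
    patients, orientation maximizing p0 - p1 (lexicographic on ties),
    candidate order (delta desc, gamma desc, id pair asc).
    """
    n_genes = len(gene_ids)
    n = len(labels)
    idx0 = [j for j in range(n) if labels[j] == 0]
    idx1 = [j for j in range(n) if labels[j] == 1]
    assert idx0 and idx1

    n0, n1 = len(idx0), len(idx1)

    def count_less(a, b, idx):
        return sum(1 for j in idx if values[a][j] < values[b][j])

    # doubled average ranks are integers; scores compare as exact integers
    ranks2 = [
        [int(round(2.0 * r)) for r in _average_ranks(values[g])]
        for g in range(n_genes)
    ]
    T = [
        sum(ranks2[g][m] for m in idx0) * n1 - sum(ranks2[g][m] for m in idx1) * n0
        for g in range(n_genes)
    ]

    candidates = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            fwd = count_less(i, j, idx0) * n1 - count_less(i, j, idx1) * n0
            rev = count_less(j, i, idx0) * n1 - count_less(j, i, idx1) * n0
            if fwd > rev:
                a, b = i, j
            elif rev > fwd:
                a, b = j, i
            else:
                a, b = sorted((i, j), key=lambda g: gene_ids[g])
            c0 = count_less(a, b, idx0)
            c1 = count_less(a, b, idx1)
            delta_key = abs(c0 * n1 - c1 * n0)
            gamma_key = abs(T[a] - T[b])
            candidates.append(
                (delta_key, gamma_key, gene_ids[a], gene_ids[b], c0 / n0, c1 / n1)
            )
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    candidates = [
        (abs(p0 - p1), gk / (2.0 * n0 * n1), ga, gb, p0, p1)
        for dk, gk, ga, gb, p0, p1 in candidates
    ]

    chosen = []
    used = set()
    for delta, gamma, ga, gb, p0, p1 in candidates:
        if ga in used or gb in used:
            continue
        chosen.append((ga, gb, delta, gamma, p0, p1))
        used.update((ga, gb))
        if len(chosen) == k:
            break
    return chosen
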