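"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the implementation paths they check: the Ward
oracle recomputes every candidate merge cost from raw points and cluster
means at every step (no Lance-Williams recurrence), and the AUC oracle
counts ordered pairs directly.
"""

import numpy as np


def brute_force_auc(case, control) -> float:
    wins = sum(1.0 for c in case for k in control if c > k)
    ties = sum(1.0 for c in case for k in control if c == k)
    return (wins + 0.5 * ties) / (len(case) * len(control))


def ward_oracle(points: np.ndarray):
    """Exhaustive Ward.D2 agglomeration from raw points.

    The Ward.D2 distance between clusters A and B is
    sqrt(2|A||B|/(|A|+|B|)) * ||mean(A) - mean(B)||, recomputed from the raw
    points for every active pair at every step; ties break on the smallest
    (left id, right id) pair in cluster-creation order.  Returns a scipy-style
    merge array (left, right, height, size).
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(clusters)
        best = (np.inf, None, None)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                ma = x[clusters[a]].mean(axis=0)
                mb = x[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d = np.sqrt(
                    2.0 * na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
                )
                if d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges[step] = (a, b, d, len(clusters[a]) + len(clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges
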