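"""Independent brute-force oracles shared by the acceptance suite."""


def brute_bh(p):
    """Textbook Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0)
    return q


def brute_linkage(d, n, method):
    """Naive O(n^3) agglomerative clustering; returns sorted merge heights."""
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        new_dist = {}
        for k, members in clusters.items():
            pair = [d[a, b] for a in merged for b in members]
            if method == "complete":
                nd = max(pair)
            elif method == "single":
                nd = min(pair)
            else:
                nd = sum(pair) / len(pair)
            new_dist[(min(k, next_id), max(k, next_id))] = nd
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    return sorted(heights)
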