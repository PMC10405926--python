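"""Independent brute-force oracles used to validate the implementation.

Everything here is written deliberately as naive enumeration over plain
Python data structures, sharing no code path with the package.
"""

from __future__ import annotations

from itertools import combinations

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_THRESHOLDS = {"species": 95.0, "genus": 85.0, "phylum": 65.0}


def oracle_assign(hits, score_fraction=0.9, consensus_fraction=0.5,
                  min_identity=65.0, min_coverage=80.0):
    """Brute-force consensus/LCA assignment.

    ``hits`` is a list of dicts with keys identity, coverage, bitscore,
    lineage (a tuple of labels). Returns the assigned lineage tuple.
    """
    floor = [h for h in hits if h["identity"] >= min_identity and h["coverage"] >= min_coverage]
    if not floor:
        return ()
    best = max(h["bitscore"] for h in floor)
    retained = [h for h in floor if h["bitscore"] >= score_fraction * best]
    n = len(retained)
    for rank in ("species", "genus", "phylum"):
        ri = RANKS.index(rank)
        threshold = RANK_THRESHOLDS[rank]
        # enumerate every label seen at this rank and test the consensus
        # condition directly
        labels = set()
        for h in retained:
            if len(h["lineage"]) > ri and h["identity"] >= threshold:
                labels.add(h["lineage"][ri])
        winners = []
        for lab in labels:
            count = sum(
                1
                for h in retained
                if len(h["lineage"]) > ri
                and h["identity"] >= threshold
                and h["lineage"][ri] == lab
            )
            if count / n >= consensus_fraction:
                winners.append(lab)
        if len(winners) == 1:
            lab = winners[0]
            prefixes = sorted(
                h["lineage"][: ri + 1]
                for h in retained
                if len(h["lineage"]) > ri
                and h["identity"] >= threshold
                and h["lineage"][ri] == lab
            )
            best_count = max(prefixes.count(p) for p in prefixes)
            return min(p for p in prefixes if prefixes.count(p) == best_count)
    # LCA of all retained lineages
    lca = []
    for i in range(min(len(h["lineage"]) for h in retained)):
        labs = {h["lineage"][i] for h in retained}
        if len(labs) == 1:
            lca.append(labs.pop())
        else:
            break
    return tuple(lca)


def oracle_exact_wilcoxon_p(x, y):
    """Two-sided exact rank-sum p by full enumeration (tie-free data)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    u_hi = max(u_obs, n1 * n2 - u_obs)
    total = 0
    extreme = 0
    all_ranks = list(range(1, n1 + n2 + 1))
    for combo in combinations(all_ranks, n1):
        total += 1
        u = sum(combo) - n1 * (n1 + 1) / 2
        if u >= u_hi:
            extreme += 1
    return min(1.0, 2 * extreme / total)


def oracle_bh(p_values):
    """One-pass BH: q_(i) = min_{j>=i} (m/j) p_(j), clipped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p_values[i] * m / (pos + 1))
        q[i] = running
    return q


def oracle_select_features(ks, means, sds):
    """Independent one-pass error-curve selection rule."""
    i_star = 0
    for i in range(1, len(ks)):
        if means[i] < means[i_star]:
            i_star = i
    cutoff = means[i_star] + sds[i_star]
    candidates = [k for k, m in zip(ks, means) if m < cutoff]
    chosen = min(candidates) if candidates else ks[i_star]
    return cutoff, candidates, chosen


def oracle_auc(scores, labels):
    """AUC by exhaustive concordant-pair counting (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
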