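"""Independent brute-force oracles used by the test suite.

Deliberately written with plain Python loops and math.erf so they share no
code path with the vectorised implementations they check.
"""

import math


def phi(t):
    return 0.5 * (1.0 + math.erf(t / math.sqrt(2.0)))


def gsva_bruteforce(values, scale="tpm", tau=1.0):
    """Per-unit GSVA enrichment scores as a function of the in-set mask.

    values: list of rows (genes) of per-unit expression.
    Returns a function in_set_mask -> list of per-unit scores.
    """
    n_genes = len(values)
    n_units = len(values[0])
    if scale in ("tpm", "counts"):
        x = [[math.log2(v + 1.0) for v in row] for row in values]
    else:
        x = [list(row) for row in values]
    # Gaussian-kernel CDF statistic, bandwidth sd/4 floored at 1e-8
    z = []
    for row in x:
        mean = sum(row) / n_units
        var = sum((v - mean) ** 2 for v in row) / (n_units - 1)
        h = max(math.sqrt(var) / 4.0, 1e-8)
        z.append([sum(phi((v - w) / h) for w in row) for v in row])

    def score(in_set):
        out = []
        for j in range(n_units):
            stat = [z[i][j] for i in range(n_genes)]
            # decreasing order, stable in input gene order on ties
            order = sorted(range(n_genes), key=lambda i: (-stat[i], i))
            rank = {g: k + 1 for k, g in enumerate(order)}
            weight = {g: abs(rank[g] - (n_genes + 1) / 2.0) ** tau for g in range(n_genes)}
            w_tot = sum(weight[g] for g in range(n_genes) if in_set[g])
            n_out = n_genes - sum(in_set)
            walk = [0.0]
            for g in order:
                if in_set[g]:
                    step = weight[g] / w_tot if w_tot > 0 else 0.0
                else:
                    step = -1.0 / n_out if n_out > 0 else 0.0
                walk.append(walk[-1] + step)
            out.append(max(walk) + min(walk))
        return out

    return score


def aucell_bruteforce(values, in_set, top_fraction):
    """Per-unit AUCell recovery-curve scores by direct enumeration."""
    n_genes = len(values)
    n_units = len(values[0])
    k = math.ceil(top_fraction * n_genes)
    n_set = sum(in_set)
    # maximal step-sum: all in-set genes at the very top
    best = 0
    hits = 0
    for i in range(k):
        if i < n_set:
            hits += 1
        best += hits
    out = []
    for j in range(n_units):
        order = sorted(range(n_genes), key=lambda i: (-values[i][j], i))
        auc = 0
        hits = 0
        for i in range(k):
            if in_set[order[i]]:
                hits += 1
            auc += hits
        out.append(auc / best)
    return out


def fisher_two_sided_bruteforce(both, a_only, b_only, neither):
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    n = both + a_only + b_only + neither
    row1 = both + a_only
    col1 = both + b_only

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(both)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))
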