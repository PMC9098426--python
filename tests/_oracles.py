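"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (exhaustive
enumeration, direct formula evaluation, naive nested loops) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive pairwise local-event pattern matcher


def _overlap(x, y):
    return max(x[0], y[0]) < min(x[1], y[1])


def oracle_gene_events(gene) -> set[tuple[str, str]]:
    """All (event_type, coordinate-string) pairs supported by any
    transcript pair of the gene, checking every pair against each of the
    seven patterns literally."""
    out: set[tuple[str, str]] = set()
    txs = []
    for t in gene.transcripts.values():
        exons = sorted(t.exons)
        juncs = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
        txs.append((exons, juncs))
    strand = gene.strand
    for (ex1, j1), (ex2, j2) in itertools.permutations(txs, 2):
        # SE: internal exon of form 1 skipped by a junction of form 2
        for i in range(1, len(ex1) - 1):
            a, (b, c), d = ex1[i - 1][1], ex1[i], ex1[i + 1][0]
            if (a, d) in j2:
                out.add(("SE", f"{a}-{b}:{c}-{d}"))
        # RI: junction of form 1 inside a single exon of form 2
        for i, (a, b) in enumerate(j1):
            s, e = ex1[i][0], ex1[i + 1][1]
            if (s, e) in ex2:
                out.add(("RI", f"{s}:{a}-{b}:{e}"))
        # A5/A3: shared endpoint, alternative boundary, overlapping exons
        for k1, (d1, a1) in enumerate(j1):
            for k2, (d2, a2) in enumerate(j2):
                if a1 == a2 and d1 != d2 and _overlap(ex1[k1], ex2[k2]):
                    dlo, dhi = sorted((d1, d2))
                    et = "A5" if strand == "+" else "A3"
                    out.add((et, f"{dhi}-{a1}:{dlo}-{a1}"))
                if d1 == d2 and a1 != a2 and _overlap(ex1[k1 + 1], ex2[k2 + 1]):
                    alo, ahi = sorted((a1, a2))
                    et = "A3" if strand == "+" else "A5"
                    out.add((et, f"{d1}-{alo}:{d1}-{ahi}"))
        # MX: two internal exons, shared flanks, mutually exclusive
        for i in range(1, len(ex1) - 1):
            for j in range(1, len(ex2) - 1):
                a1, e1i, d1 = ex1[i - 1][1], ex1[i], ex1[i + 1][0]
                a2, e2j, d2 = ex2[j - 1][1], ex2[j], ex2[j + 1][0]
                if a1 == a2 and d1 == d2 and e1i != e2j and not _overlap(e1i, e2j):
                    (bl, cl), (br, cr) = sorted([e1i, e2j])
                    out.add(("MX", f"{a1}-{bl}:{cl}-{d1}:{a1}-{br}:{cr}-{d1}"))
        # AF / AL: alternative, non-overlapping terminal exons
        if len(ex1) >= 2 and len(ex2) >= 2:
            if strand == "+":
                f1, sh1 = ex1[0], ex1[1][0]
                f2, sh2 = ex2[0], ex2[1][0]
            else:
                f1, sh1 = ex1[-1], ex1[-2][1]
                f2, sh2 = ex2[-1], ex2[-2][1]
            if sh1 == sh2 and f1 != f2 and not _overlap(f1, f2):
                exd, exp = sorted((f1, f2))
                if strand == "-":
                    exd, exp = exp, exd
                out.add(("AF", f"{exd[0]}-{exd[1]}:{exp[0]}-{exp[1]}:{sh1}"))
            if strand == "+":
                l1, sh1 = ex1[-1], ex1[-2][1]
                l2, sh2 = ex2[-1], ex2[-2][1]
            else:
                l1, sh1 = ex1[0], ex1[1][0]
                l2, sh2 = ex2[0], ex2[1][0]
            if sh1 == sh2 and l1 != l2 and not _overlap(l1, l2):
                exp, exd = sorted((l1, l2))
                if strand == "-":
                    exp, exd = exd, exp
                out.add(("AL", f"{exd[0]}-{exd[1]}:{exp[0]}-{exp[1]}:{sh1}"))
    return out


def event_coords(event) -> tuple[str, str]:
    """(event_type, coordinate string) parsed from a LocalEvent id."""
    body = event.event_id.split(";", 1)[1]  # TYPE:chrom:coords:strand
    parts = body.split(":")
    return parts[0], ":".join(parts[2:-1])


# ---------------------------------------------------------------------------
# rank statistics


def oracle_exhaustive_umbrella_p(values, groups) -> float:
    """Exact permutation p: enumerate every assignment of values.

    Specialized to one sample per phase group; the circular Mack-Wolfe
    maximum is recomputed for every permutation with plain pairwise
    comparisons (vectorized across the enumeration only)."""
    k = max(groups) + 1
    assert sorted(groups) == list(range(k)), "one sample per group expected"
    perms = np.array(list(itertools.permutations(values)))
    comp = (perms[:, :, None] < perms[:, None, :]) + 0.5 * (
        perms[:, :, None] == perms[:, None, :]
    )
    best = np.full(perms.shape[0], -np.inf)
    for p in range(k):
        start = (p + k // 2 + 1) % k
        order = [(start + i) % k for i in range(k)]
        q = order.index(p)
        a_stat = np.zeros(perms.shape[0])
        n_pairs = 0
        for i in range(k):
            for j in range(i + 1, k):
                if j <= q:
                    a_stat += comp[:, groups.index(order[i]), groups.index(order[j])]
                    n_pairs += 1
                elif i >= q:
                    a_stat += comp[:, groups.index(order[j]), groups.index(order[i])]
                    n_pairs += 1
        # null moments for one observation per group (tie-free formulas)
        n1, n2 = q + 1, k - q
        mu = (n1**2 + n2**2 - k - 1) / 4.0
        var = (
            2 * (n1**3 + n2**3) + 3 * (n1**2 + n2**2) - 5 * k - 5
            + 12 * n1 * n2 - 12 * k
        ) / 72.0
        best = np.maximum(best, (a_stat - mu) / np.sqrt(var))
    obs = _oracle_stat_single(values, groups, k)
    return float(np.mean(best >= obs - 1e-12))


def _oracle_stat_single(values, groups, k) -> float:
    vals = np.array(values, float)
    comp = (vals[:, None] < vals[None, :]) + 0.5 * (vals[:, None] == vals[None, :])
    np.fill_diagonal(comp, 0.0)
    best = -np.inf
    for p in range(k):
        start = (p + k // 2 + 1) % k
        order = [(start + i) % k for i in range(k)]
        q = order.index(p)
        a_stat = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                if j <= q:
                    a_stat += comp[groups.index(order[i]), groups.index(order[j])]
                elif i >= q:
                    a_stat += comp[groups.index(order[j]), groups.index(order[i])]
        n1, n2 = q + 1, k - q
        mu = (n1**2 + n2**2 - k - 1) / 4.0
        var = (
            2 * (n1**3 + n2**3) + 3 * (n1**2 + n2**2) - 5 * k - 5
            + 12 * n1 * n2 - 12 * k
        ) / 72.0
        best = max(best, (a_stat - mu) / np.sqrt(var))
    return best


def oracle_mannwhitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = pooled[[i for i in idx if i not in set(ix)]]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(idx, n1)]
    n_tot = len(us)
    ge = sum(u >= u_obs for u in us)
    le = sum(u <= u_obs for u in us)
    return min(1.0, 2.0 * min(ge, le) / n_tot)


def oracle_hypergeom_p(n_universe, set_size, query_size, k) -> float:
    """P(overlap >= k) by exhaustive enumeration of query subsets."""
    universe = range(n_universe)
    members = set(range(set_size))
    total = 0
    hit = 0
    for query in itertools.combinations(universe, query_size):
        total += 1
        hit += len(members & set(query)) >= k
    return hit / total


def oracle_cosinor_gridsearch(values, times, period=24.0):
    """Dense grid + local refinement least squares over acrophase."""
    from scipy.optimize import minimize_scalar

    y = np.asarray(values, float)
    t = np.asarray(times, float)
    w = 2 * np.pi / period

    def rss_at(phi):
        x = np.column_stack([np.ones_like(t), np.cos(w * (t - phi))])
        beta, res, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r), beta

    grid = np.arange(0, period, 0.01)
    rss = [rss_at(p)[0] for p in grid]
    p0 = grid[int(np.argmin(rss))]
    opt = minimize_scalar(
        lambda p: rss_at(p)[0], bracket=(p0 - 0.02, p0, p0 + 0.02), method="brent",
        options={"xtol": 1e-12},
    )
    phi = float(opt.x) % period
    _, (m, a) = rss_at(phi)
    if a < 0:  # amplitude sign flip = half-period phase shift
        a, phi = -a, (phi + period / 2) % period
    return float(m), float(a), phi
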