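"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exact rational
arithmetic, exhaustive scans) and shares no code with the package.
"""

import math
from fractions import Fraction

import numpy as np


def pearson_r2_naive(x, y):
    """Pearson r^2 from raw sums, no numpy statistics helpers."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    if den <= 0:
        return 0.0
    return num * num / den


def hwe_exact_oracle(n_AA, n_Aa, n_aa):
    """Exact HWE p by full enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)
    if rare == 0:
        return 1.0

    def prob(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        ways = (
            Fraction(math.factorial(n))
            / (math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
            * Fraction(2) ** h
        )
        total = Fraction(math.factorial(2 * n)) / (
            math.factorial(nA) * math.factorial(na)
        )
        return ways / total

    hets = list(range(rare % 2, rare + 1, 2))
    probs = {h: prob(h) for h in hets}
    assert abs(float(sum(probs.values())) - 1.0) < 1e-9
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def clump_oracle(variant_rows, dosage_by_id, r2_threshold, window_bp):
    """Greedy clumping re-implemented with explicit loops.

    ``variant_rows``: list of dicts with id, chrom, pos, p.  Returns
    (index_ids, removed_map).  Verifies the retention conditions on its
    own output before returning.
    """
    cutoff = r2_threshold if r2_threshold < 1 else 1 - 1e-12
    order = sorted(variant_rows, key=lambda r: (r["p"], r["chrom"], r["pos"], r["id"]))
    assigned = set()
    index_ids, removed = [], {}
    for row in order:
        if row["id"] in assigned:
            continue
        assigned.add(row["id"])
        index_ids.append(row["id"])
        for other in order:
            if other["id"] in assigned:
                continue
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_bp:
                continue
            r2 = pearson_r2_naive(
                list(dosage_by_id[row["id"]]), list(dosage_by_id[other["id"]])
            )
            if r2 >= cutoff:
                assigned.add(other["id"])
                removed[other["id"]] = row["id"]

    # exhaustive verification of the retention conditions
    pos = {r["id"]: r["pos"] for r in variant_rows}
    chrom = {r["id"]: r["chrom"] for r in variant_rows}
    for rem, idx in removed.items():
        assert chrom[rem] == chrom[idx]
        assert abs(pos[rem] - pos[idx]) <= window_bp
        assert (
            pearson_r2_naive(list(dosage_by_id[rem]), list(dosage_by_id[idx]))
            >= cutoff
        )
    assert set(index_ids).isdisjoint(removed)
    assert set(index_ids) | set(removed) == {r["id"] for r in variant_rows}
    return index_ids, removed


def prune_oracle(variant_rows, dosage_by_id, maf_by_id, r2_threshold, window_bp, step):
    """Sliding-window pruning with the drop-smaller-MAF rule, naive loops."""
    order = sorted(variant_rows, key=lambda r: (r["chrom"], r["pos"], r["id"]))
    dropped = set()
    start = 0
    while start < len(order):
        anchor = order[start]
        window = [
            r for r in order[start:]
            if r["chrom"] == anchor["chrom"] and r["pos"] - anchor["pos"] <= window_bp
        ]
        changed = True
        while changed:
            changed = False
            live = [r for r in window if r["id"] not in dropped]
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    ra, rb = live[a], live[b]
                    r2 = pearson_r2_naive(
                        list(dosage_by_id[ra["id"]]), list(dosage_by_id[rb["id"]])
                    )
                    if r2 >= r2_threshold:
                        loser = min(
                            (ra, rb),
                            key=lambda r: (maf_by_id[r["id"]], -r["pos"], r["id"]),
                        )
                        dropped.add(loser["id"])
                        changed = True
                        break
                if changed:
                    break
        start += step
    return [r["id"] for r in order if r["id"] not in dropped]


def auc_all_pairs(scores, y):
    """All-pairs concordance count, ties 1/2."""
    cases = [s for s, yy in zip(scores, y) if yy == 1]
    ctrls = [s for s, yy in zip(scores, y) if yy == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def s80_threshold_scan(probs, y, specificity=0.80):
    """Exhaustive threshold scan for sensitivity at >= 80% specificity."""
    n1 = sum(y)
    n0 = len(y) - n1
    best = 0.0
    best_spec = None
    for t in sorted(set(probs)) + [float("inf")]:
        pos = [p >= t for p in probs]
        sens = sum(1 for p, yy in zip(pos, y) if p and yy == 1) / n1
        spec = sum(1 for p, yy in zip(pos, y) if not p and yy == 0) / n0
        if spec >= specificity and (best_spec is None or spec < best_spec):
            best, best_spec = sens, spec
    return best


def logistic_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))
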