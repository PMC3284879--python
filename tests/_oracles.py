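"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function re-derives a result by the most literal method available —
positional scans, sorting + median by hand, textbook formulas — deliberately
sharing no code with the package implementation it checks.
"""

import math
import statistics


def oracle_match(insert, db, policy):
    """Scan every reference at the 5' anchor, count mismatches position by
    position, apply head/tail budgets, resolve best hit by total mismatches."""
    if len(insert) < policy.min_insert_len:
        return ("too_short", None)
    candidates = []
    for name, ref in zip(db.names, db.seqs):
        overlap = min(len(insert), len(ref))
        mms = [i for i in range(overlap) if insert[i] != ref[i]]
        head = sum(1 for i in mms if i < policy.head_len)
        tail = len(mms) - head
        if head > policy.head_mm or tail > policy.tail_mm:
            continue
        if policy.total_mm is not None and len(mms) > policy.total_mm:
            continue
        candidates.append((len(mms), name))
    if not candidates:
        return ("none", None)
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        return ("multi", None)
    return ("hit", candidates[0][1])


def oracle_factors(matrix, reference, min_count=5):
    """Sort, pair, difference, median — straight-line scaling factors."""
    out = {}
    ref = matrix[reference]
    for d in matrix.columns:
        col = matrix[d]
        rows = [i for i in matrix.index if col[i] > min_count and ref[i] > min_count]
        qd = sorted(math.log2(col[i]) for i in rows)
        qr = sorted(math.log2(ref[i]) for i in rows)
        out[d] = statistics.median(a - b for a, b in zip(qd, qr))
    return out


def oracle_filter(matrix, threshold, min_datasets, datasets=None):
    cols = list(matrix.columns) if datasets is None else list(datasets)
    return [
        i for i in matrix.index
        if sum(1 for j in cols if matrix.loc[i, j] > threshold) >= min_datasets
    ]


def oracle_pearson(x, y):
    """Textbook product-moment formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def welch_oracle(a, b):
    """Hand-computed Welch t and two-sided p."""
    from scipy.stats import t as tdist

    ma, mb = statistics.mean(a), statistics.mean(b)
    va, vb = statistics.variance(a), statistics.variance(b)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)
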