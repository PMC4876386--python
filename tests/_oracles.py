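"""Independent brute-force reference implementations used only by tests.

Each oracle favours obviousness over speed: plain loops, full dynamic
programming, exhaustive enumeration.  They deliberately avoid the package's
own fast paths (seed prefilters, vectorized correlation, library calls).
"""

from __future__ import annotations

import numpy as np

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

NEG = -1e30


def merge_brute(s1: str, s2_rc: str, min_overlap: int, max_diff: float):
    """All-offset overlap search by direct character comparison."""
    n1, n2 = len(s1), len(s2_rc)
    best = None
    for offset in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        start = max(0, offset)
        end = min(n1, offset + n2)
        length = end - start
        if length < min_overlap:
            continue
        mism = sum(
            1 for pos in range(start, end) if s1[pos] != s2_rc[pos - offset]
        )
        if mism > max_diff * length:
            continue
        key = (-length, mism, offset)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], -best[0], best[1]


def smith_waterman(query: str, target: str):
    """Affine-gap local alignment with full traceback.

    Gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND (the first gapped
    position pays the open score).  Returns (score, identity %, query
    coverage, aligned columns).
    """
    n, m = len(query), len(target)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in target (consume query)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query (consume target)
    M[0, :] = M[:, 0] = 0.0
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 start,1 M,2 Ix,3 Iy
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if query[i - 1] == target[j - 1] else MISMATCH
            opts = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(opts))
            val = opts[k] + s
            if val < 0:
                M[i, j], ptr_m[i, j] = 0.0, 0
            else:
                M[i, j], ptr_m[i, j] = val, k + 1
            ox = (M[i - 1, j] + GAP_OPEN, Ix[i - 1, j] + GAP_EXTEND)
            k = int(np.argmax(ox))
            Ix[i, j], ptr_x[i, j] = ox[k], (1 if k == 0 else 2)
            oy = (M[i, j - 1] + GAP_OPEN, Iy[i, j - 1] + GAP_EXTEND)
            k = int(np.argmax(oy))
            Iy[i, j], ptr_y[i, j] = oy[k], (1 if k == 0 else 3)
    score = float(M.max())
    if score <= 0:
        return 0.0, 0.0, 0.0, 0
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    state = 1
    matches = cols = 0
    q_end = int(i)
    while True:
        if state == 1:
            if ptr_m[i, j] == 0 and (M[i, j] == 0.0):
                break
            prev = ptr_m[i, j]
            cols += 1
            if query[i - 1] == target[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = prev
        elif state == 2:
            prev = ptr_x[i, j]
            cols += 1
            i -= 1
            state = prev
        else:
            prev = ptr_y[i, j]
            cols += 1
            j -= 1
            state = prev
    q_start = int(i)
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = (q_end - q_start) / len(query) if query else 0.0
    return score, identity, coverage, cols


def greedy_cluster_brute(items, predicate, min_id=95.0, min_cov=0.90):
    """Greedy clustering scanning every representative, no prefilter.

    ``predicate(query_seq, rep_seq)`` must return (identity, coverage);
    returns the list of member-id lists in cluster creation order.
    """
    order = sorted(range(len(items)), key=lambda i: -len(items[i].seq))
    reps: list[str] = []
    members: list[list[str]] = []
    for i in order:
        item = items[i]
        for c, rep_seq in enumerate(reps):
            identity, coverage = predicate(item.seq, rep_seq)
            if identity >= min_id and coverage >= min_cov:
                members[c].append(item.id)
                break
        else:
            reps.append(item.seq)
            members.append([item.id])
    return members


def bh_brute(pvalues):
    """q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at 1."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, p[idx] * m / (rank_from_top + 1))
        q[idx] = running_min
    return q


def auc_concordance(scores, truth):
    """Mann-Whitney AUC: mean over (positive, negative) pairs of
    1 / 0.5 / 0 for concordant / tied / discordant scores."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def trim_brute(seq, qual, min_phred, min_len):
    """Position-by-position reference for N/quality trimming."""
    start, end = 0, len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    while end > start and qual[end - 1] < min_phred:
        end -= 1
    if end - start < min_len:
        return None
    return seq[start:end], list(qual[start:end])
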