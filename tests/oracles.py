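"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops, no vectorization, no reuse of library
code from the package paths they verify.
"""

from __future__ import annotations

STANDARD_AA = set("ARNDCQEGHILKMFPSTWYV")


def brute_force_psee(sequence, p_bur, cr, matrix, symmetrize=False,
                     normalize_by_count=False):
    """Direct double-loop evaluation of the per-residue energy."""
    L = len(sequence)
    out = []
    for i in range(L):
        if sequence[i].upper() not in STANDARD_AA:
            out.append(None)
            continue
        total = 0.0
        count = 0
        for j in range(max(0, i - cr), min(L - 1, i + cr) + 1):
            if j == i:
                continue
            count += 1
            if sequence[j].upper() not in STANDARD_AA:
                continue
            e = matrix[sequence[i], sequence[j]]
            if symmetrize:
                e = 0.5 * (e + matrix[sequence[j], sequence[i]])
            total += e * p_bur[j]
        divisor = max(count, 1) if normalize_by_count else 2 * cr
        out.append(p_bur[i] * total / divisor)
    return out


def pairwise_auc(scores, truth, positive="D"):
    """Rank-statistic AUC: P(random positive outscores a random negative),
    ties counted one half."""
    pos = [s for s, t in zip(scores, truth) if t == positive]
    neg = [s for s, t in zip(scores, truth) if t != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def youden_exhaustive(probabilities, labels, positive="D"):
    """Exhaustive candidate search for the J-optimal threshold with the
    (J, specificity, lower-threshold) tie-break."""
    distinct = sorted(set(probabilities))
    candidates = [0.0, 1.0] + [
        0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])
    ]
    n_pos = sum(1 for l in labels if l == positive)
    n_neg = len(labels) - n_pos
    scored = []
    for t in candidates:
        tp = sum(1 for p, l in zip(probabilities, labels) if l == positive and p >= t)
        tn = sum(1 for p, l in zip(probabilities, labels) if l != positive and p < t)
        sens, spec = tp / n_pos, tn / n_neg
        scored.append((-(sens + spec), -spec, t))
    return min(scored)[2]
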