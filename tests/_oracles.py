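"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths they verify: brute-force scans,
full enumeration, and big-rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from typing import Sequence


def bh_stepup(pvalues: Sequence[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up: adj_(i) = min_{k>=i} m*p_(k)/k."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adj[i] = running
    return adj


def binomial_tail_exact(k: int, n: int, e: Fraction = Fraction(1, 1000)) -> Fraction:
    """Exact rational P(X >= k), X ~ Binomial(n, e)."""
    return sum(
        Fraction(math.comb(n, i)) * e**i * (1 - e) ** (n - i) for i in range(k, n + 1)
    )


def mannwhitney_enumerated_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n = len(x)

    def min_u(xs, ys):
        u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        return min(u, len(xs) * len(ys) - u)

    observed = min_u(x, y)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        hits += min_u(xs, ys) <= observed + 1e-12
    return hits / total


def pearson_brute(x: Sequence[float], y: Sequence[float]) -> float:
    """Covariance-formula Pearson r, written independently."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def align_enumerate(
    read: str, precursor: str, max_mismatch: int = 1, max_tail: int = 3
) -> list[tuple[int, int, int, str]]:
    """Exhaustive offset x decomposition scan for the read aligner.

    Returns (start, body_len, n_mismatch, tail) per admissible offset,
    keeping the longest valid body at each offset. A decomposition is valid
    when the body fits the precursor with at most ``max_mismatch``
    mismatches and the tail is empty, overhangs the precursor, or mismatches
    the precursor at its first base.
    """
    out = []
    rlen, plen = len(read), len(precursor)
    for start in range(1, plen + 1):
        best = None
        for body_len in range(rlen, max(rlen - max_tail, 1) - 1, -1):
            if start + body_len - 1 > plen:
                continue
            mismatch_at = [
                i for i in range(body_len) if read[i] != precursor[start - 1 + i]
            ]
            mism = len(mismatch_at)
            if mism > max_mismatch:
                continue
            tail = read[body_len:]
            if tail:
                if mismatch_at and mismatch_at[-1] == body_len - 1:
                    continue  # a mismatch touching the tail belongs to the tail
                tpos = start + body_len
                if tpos <= plen and precursor[tpos - 1] == tail[0]:
                    continue
            best = (start, body_len, mism, tail)
            break
        if best is not None:
            out.append(best)
    return out
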