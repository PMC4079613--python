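"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's implementations: the repeat oracle
is a naive per-(start, period) scanner over substrings, and the Fisher
oracle enumerates every 2x2 table with the observed margins.
"""

from __future__ import annotations

import math
from math import comb


def _ham(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_find_tandem_repeats(
    seq: str,
    min_unit: int = 10,
    max_unit: int = 300,
    min_copies: int = 2,
    max_mismatch: float = 0.1,
) -> list[tuple[int, int, int, int]]:
    """All-period brute-force scan returning (start, unit_length,
    full_copies, partial_length) per selected array, under the documented
    semantics: adjacent-copy comparison within floor(max_mismatch * p)
    mismatches per unit, largest in-budget partial, score-maximal edge
    trim, greedy selection by descending match score then ascending unit
    length then start."""
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, int, int, int]] = []
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        budget = math.floor(max_mismatch * p)
        i = 0
        while i + 2 * p <= n:
            c = 1
            while i + (c + 1) * p <= n and _ham(
                seq[i + c * p : i + (c + 1) * p], seq[i + (c - 1) * p : i + c * p]
            ) <= budget:
                c += 1
            if c < min_copies:
                i += 1
                continue
            t = 0
            for cand in range(min(p - 1, n - i - c * p), -1, -1):
                if _ham(
                    seq[i + c * p : i + c * p + cand],
                    seq[i + (c - 1) * p : i + (c - 1) * p + cand],
                ) <= math.floor(max_mismatch * cand):
                    t = cand
                    break
            span = c * p + t
            flags = [seq[x] != seq[x + p] for x in range(i, i + span - p)]
            a = _longest_max_excess_prefix(flags)
            b = _longest_max_excess_prefix(flags[a:][::-1])
            s2, e2 = i + a, i + span - b
            c2, t2 = (e2 - s2) // p, (e2 - s2) % p
            if c2 >= min_copies:
                mism = sum(flags[a : len(flags) - b])
                compared = p * (c2 - 1) + t2
                candidates.append((s2, p, c2, t2, compared - 2 * mism, e2))
            i += span
    candidates.sort(key=lambda r: (-r[4], r[1], r[0]))
    kept: list[tuple[int, int, int, int, int, int]] = []
    for cand in candidates:
        if all(cand[5] <= k[0] or k[5] <= cand[0] for k in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r[0])
    return [(s, p, c, t) for s, p, c, t, _score, _end in kept]


def _longest_max_excess_prefix(flags: list[bool]) -> int:
    best_len, best_ex = 0, 0
    ex = 0
    for k, f in enumerate(flags, start=1):
        ex += 1 if f else -1  # 2*mism - len in unit steps
        if ex >= best_ex and ex > 0:
            best_len, best_ex = k, ex
    return best_len


def fisher_exact_enumeration(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration of all 2x2
    tables with the observed margins (hypergeometric probabilities;
    two-sided rule: sum of tables no more probable than the observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        if not (0 <= x <= r1 and 0 <= c1 - x <= r2):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
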