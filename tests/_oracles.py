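"""Independent reference implementations used only as test oracles.

Each function re-derives its quantity by the most direct route available
(substring comparison, exact rational arithmetic, exhaustive path
enumeration, textbook covariance formula) without touching the package's
own code paths.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, sqrt

from scipy import stats

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

_PRECEDENCE = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _rc(s: str) -> str:
    out = ""
    for ch in s:
        out = _COMP[ch] + out
    return out


def naive_patterns(mirna_seq: str) -> dict[str, str]:
    seq = mirna_seq.upper().replace("T", "U")
    m8 = _rc(seq[1:8])
    a1 = _rc(seq[1:7])
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1 + "A", "6mer": a1}


def naive_scan(mirna_seq: str, utr_seq: str) -> list[tuple[int, int, str]]:
    """Position-by-position substring scan with the precedence rule:
    types in decreasing specificity, windows greedily non-overlapping."""
    utr = utr_seq.upper().replace("T", "U")
    pats = naive_patterns(mirna_seq)
    accepted: list[tuple[int, int, str]] = []
    for stype in _PRECEDENCE:
        pat = pats[stype]
        L = len(pat)
        for start in range(len(utr) - L + 1):
            if utr[start : start + L] != pat:
                continue
            end = start + L
            if any(start < e and s < end for s, e, _ in accepted):
                continue
            accepted.append((start, end, stype))
    order = {t: i for i, t in enumerate(_PRECEDENCE)}
    return sorted(accepted, key=lambda x: (x[0], order[x[2]]))


def brute_fisher_right_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact hypergeometric right tail by direct rational summation."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc


def brute_local_align(m: str, w: str, seed_flags: list[bool], p: dict) -> float:
    """Exhaustive enumeration of every local alignment path (small inputs)."""

    def pair(a: str, b: str) -> float:
        if _COMP[a] == b:
            return p["wc"]
        if {a, b} == {"G", "U"}:
            return p["wobble"]
        return p["mismatch"]

    best = 0.0

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(m) and j < len(w):
            s = pair(m[i], w[j])
            if seed_flags[i]:
                s *= p["seed_multiplier"]
            extend(i + 1, j + 1, score + s, "M")
        if i < len(m):
            cost = p["gap_extend"] if last == "X" else p["gap_open"]
            extend(i + 1, j, score + cost, "X")
        if j < len(w):
            cost = p["gap_extend"] if last == "Y" else p["gap_open"]
            extend(i, j + 1, score + cost, "Y")

    for i in range(len(m)):
        for j in range(len(w)):
            s = pair(m[i], w[j])
            if seed_flags[i]:
                s *= p["seed_multiplier"]
            extend(i + 1, j + 1, s, "M")
    return best


def pearson_oracle(x, y) -> tuple[float, float]:
    """Textbook covariance-over-sd-product r with a two-sided t-test p."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / sqrt(vx * vy)
    if abs(r) >= 1.0 - 1e-15:
        return (1.0 if r > 0 else -1.0), 0.0
    t = r * sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p
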