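"""Independent brute-force oracles used to check senotf implementations.

Everything here is written from first principles (character sets, recursion,
integer combinatorics) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_variants(pattern: str) -> set[str]:
    """All concrete words matching an IUPAC pattern, by recursion."""
    if not pattern:
        return {""}
    rest = brute_variants(pattern[1:])
    return {base + tail for base in _SETS[pattern[0]] for tail in rest}


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    return all(seq[pos + i] in _SETS[c] for i, c in enumerate(pattern))


def _rc_pattern(pattern: str) -> str:
    # reverse complement via the base sets themselves
    out = []
    for c in reversed(pattern):
        comp = frozenset(_COMP[b] for b in _SETS[c])
        for code, bases in _SETS.items():
            if frozenset(bases) == comp:
                out.append(code)
                break
    return "".join(out)


def naive_scan(
    seq: str, pattern: str, strand_mode: str = "both", overlap: str = "allowed"
) -> list[tuple[int, int, str]]:
    """Position-by-position scanner: (start, end, strand) tuples."""
    hits: dict[int, str] = {}
    for pos in range(len(seq)):
        if _matches_at(seq, pattern, pos):
            hits[pos] = "+"
    if strand_mode == "both":
        rc = _rc_pattern(pattern)
        for pos in range(len(seq)):
            if _matches_at(seq, rc, pos) and pos not in hits:
                hits[pos] = "-"
    out = [(pos, pos + len(pattern), strand) for pos, strand in sorted(hits.items())]
    if overlap == "disallowed":
        kept, last_end = [], -1
        for start, end, strand in out:
            if start >= last_end:
                kept.append((start, end, strand))
                last_end = end
        out = kept
    return out


def hypergeom_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer tail summation.

    Enumerates every table with the observed margins; sums the (exact,
    integer-weighted) probabilities of tables no more likely than the
    observed one.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    r2 = n - r1
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = math.comb(n, c1)
    return sum(w for w in weights.values() if w <= w_obs) / total


def pooled_t_p(xs: list[float], ys: list[float]) -> float:
    """Hand-coded pooled-variance two-tailed Student t p-value."""
    from scipy.stats import t as t_dist

    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    ssx = sum((x - mx) ** 2 for x in xs)
    ssy = sum((y - my) ** 2 for y in ys)
    df = nx + ny - 2
    sp2 = (ssx + ssy) / df
    tstat = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2.0 * t_dist.sf(abs(tstat), df)
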