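"""Independent brute-force oracles used to check the implementation."""
from __future__ import annotations

from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Textbook recursive definition of edit distance (memoized)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def brute_force_candidates(text: str, lexicon) -> list[tuple[int, int, str]]:
    """Every variant tested against every contiguous token window.

    Tokens are maximal [a-z0-9]+ runs of the lowercased text; a variant
    matches a window iff the window's tokens equal the variant's tokens and
    the inter-token gaps are pure whitespace.  Returns (start, end,
    pattern_id) triples.
    """
    import re

    low = text.lower()
    tokens = [(m.start(), m.end(), m.group()) for m in re.finditer(r"[a-z0-9]+", low)]
    out = []
    for pat in lexicon.patterns.values():
        vtoks = pat.variant.split()
        k = len(vtoks)
        for i in range(len(tokens) - k + 1):
            window = tokens[i : i + k]
            if [t[2] for t in window] != vtoks:
                continue
            gaps_ok = all(
                low[window[j][1] : window[j + 1][0]].strip() == ""
                for j in range(k - 1)
            )
            if gaps_ok:
                out.append((window[0][0], window[-1][1], pat.pattern_id))
    return out


def brute_force_matches(text: str, lexicon) -> list[tuple[int, int, str]]:
    """Candidates resolved longest-match-first, then leftmost, then pattern id."""
    cands = brute_force_candidates(text, lexicon)
    cands.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, str]] = []
    for s, e, pid in cands:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, pid))
    return sorted(chosen)
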