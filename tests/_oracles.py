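"""Independent reference implementations used only to check the package.

These deliberately restate the definitions (recursively / by exhaustive
enumeration) rather than sharing any code path with gaitmod.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def osa_distance_recursive(a: str, b: str) -> int:
    """Optimal-string-alignment distance straight from the definitional
    recursion over suffix pairs (insert/delete/substitute/adjacent
    transposition, no substring edited twice)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (0 if a[i - 1] == b[j - 1] else 1),
        )
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    result = d(len(a), len(b))
    d.cache_clear()
    return result


def all_strings(alphabet: str, max_len: int):
    for length in range(max_len + 1):
        for tup in itertools.product(alphabet, repeat=length):
            yield "".join(tup)


def ks_exhaustive(a, b, wa=None, wb=None) -> float:
    """Weighted two-sample KS by brute force over every jump point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    wa = np.ones_like(a) if wa is None else np.asarray(wa, float)
    wb = np.ones_like(b) if wb is None else np.asarray(wb, float)

    def cdf(x, w, v):
        return float(np.sum(w[x <= v]) / np.sum(w))

    best = 0.0
    for v in np.concatenate([a, b]):
        best = max(best, abs(cdf(a, wa, v) - cdf(b, wb, v)))
    return best


def window_score_exhaustive(description: str, text_tokens, threshold: float) -> float:
    """Best moving-window score for a multi-token description, computed by
    exhaustive enumeration of windows and per-token comparisons."""
    desc = description.split()
    w = len(desc) + 2
    n = len(text_tokens)
    best = 0.0
    for start in range(max(1, n - w + 1) if n else 0):
        window = text_tokens[start : start + w]
        total = 0.0
        for d_tok in desc:
            token_best = 0.0
            for t_tok in window:
                if any(ch.isdigit() for ch in t_tok) or len(t_tok) < 3 or len(d_tok) < 3:
                    s = 0.0
                elif d_tok == t_tok:
                    s = 1.0
                elif min(len(d_tok), len(t_tok)) < 4:
                    s = 0.0
                else:
                    s = 1.0 - osa_distance_recursive(d_tok, t_tok) / max(
                        len(d_tok), len(t_tok)
                    )
                token_best = max(token_best, s)
            total += token_best
        best = max(best, total / len(desc))
    return best
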