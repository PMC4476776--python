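"""String-similarity primitives for register linkage.

Levenshtein distance is delegated to edlib; the Jaro similarity is
implemented here (no installed package provides it).
"""

from __future__ import annotations

import re

import edlib

_CLEAN_RE = re.compile(r"[\s\W_]+")


def normalize(s: str) -> str:
    """Case-fold and strip whitespace/punctuation before comparison."""
    if s is None:
        return ""
    return _CLEAN_RE.sub("", str(s)).upper()


def levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - d/max(len); 1.0 for two empty strings."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein(a, b) / m


def jaro(a: str, b: str) -> float:
    """Classic Jaro similarity in [0, 1]."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = True
                match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: half the number of matched characters out of order
    bs = [b[j] for j in range(lb) if match_b[j]]
    transpositions = sum(
        1 for ca, cb in zip((a[i] for i in range(la) if match_a[i]), bs) if ca != cb
    ) // 2
    m = matches
    return (m / la + m / lb + (m - transpositions) / m) / 3.0
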