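"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately share nothing with the implementation's search logic:
the alignment oracle enumerates every diagonal window, and the hairpin
oracle enumerates every (outer pair, stem length) structure.  Both are
O(n*m) / O(n^3) and only suitable for small inputs.
"""

from __future__ import annotations

import math

import numpy as np

from probesieve.scoring import (
    HAIRPIN_LOOP_DG37,
    MIN_LOOP,
    MIN_STEM,
    NN_STACK_DG37,
    hairpin_loop_penalty,
)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def qualifying_windows(probe: str, subject: str, window: int = 20, min_matches: int = 14):
    """All (diagonal, probe offset) windows meeting the identity rule."""
    p, s = _enc(probe), _enc(subject)
    n, m = len(p), len(s)
    out = []
    for diag in range(-(n - window), m - window + 1):
        qlo = max(0, -diag)
        qhi = min(n, m - diag)
        if qhi - qlo < window:
            continue
        matches = p[qlo:qhi] == s[qlo + diag : qhi + diag]
        csum = np.concatenate([[0], np.cumsum(matches)])
        for q0 in range(0, len(matches) - window + 1):
            if csum[q0 + window] - csum[q0] >= min_matches:
                out.append((diag, qlo + q0))
    return out


def bruteforce_hit_exists(probe: str, subject: str, window: int = 20, min_matches: int = 14) -> bool:
    """Sliding-window aligner: is there any >=70%-over-20-nt diagonal window?"""
    p, s = _enc(probe), _enc(subject)
    n, m = len(p), len(s)
    for diag in range(-(n - window), m - window + 1):
        qlo = max(0, -diag)
        qhi = min(n, m - diag)
        if qhi - qlo < window:
            continue
        matches = (p[qlo:qhi] == s[qlo + diag : qhi + diag]).astype(int)
        run = np.convolve(matches, np.ones(window, dtype=int), mode="valid")
        if (run >= min_matches).any():
            return True
    return False


def window_has_seed(probe: str, subject: str, diag: int, q0: int,
                    window: int = 20, word: int = 7) -> bool:
    """Does the given qualifying window contain an exact ``word``-mer run?"""
    p, s = _enc(probe), _enc(subject)
    matches = p[q0 : q0 + window] == s[q0 + diag : q0 + diag + window]
    best = cur = 0
    for m in matches:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best >= word


def enumerate_hairpin_mfe(seq: str) -> float:
    """Exhaustive single-hairpin minimum free energy.

    Enumerates every structure (outer pair a..b, stem length s >= MIN_STEM,
    loop >= MIN_LOOP nt, all stem pairs Watson-Crick) and sums the
    nearest-neighbor stack terms plus the loop penalty.
    """
    n = len(seq)
    best = math.inf
    for a in range(n):
        for b in range(a + 1, n):
            max_stem = (b - a + 1 - MIN_LOOP) // 2
            for s in range(MIN_STEM, max_stem + 1):
                loop = (b - s + 1) - (a + s - 1) - 1
                if loop < MIN_LOOP:
                    continue
                if any(seq[b - t] != _PAIR[seq[a + t]] for t in range(s)):
                    continue
                dg = hairpin_loop_penalty(loop)
                for t in range(s - 1):
                    dg += NN_STACK_DG37[seq[a + t] + seq[a + t + 1]]
                best = min(best, dg)
    return best
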