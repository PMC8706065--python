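"""Independent brute-force oracle for prominence-filtered extrema detection.

Deliberately naive O(n^2) re-implementation of the rules: subtract the
signal mean as baseline, locate local maxima (plateau -> middle sample,
rounded down), compute topographic prominence by scanning outward to the
nearest strictly-higher sample or the signal edge, retain maxima with
prominence >= height-above-baseline and height >= threshold, repeat on the
negated signal for valleys, then enforce strict peak/valley alternation by
keeping the larger-|height| extremum of any same-kind run (ties -> earlier).
Kept free of scipy so it stays independent of the implementation it checks.
"""

from __future__ import annotations

import numpy as np

# shared rule semantics: the prominence-vs-height comparison carries a tiny
# absolute tolerance so baseline-grazing region boundaries are not lost to
# float dust (same constant as the implementation under test)
PROMINENCE_TOL = 1e-9


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict local maxima; flat tops yield the middle index."""
    out = []
    n = len(y)
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def _prominence(y: np.ndarray, p: int) -> float:
    left_min = y[p]
    for i in range(p - 1, -1, -1):
        if y[i] > y[p]:
            break
        left_min = min(left_min, y[i])
    right_min = y[p]
    for i in range(p + 1, len(y)):
        if y[i] > y[p]:
            break
        right_min = min(right_min, y[i])
    return y[p] - max(left_min, right_min)


def oracle_extrema(times: np.ndarray, angles: np.ndarray, min_height: float):
    """Return [(time, signed_height, prominence, kind), ...], alternation enforced."""
    x = np.asarray(angles, float) - np.mean(angles)
    found = []
    for sign, kind in ((1.0, "peak"), (-1.0, "valley")):
        y = sign * x
        for p in _local_maxima(y):
            prom = _prominence(y, p)
            if prom >= y[p] - PROMINENCE_TOL and y[p] >= min_height:
                found.append((float(times[p]), float(sign * y[p]), float(prom), kind))
    found.sort(key=lambda e: e[0])
    kept: list[tuple] = []
    for e in found:
        if kept and kept[-1][3] == e[3]:
            if abs(e[1]) > abs(kept[-1][1]):
                kept[-1] = e
        else:
            kept.append(e)
    return kept
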