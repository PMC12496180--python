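"""Affine-gap global alignment (Gotoh) with deterministic traceback.

The dynamic program is vectorised row-by-row with numpy; the within-row
dependency of the horizontal-gap state is resolved with a running-maximum
prefix scan, which is exact because gap extension is linear in length.

Scoring convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(both passed as positive numbers), so a single contiguous gap is always
preferred over the same columns split into several gaps.

Tie-breaking during traceback is fixed: diagonal first, then a gap in the
second sequence (``b``), then a gap in the first (``a``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -1.0e18


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment: two equal-length gapped rows and a score."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.a)

    def identity(self) -> float:
        """Matches divided by alignment columns."""
        matches = sum(1 for x, y in zip(self.a, self.b) if x == y and x != "-")
        return matches / len(self.a) if self.a else 0.0


def _substitution_rows(a: str, b: str, match: float, mismatch: float,
                       wildcard: str | None) -> np.ndarray:
    """(len(a), len(b)) substitution score matrix for these two strings."""
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    eq = arr_a[:, None] == arr_b[None, :]
    if wildcard is not None:
        w = ord(wildcard)
        is_w = (arr_a[:, None] == w) | (arr_b[None, :] == w)
        eq = eq & ~is_w
    return np.where(eq, match, mismatch)


def global_align(a: str, b: str, *, match: float = 2.0, mismatch: float = -3.0,
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 wildcard: str | None = None) -> Alignment:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    Parameters
    ----------
    a, b
        Sequences to align (``a`` indexes the rows of the DP).
    match, mismatch
        Per-column substitution scores.
    gap_open, gap_extend
        Positive costs; a length-``L`` gap scores ``-(gap_open + (L-1)*gap_extend)``.
    wildcard
        Optional symbol that never scores as a match (e.g. ``"N"``).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    n, m = len(a), len(b)
    o, e = float(gap_open), float(gap_extend)
    sub = _substitution_rows(a, b, float(match), float(mismatch), wildcard)

    # M: a[i] aligned to b[j]; X: gap in b (consumes a); Y: gap in a (consumes b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j_idx = np.arange(1, m + 1, dtype=float)
    Y[0, 1:] = -(o + (j_idx - 1.0) * e)
    i_idx = np.arange(1, n + 1, dtype=float)
    X[1:, 0] = -(o + (i_idx - 1.0) * e)

    ks = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - o, X[i - 1, 1:] - e, Y[i - 1, 1:] - o])
        best_prev = np.maximum.reduce([M[i - 1], X[i - 1], Y[i - 1]])
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        # Y[i, j] = max_{k < j} (max(M, X)[i, k] - o - (j - 1 - k) * e)
        cand = np.maximum(M[i], X[i]) + ks * e
        prefix = np.maximum.accumulate(cand)
        Y[i, 1:] = prefix[:-1] - o - (ks[1:] - 1.0) * e

    rows_a: list[str] = []
    rows_b: list[str] = []
    i, j = n, m
    final = max(M[n, m], X[n, m], Y[n, m])
    if M[n, m] == final:
        state = "M"
    elif X[n, m] == final:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            rows_a.append(a[i - 1])
            rows_b.append("-")
            val = X[i, j]
            i -= 1
            if M[i, j] - o == val:
                state = "M"
            elif X[i, j] - e == val:
                state = "X"
            else:
                state = "Y"
        else:
            rows_a.append("-")
            rows_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if M[i, j] - o == val:
                state = "M"
            elif X[i, j] - o == val:
                state = "X"
            else:
                state = "Y"
    return Alignment("".join(reversed(rows_a)), "".join(reversed(rows_b)), final)
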