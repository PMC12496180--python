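"""Exhaustive sliding-window deletion mutagenesis with a pluggable scorer.

A scorer is any callable ``scorer(sequence) -> (scalar, per_residue)`` that
is deterministic for a fixed input and returns one value per residue of the
input sequence. Score orientation: higher = more benign, lower = more
damaging (per-residue values near −1 damaging, near +1 beneficial).

The trained language-model scorer used in production is external; this
module ships the scan framework, a reference additive hydropathy scorer,
and an adapter that shells out to any command producing JSON
``{"scalar": x, "per_residue": [...]}``.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class DeletionVariant:
    """One w-residue deletion window in 1-based domain numbering."""

    aa_start: int
    aa_end: int
    sequence: str
    hgvs: str


@dataclass
class ScanResult:
    """Scores for the wild type and every deletion variant of one scan."""

    sequence: str
    window: int
    variants: list[DeletionVariant]
    wt_scalar: float
    wt_per_residue: np.ndarray
    scalars: np.ndarray  # (n_variants,)
    per_residue: list[np.ndarray]  # each length L - window
    table: pd.DataFrame  # aa_start, aa_end, hgvs, scalar, rank

    def mean_score(self) -> float:
        return float(self.scalars.mean())

    def rank_of(self, window: tuple[int, int]) -> int:
        row = self.table[(self.table["aa_start"] == window[0])
                         & (self.table["aa_end"] == window[1])]
        if row.empty:
            raise KeyError(f"window {window} not in scan")
        return int(row["rank"].iloc[0])

    def variant_at(self, window: tuple[int, int]) -> int:
        for i, v in enumerate(self.variants):
            if (v.aa_start, v.aa_end) == window:
                return i
        raise KeyError(f"window {window} not in scan")


def deletion_hgvs(sequence: str, aa_start: int, aa_end: int) -> str:
    if aa_start == aa_end:
        return f"p.{sequence[aa_start - 1]}{aa_start}del"
    return (f"p.{sequence[aa_start - 1]}{aa_start}_"
            f"{sequence[aa_end - 1]}{aa_end}del")


def enumerate_deletions(sequence: str, window: int = 3, step: int = 1,
                        allow_empty: bool = False) -> list[DeletionVariant]:
    """All deletion windows of the given size, start positions 1..L−w+1."""
    length = len(sequence)
    if window > length:
        raise ValueError("window larger than the sequence")
    if window == length and not allow_empty:
        raise ValueError("full-length deletion needs allow_empty=True")
    variants = []
    for start0 in range(0, length - window + 1, step):
        aa_start, aa_end = start0 + 1, start0 + window
        variants.append(DeletionVariant(
            aa_start=aa_start, aa_end=aa_end,
            sequence=sequence[:start0] + sequence[start0 + window:],
            hgvs=deletion_hgvs(sequence, aa_start, aa_end)))
    return variants


def additive_hydropathy_scorer(sequence: str) -> tuple[float, np.ndarray]:
    """Reference scorer: Kyte-Doolittle values, scalar = their sum."""
    vec = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in sequence])
    return float(vec.sum()), vec


def constant_scorer(sequence: str) -> tuple[float, np.ndarray]:
    return 0.0, np.zeros(len(sequence))


class ExternalCommandScorer:
    """Adapter for an external scorer command.

    The command receives the sequence as its final argument and must print
    JSON ``{"scalar": <float>, "per_residue": [<float>, ...]}`` to stdout.
    """

    def __init__(self, command: list[str]):
        self.command = list(command)

    def __call__(self, sequence: str) -> tuple[float, np.ndarray]:
        out = subprocess.run(self.command + [sequence], check=True,
                             capture_output=True, text=True).stdout
        payload = json.loads(out)
        return float(payload["scalar"]), np.asarray(payload["per_residue"], dtype=float)


def _checked_score(scorer, sequence: str) -> tuple[float, np.ndarray]:
    scalar, vec = scorer(sequence)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (len(sequence),):
        raise ValueError("scorer returned wrong per-residue length")
    if not np.isfinite(scalar) or not np.all(np.isfinite(vec)):
        raise ValueError("scorer returned non-finite values")
    return float(scalar), vec


def run_scan(sequence: str, scorer, window: int = 3, step: int = 1) -> ScanResult:
    """Score the wild type and every deletion variant.

    Ranks are by descending scalar score (rank 1 = most benign), ties broken
    by ascending start position.
    """
    variants = enumerate_deletions(sequence, window, step)
    wt_scalar, wt_vec = _checked_score(scorer, sequence)
    scalars = np.empty(len(variants))
    vectors: list[np.ndarray] = []
    for i, v in enumerate(variants):
        s, vec = _checked_score(scorer, v.sequence)
        scalars[i] = s
        vectors.append(vec)
    order = sorted(range(len(variants)),
                   key=lambda i: (-scalars[i], variants[i].aa_start))
    rank = np.empty(len(variants), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    table = pd.DataFrame({
        "aa_start": [v.aa_start for v in variants],
        "aa_end": [v.aa_end for v in variants],
        "hgvs": [v.hgvs for v in variants],
        "scalar": scalars,
        "rank": rank,
    })
    return ScanResult(sequence=sequence, window=window, variants=variants,
                      wt_scalar=wt_scalar, wt_per_residue=wt_vec,
                      scalars=scalars, per_residue=vectors, table=table)


def difference_map(result: ScanResult, window: tuple[int, int]) -> pd.DataFrame:
    """Δ_j = mutated value − wt value on the residues shared with the variant.

    Deleted positions are absent; positions after the window map back by the
    window size (mutated index j − w for wild-type position j > aa_end).
    """
    i = result.variant_at(window)
    vec = result.per_residue[i]
    w = result.window
    aa_start, aa_end = window
    rows = []
    for j in range(1, len(result.sequence) + 1):
        if aa_start <= j <= aa_end:
            continue
        mut_idx = j - 1 if j < aa_start else j - 1 - w
        rows.append({"residue": j,
                     "wt": float(result.wt_per_residue[j - 1]),
                     "mutated": float(vec[mut_idx]),
                     "delta": float(vec[mut_idx] - result.wt_per_residue[j - 1])})
    return pd.DataFrame(rows)


def per_residue_impact(result: ScanResult, window: tuple[int, int],
                       tau_neg: float = -0.3) -> pd.DataFrame:
    """Difference map with positions below ``tau_neg`` flagged as negatively affected."""
    df = difference_map(result, window)
    df["negatively_affected"] = df["delta"] < tau_neg
    return df


def classify(result: ScanResult, window: tuple[int, int], rule: str = "above_mean",
             k: int = 50, tau: float | None = None) -> dict:
    """Label a query deletion relative to the scan distribution.

    Rules: ``above_mean`` (score ≥ mean of all variants), ``top_k``
    (rank ≤ k), ``fixed_threshold`` (score ≥ tau). Ties at the mean count as
    benign-leaning.
    """
    i = result.variant_at(window)
    score = float(result.scalars[i])
    rank = result.rank_of(window)
    mean = result.mean_score()
    if rule == "above_mean":
        benign = score >= mean
    elif rule == "top_k":
        benign = rank <= k
    elif rule == "fixed_threshold":
        if tau is None:
            raise ValueError("fixed_threshold needs tau")
        benign = score >= tau
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {"label": "benign-leaning" if benign else "damaging-leaning",
            "score": score, "rank": rank, "mean": mean, "rule": rule,
            "n_variants": len(result.variants)}
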