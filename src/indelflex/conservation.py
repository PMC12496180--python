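"""Per-residue conservation scoring and alignment diversity.

The column score is entropy-based with gap down-weighting:

    score_c = (1 - H_c / ln 20) * (1 - g_c)

where H_c is the weighted Shannon entropy of the 20 amino-acid frequencies
in column c (gaps excluded from H, counted only through the weighted gap
fraction g_c). Sequence weights are position-based (Henikoff-style) computed
on the set of *unique* rows and split evenly among identical copies, which
makes column scores exactly invariant to duplicating sequences.

Alignment diversity (DOPS) is the fraction of distinct column scores after
rounding to 3 decimals; values near 1 indicate a diverse alignment whose
conserved calls are robust.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import global_align

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA20)}
_LN20 = float(np.log(20.0))


@dataclass
class MSA:
    """An aligned set of amino-acid sequences with optional sequence weights."""

    sequences: list[tuple[str, str]]  # (id, aligned row with '-')
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty MSA")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("MSA rows have unequal lengths")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.sequences),):
                raise ValueError("one weight per sequence required")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    def column(self, c: int) -> str:
        return "".join(row[c] for _, row in self.sequences)


@dataclass
class ConservationProfile:
    """Per-column conservation with the diversity summary."""

    positions: np.ndarray  # 1-based reference residue positions
    scores: np.ndarray  # in [0, 1]
    gap_fractions: np.ndarray
    tau: float
    conserved_positions: np.ndarray = field(init=False)
    dops: float = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        self.gap_fractions = np.asarray(self.gap_fractions, dtype=float)
        self.conserved_positions = self.positions[self.scores >= self.tau]
        self.dops = dops(self.scores)


def length_filter(query_length: int, candidates: list[str],
                  max_rel_diff: float = 0.2) -> list[str]:
    """Keep sequences whose length differs from the query by at most the fraction."""
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    return [s for s in candidates
            if abs(len(s) - query_length) / query_length <= max_rel_diff]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    return global_align(a, b, match=1.0, mismatch=-1.0,
                        gap_open=5.0, gap_extend=1.0).identity()


def cluster_by_identity(sequences: list[str], threshold: float = 0.70
                        ) -> list[list[str]]:
    """Greedy incremental clustering by global-alignment identity.

    Sequences are processed longest-first (ties by input order); each joins
    the first existing cluster whose representative (founding, longest
    member, kept at index 0) reaches the identity threshold, else founds a
    new cluster. Deterministic for a given input list.
    """
    if not sequences:
        raise ValueError("empty input")
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    clusters: list[list[str]] = []
    for i in order:
        seq = sequences[i]
        for cluster in clusters:
            if pairwise_identity(cluster[0], seq) >= threshold:
                cluster.append(seq)
                break
        else:
            clusters.append([seq])
    return clusters


def representatives(clusters: list[list[str]]) -> list[str]:
    return [c[0] for c in clusters]


def _henikoff_unique(rows: list[str]) -> np.ndarray:
    """Henikoff position-based weights for a list of distinct rows (unnormalised)."""
    n = len(rows)
    ncol = len(rows[0])
    w = np.zeros(n)
    for c in range(ncol):
        col = [row[c] for row in rows]
        counts = Counter(col)
        r = len(counts)
        for i, sym in enumerate(col):
            w[i] += 1.0 / (r * counts[sym])
    return w / ncol


def sequence_weights(msa: MSA) -> np.ndarray:
    """Position-based sequence weights, normalised to sum to n_sequences.

    Computed on unique rows and split evenly among identical copies, so
    duplicated sequences carry exactly the weight of one copy between them.
    """
    rows = [row for _, row in msa.sequences]
    unique: dict[str, list[int]] = {}
    for i, row in enumerate(rows):
        unique.setdefault(row, []).append(i)
    uniq_rows = list(unique)
    if len(uniq_rows) == 1:
        w = np.ones(len(rows))
    else:
        uw = _henikoff_unique(uniq_rows)
        w = np.empty(len(rows))
        for u, row in enumerate(uniq_rows):
            members = unique[row]
            w[members] = uw[u] / len(members)
    return w * (len(rows) / w.sum())


def conservation_profile(msa: MSA, tau: float = 0.70, reference: int | str = 0,
                         weights: np.ndarray | None = None) -> ConservationProfile:
    """Score every reference (non-gap) column of the MSA.

    ``reference`` selects the reference row by index or id; positions are
    1-based indices into that sequence's ungapped coordinates. All-gap
    columns score 0 by convention.
    """
    if isinstance(reference, str):
        ids = [i for i, (sid, _) in enumerate(msa.sequences) if sid == reference]
        if not ids:
            raise KeyError(f"no sequence with id {reference!r}")
        reference = ids[0]
    if weights is None:
        weights = msa.weights if msa.weights is not None else sequence_weights(msa)
    ref_row = msa.sequences[reference][1]

    positions, scores, gap_fracs = [], [], []
    ref_pos = 0
    total_w = weights.sum()
    for c in range(msa.n_columns):
        if ref_row[c] == "-":
            continue
        ref_pos += 1
        col = msa.column(c)
        freq = np.zeros(20)
        gap_w = 0.0
        for w, sym in zip(weights, col):
            if sym == "-":
                gap_w += w
            elif sym in _AA_INDEX:
                freq[_AA_INDEX[sym]] += w
        g = gap_w / total_w
        present = freq.sum()
        if present <= 0:
            score = 0.0
        else:
            p = freq[freq > 0] / present
            entropy = float(-(p * np.log(p)).sum())
            score = (1.0 - entropy / _LN20) * (1.0 - g)
        positions.append(ref_pos)
        scores.append(score)
        gap_fracs.append(g)
    return ConservationProfile(np.array(positions), np.array(scores),
                               np.array(gap_fracs), tau)


def dops(scores: np.ndarray) -> float:
    """Diversity of position scores: distinct values (3-decimal) / columns."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scored columns")
    return len(np.unique(np.round(scores, 3))) / scores.size


def align_small_msa(sequences: list[tuple[str, str]]) -> MSA:
    """Center-star progressive alignment for toy-scale sequence sets.

    The longest sequence is the star center; all others are pairwise-aligned
    to it and their gaps merged. Intended for small inputs only — not a
    substitute for a production MSA tool.
    """
    if not sequences:
        raise ValueError("empty input")
    if len(sequences) == 1:
        return MSA(list(sequences))
    center_idx = max(range(len(sequences)), key=lambda i: len(sequences[i][1]))
    center_id, center = sequences[center_idx]
    pairs = []
    for i, (sid, seq) in enumerate(sequences):
        if i == center_idx:
            continue
        aln = global_align(center, seq, match=1.0, mismatch=-1.0,
                           gap_open=5.0, gap_extend=1.0)
        pairs.append((sid, aln.a, aln.b))

    # merge: build the union gap pattern of the center across all pairs
    insertions: dict[int, int] = {}  # center position (ungapped, 0-based) -> max run
    for _, crow, _ in pairs:
        pos, run = 0, 0
        for ch in crow:
            if ch == "-":
                run += 1
            else:
                if run:
                    insertions[pos] = max(insertions.get(pos, 0), run)
                    run = 0
                pos += 1
        if run:
            insertions[pos] = max(insertions.get(pos, 0), run)

    def expand(crow: str, srow: str) -> str:
        out = []
        pos, run = 0, 0
        buf = []
        for c_ch, s_ch in zip(crow, srow):
            if c_ch == "-":
                buf.append(s_ch)
                run += 1
            else:
                pad = insertions.get(pos, 0)
                out.append("".join(buf) + "-" * (pad - run))
                buf, run = [], 0
                out.append(s_ch)
                pos += 1
        pad = insertions.get(pos, 0)
        out.append("".join(buf) + "-" * (pad - run))
        return "".join(out)

    rows = [(center_id, expand(center, center))]
    for sid, crow, srow in pairs:
        rows.append((sid, expand(crow, srow)))
    order = {sid: i for i, (sid, _) in enumerate(sequences)}
    rows.sort(key=lambda t: order[t[0]])
    return MSA(rows)
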