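"""Cross-condition comparison statistics for trajectory ensembles.

Implements sliding-window per-residue flexibility peaks with two-sample
t-tests and Benjamini-Hochberg FDR control, resolution and cross-condition
consistency filters, loop-level flexibility tests, and secondary-structure
occupancy comparison. Windows are built over contiguous runs of shared
residue IDs only, so they never straddle a deleted-residue gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traj_core import ResidueProfile

DEFAULT_COMPARISONS = [("wt", "del"), ("wtg", "delg"), ("wt", "wtg"), ("del", "delg")]


# ------------------------------------------------------------------- windows

def contiguous_runs(residue_ids: np.ndarray) -> list[np.ndarray]:
    """Split sorted residue IDs into maximal runs of consecutive integers."""
    ids = np.asarray(residue_ids, dtype=int)
    if ids.size == 0:
        return []
    breaks = np.nonzero(np.diff(ids) != 1)[0] + 1
    return np.split(ids, breaks)


def window_means(profile: ResidueProfile, window: int = 3, step: int = 1
                 ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Sliding-window means of per-replicate RMSF over contiguous ID runs.

    Returns the (start_id, end_id) window labels and a (replicates, windows)
    matrix of window means. Raises if no contiguous run holds a full window.
    """
    ids = profile.residue_ids
    index_of = {int(r): i for i, r in enumerate(ids)}
    windows: list[tuple[int, int]] = []
    cols: list[np.ndarray] = []
    for run in contiguous_runs(np.sort(ids)):
        for s in range(0, len(run) - window + 1, step):
            span = run[s:s + window]
            idx = [index_of[int(r)] for r in span]
            windows.append((int(span[0]), int(span[-1])))
            cols.append(profile.per_replicate[:, idx].mean(axis=1))
    if not windows:
        raise ValueError("no contiguous run long enough for the window")
    return windows, np.column_stack(cols)


# ---------------------------------------------------------------- statistics

def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Student's t with pooled variance.

    Degenerate conventions: zero pooled variance with equal means gives
    (0, 1); zero pooled variance with unequal means gives (±inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.copysign(np.inf, diff)), 0.0
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and reject flags at alpha."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= alpha


# --------------------------------------------------------------- comparisons

@dataclass
class PeakTable:
    """Per-window comparison results plus the cross-condition consistency report."""

    table: pd.DataFrame  # one row per (comparison, window)
    consistent_windows: list[tuple[int, int]]
    direction_concordance: dict[tuple[int, int], bool]
    conclusion: str  # "no_consistent_effect" | "possible_consistent_effect"

    def for_comparison(self, a: str, b: str) -> pd.DataFrame:
        return self.table[self.table["comparison"] == f"{a}_vs_{b}"]


def compare_systems(profiles: dict[str, ResidueProfile],
                    comparisons=None, window: int = 3, step: int = 1,
                    alpha: float = 0.05, resolution: float = 2.5) -> PeakTable:
    """Sliding-window flexibility comparison across conditions.

    Per comparison, windows over the shared residue IDs of the pair are
    t-tested across replicate window means and BH-adjusted within that
    comparison. Consistency intersects the significant windows of the first
    two comparisons (deletion effect with and without the modifier
    condition); direction concordance compares the sign of the group-mean
    difference between those two comparisons.
    """
    comparisons = DEFAULT_COMPARISONS if comparisons is None else list(comparisons)
    for a, b in comparisons:
        if a not in profiles or b not in profiles:
            raise KeyError(f"missing system for comparison ({a}, {b})")

    rows = []
    sig_windows: dict[tuple[str, str], set[tuple[int, int]]] = {}
    deltas: dict[tuple[str, str], dict[tuple[int, int], float]] = {}
    for a, b in comparisons:
        shared = np.intersect1d(profiles[a].residue_ids, profiles[b].residue_ids)
        if shared.size == 0:
            raise ValueError(f"no shared residues for ({a}, {b})")
        pa, pb = profiles[a].select(shared), profiles[b].select(shared)
        wins_a, ma = window_means(pa, window, step)
        wins_b, mb = window_means(pb, window, step)
        assert wins_a == wins_b
        t_p = [two_sample_t(ma[:, j], mb[:, j]) for j in range(len(wins_a))]
        raw_p = np.array([p for _, p in t_p])
        adj_p, reject = bh_adjust(raw_p, alpha)
        sig_windows[(a, b)] = {w for w, rej in zip(wins_a, reject) if rej}
        deltas[(a, b)] = {}
        for j, w in enumerate(wins_a):
            mean_a, mean_b = float(ma[:, j].mean()), float(mb[:, j].mean())
            delta = mean_b - mean_a
            deltas[(a, b)][w] = delta
            rows.append({
                "comparison": f"{a}_vs_{b}",
                "window_start": w[0], "window_end": w[1],
                "mean_a": mean_a, "mean_b": mean_b, "delta": delta,
                "t": t_p[j][0], "p": raw_p[j], "p_adj": adj_p[j],
                "significant": bool(reject[j]),
                "above_resolution": bool(abs(delta) > resolution),
                "direction": int(np.sign(delta)),
            })

    first, second = comparisons[0], comparisons[1]
    consistent = sorted(sig_windows[first] & sig_windows[second])
    concordance = {w: np.sign(deltas[first][w]) == np.sign(deltas[second][w])
                   for w in consistent}
    table = pd.DataFrame(rows)
    effect = any(
        concordance[w]
        and bool(table[(table["comparison"] == f"{first[0]}_vs_{first[1]}")
                       & (table["window_start"] == w[0])]["above_resolution"].iloc[0])
        for w in consistent)
    return PeakTable(
        table=table, consistent_windows=consistent,
        direction_concordance=concordance,
        conclusion="possible_consistent_effect" if effect else "no_consistent_effect")


def loop_flexibility_test(profiles: dict[str, ResidueProfile], loop_residues,
                          pairs) -> dict[tuple[str, str], tuple[float, float]]:
    """Pooled-t comparison of per-replicate mean loop RMSF between conditions."""
    loop = np.asarray(sorted(set(int(r) for r in loop_residues)), dtype=int)
    out = {}
    for a, b in pairs:
        shared = np.intersect1d(profiles[a].residue_ids, profiles[b].residue_ids)
        sel = np.intersect1d(loop, shared)
        if sel.size == 0:
            raise ValueError(f"empty loop intersection for ({a}, {b})")
        mean_a = profiles[a].select(sel).per_replicate.mean(axis=1)
        mean_b = profiles[b].select(sel).per_replicate.mean(axis=1)
        out[(a, b)] = two_sample_t(mean_a, mean_b)
    return out


# ----------------------------------------------------------- secondary structure

_SS_MAP = {"G": "H", "H": "H", "I": "H", "E": "E", "B": "E"}


@dataclass
class SSOccupancy:
    """Helix/strand/other frequency per residue, averaged over replicates."""

    residue_ids: np.ndarray
    helix: np.ndarray  # (N,) mean over replicates
    strand: np.ndarray
    other: np.ndarray
    helix_sd: np.ndarray
    strand_sd: np.ndarray


def simplify_ss(label: str) -> str:
    """Map a rich secondary-structure alphabet onto {H, E, C}."""
    return _SS_MAP.get(label, "C")


def ss_occupancy(labels_per_replicate: list[list[str]],
                 residue_ids) -> SSOccupancy:
    """Occupancy from per-frame label strings (one character per residue).

    ``labels_per_replicate[r]`` is a list of frame strings for replicate r.
    Richer alphabets are simplified (G/H/I → H, E/B → E, else C).
    """
    ids = np.asarray(residue_ids, dtype=int)
    n = ids.size
    per_rep_h, per_rep_e = [], []
    for frames in labels_per_replicate:
        if not frames:
            raise ValueError("replicate with no frames")
        counts_h = np.zeros(n)
        counts_e = np.zeros(n)
        for frame in frames:
            if len(frame) != n:
                raise ValueError("label string length does not match residues")
            simple = [simplify_ss(ch) for ch in frame]
            counts_h += np.array([ch == "H" for ch in simple], dtype=float)
            counts_e += np.array([ch == "E" for ch in simple], dtype=float)
        per_rep_h.append(counts_h / len(frames))
        per_rep_e.append(counts_e / len(frames))
    h = np.vstack(per_rep_h)
    e = np.vstack(per_rep_e)
    r = h.shape[0]
    sd = (lambda x: x.std(axis=0, ddof=1) if r > 1 else np.zeros(n))
    return SSOccupancy(ids, h.mean(axis=0), e.mean(axis=0),
                       1.0 - h.mean(axis=0) - e.mean(axis=0), sd(h), sd(e))


def compare_occupancy(a: SSOccupancy, b: SSOccupancy) -> pd.DataFrame:
    """Per-residue occupancy differences (A − B) on shared residues."""
    shared = np.intersect1d(a.residue_ids, b.residue_ids)
    ia = {int(r): i for i, r in enumerate(a.residue_ids)}
    ib = {int(r): i for i, r in enumerate(b.residue_ids)}
    rows = []
    for r in shared:
        rows.append({
            "residue": int(r),
            "delta_helix": a.helix[ia[int(r)]] - b.helix[ib[int(r)]],
            "delta_strand": a.strand[ia[int(r)]] - b.strand[ib[int(r)]],
        })
    return pd.DataFrame(rows)
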