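"""Essential-dynamics PCA over pooled Cα coordinates.

All frames of all replicates are superposed to one reference over the shared
residues (minus any excluded set), flattened to 3k-vectors, mean-centered,
and decomposed by covariance PCA. Component signs are fixed so the
largest-magnitude loading is positive, making results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traj_core import TrajectoryEnsemble, superpose_frames


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, 3k), orthonormal rows
    explained_variance_ratio: np.ndarray  # (n_components,)
    projections: pd.DataFrame  # system, replicate, frame, pc1..pcN
    residue_ids: np.ndarray  # the k residues used
    excluded_residues: np.ndarray
    total_variance: float
    eigenvalues: np.ndarray  # all 3k eigenvalues

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def pooled_pca(ensemble: TrajectoryEnsemble, exclude_residues=(),
               n_components: int = 10,
               reference: np.ndarray | None = None) -> PCAResult:
    """Covariance PCA of pooled, superposed Cα coordinates.

    ``reference`` defaults to the first frame of the first replicate of the
    first system, restricted to the used residues. ``exclude_residues`` are
    dropped from the shared set before superposition and analysis.
    """
    shared = ensemble.shared_residue_ids()
    used = np.setdiff1d(shared, np.asarray(list(exclude_residues), dtype=int))
    if used.size < 2:
        raise ValueError("exclusion leaves fewer than 2 residues")

    blocks, labels = [], []
    ref = reference
    for system, reps in ensemble.systems.items():
        for r_idx, rep in enumerate(reps):
            sel = rep.select(used)
            order = np.argsort(sel.residue_ids)
            coords = sel.coords[:, order]
            if ref is None:
                ref = coords[0]
            moved = superpose_frames(coords, ref)
            blocks.append(moved.reshape(moved.shape[0], -1))
            labels.extend((system, r_idx, f) for f in range(moved.shape[0]))
    X = np.vstack(blocks)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / Xc.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    total = float(np.trace(cov))
    n_components = min(n_components, evecs.shape[1])
    comps = evecs[:, :n_components].T.copy()
    for i in range(n_components):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    proj = Xc @ comps.T
    frame_df = pd.DataFrame(labels, columns=["system", "replicate", "frame"])
    for i in range(n_components):
        frame_df[f"pc{i + 1}"] = proj[:, i]
    ratios = np.clip(evals[:n_components], 0.0, None) / total if total > 0 else \
        np.zeros(n_components)
    return PCAResult(components=comps, explained_variance_ratio=ratios,
                     projections=frame_df, residue_ids=used,
                     excluded_residues=np.asarray(sorted(exclude_residues), dtype=int),
                     total_variance=total, eigenvalues=evals)


def extreme_frames(result: PCAResult, pcs=(1, 2)) -> pd.DataFrame:
    """Per-replicate frames with the max/min projection on each requested PC."""
    rows = []
    for (system, rep), grp in result.projections.groupby(["system", "replicate"],
                                                         sort=False):
        if grp.empty:
            raise ValueError("empty replicate")
        for pc in pcs:
            col = f"pc{pc}"
            imax = grp[col].idxmax()
            imin = grp[col].idxmin()
            rows.append({"system": system, "replicate": rep, "pc": pc,
                         "kind": "max", "frame": int(grp.loc[imax, "frame"]),
                         "value": float(grp.loc[imax, col])})
            rows.append({"system": system, "replicate": rep, "pc": pc,
                         "kind": "min", "frame": int(grp.loc[imin, "frame"]),
                         "value": float(grp.loc[imin, col])})
    return pd.DataFrame(rows)


def flag_outlier_replicates(result: PCAResult, k: float = 3.0) -> pd.DataFrame:
    """Flag replicates whose (PC1, PC2) centroid is a robust outlier.

    A replicate is flagged when its centroid's distance from the median
    centroid exceeds the median distance by more than k times the scaled
    median absolute deviation (MAD × 1.4826) of the distances. The MAD is
    floored at 5% of the per-frame projection spread: with few replicates
    the raw MAD collapses towards zero and would flag pure sampling noise,
    whose centroids sit far below the frame-level spread.
    """
    cent = result.projections.groupby(["system", "replicate"], sort=False)[
        ["pc1", "pc2"]].mean()
    if len(cent) < 3:
        raise ValueError("need at least 3 replicates")
    med = cent.median(axis=0).to_numpy()
    d = np.linalg.norm(cent.to_numpy() - med, axis=1)
    mad = np.median(np.abs(d - np.median(d))) * 1.4826
    frame_spread = float(np.sqrt(
        result.projections[["pc1", "pc2"]].var(ddof=0).sum()))
    flags = (d - np.median(d)) > k * max(mad, 0.05 * frame_spread)
    out = cent.reset_index()
    out["distance"] = d
    out["outlier"] = flags
    return out


def loop_divergence(ensemble: TrajectoryEnsemble, loop_residues,
                    reference: np.ndarray | None = None,
                    systems=None) -> pd.DataFrame:
    """Loop-restricted mean RMSD per replicate after full-domain superposition.

    Frames are superposed to the reference over all shared residues; the RMSD
    is then evaluated on the loop residues only (no re-fitting). The spread
    column repeats max − min of the replicate means within each system.
    """
    systems = list(ensemble.systems) if systems is None else list(systems)
    shared = ensemble.shared_residue_ids(systems)
    loop = np.intersect1d(np.asarray(sorted(loop_residues), dtype=int), shared)
    if loop.size == 0:
        raise ValueError("empty loop selection")
    loop_mask = np.isin(shared, loop)

    ref = reference
    rows = []
    for system in systems:
        means = []
        for r_idx, rep in enumerate(ensemble.systems[system]):
            sel = rep.select(shared)
            order = np.argsort(sel.residue_ids)
            coords = sel.coords[:, order]
            if ref is None:
                ref = coords[0]
            moved = superpose_frames(coords, ref)
            d2 = np.sum((moved[:, loop_mask] - ref[loop_mask]) ** 2, axis=-1)
            mean_rmsd = float(np.mean(np.sqrt(d2.mean(axis=1))))
            means.append(mean_rmsd)
            rows.append({"system": system, "replicate": r_idx,
                         "loop_mean_rmsd": mean_rmsd})
        spread = max(means) - min(means)
        for row in rows:
            if row["system"] == system and "spread" not in row:
                row["spread"] = spread
    return pd.DataFrame(rows)
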