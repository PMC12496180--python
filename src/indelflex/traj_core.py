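"""Geometry and per-replicate statistics on Cα trajectories.

Coordinates are in Å, times in ps, residue IDs 1-based in the reference
numbering shared across systems (deleted residues are simply absent from the
deletion systems' ID lists). All selections are uniform-weight: on a
single-atom-type (Cα) selection, mass weighting is a constant factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Replicate:
    """One trajectory replicate: frames × atoms × 3 Cα coordinates."""

    coords: np.ndarray  # (F, N, 3) float, Å
    times_ps: np.ndarray  # (F,) strictly increasing, evenly spaced
    residue_ids: np.ndarray  # (N,) int, 1-based

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        if self.coords.shape[0] != self.times_ps.shape[0]:
            raise ValueError("times length must equal frame count")
        if self.coords.shape[1] != self.residue_ids.shape[0]:
            raise ValueError("residue_ids length must equal atom count")
        if len(self.times_ps) > 1:
            dt = np.diff(self.times_ps)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0]):
                raise ValueError("times must be evenly spaced")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        dt = self.times_ps[1] - self.times_ps[0]
        return self.n_frames * dt / 1000.0

    def select(self, residue_ids) -> "Replicate":
        """Restrict to the given residue IDs (order of this replicate kept)."""
        wanted = set(int(r) for r in residue_ids)
        mask = np.array([int(r) in wanted for r in self.residue_ids])
        if not mask.any():
            raise ValueError("selection is empty")
        return Replicate(self.coords[:, mask], self.times_ps, self.residue_ids[mask])


@dataclass
class TrajectoryEnsemble:
    """Systems × replicates of Cα trajectories with a residue correspondence."""

    systems: dict[str, list[Replicate]]

    def __post_init__(self) -> None:
        for label, reps in self.systems.items():
            for rep in reps:
                if rep.n_frames != reps[0].n_frames:
                    raise ValueError(f"unequal frame counts within system {label!r}")

    @property
    def system_labels(self) -> list[str]:
        return list(self.systems)

    def shared_residue_ids(self, labels=None) -> np.ndarray:
        """Sorted residue IDs present in every listed system."""
        labels = list(self.systems) if labels is None else list(labels)
        shared: set[int] | None = None
        for label in labels:
            ids = set(int(r) for r in self.systems[label][0].residue_ids)
            shared = ids if shared is None else shared & ids
        return np.array(sorted(shared or ()), dtype=int)

    def total_simulated_time_us(self) -> float:
        return sum(rep.duration_ns for reps in self.systems.values()
                   for rep in reps) / 1000.0

    def per_system_time_us(self) -> dict[str, float]:
        return {label: sum(r.duration_ns for r in reps) / 1000.0
                for label, reps in self.systems.items()}


@dataclass
class ScalarSeries:
    """Per-frame scalar (Rg or RMSD, Å) with times."""

    values: np.ndarray
    times_ps: np.ndarray

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ResidueProfile:
    """Per-residue RMSF for a set of replicates, plus cross-replicate stats."""

    residue_ids: np.ndarray  # (N,)
    per_replicate: np.ndarray  # (R, N)
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.per_replicate = np.atleast_2d(np.asarray(self.per_replicate, dtype=float))
        if self.per_replicate.shape[1] != len(self.residue_ids):
            raise ValueError("profile width must match residue_ids")
        r = self.per_replicate.shape[0]
        self.mean = self.per_replicate.mean(axis=0)
        self.sd = (self.per_replicate.std(axis=0, ddof=1) if r > 1
                   else np.zeros_like(self.mean))
        self.sem = self.sd / np.sqrt(r)

    def select(self, residue_ids) -> "ResidueProfile":
        wanted = set(int(x) for x in residue_ids)
        mask = np.array([int(r) in wanted for r in self.residue_ids])
        if not mask.any():
            raise ValueError("selection is empty")
        return ResidueProfile(self.residue_ids[mask], self.per_replicate[:, mask])


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Kabsch superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the minimised RMSD. The
    rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([mc, tc])) < 2:
        raise ValueError("degenerate (collinear) configuration")
    moved = _rotate_onto(mc[None], tc)[0] + target.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=-1))))
    return moved, rmsd


def _rotate_onto(mobile_centered: np.ndarray, target_centered: np.ndarray) -> np.ndarray:
    """Batched Kabsch: rotate each centered frame (F,N,3) onto a centered target (N,3)."""
    H = np.einsum("fni,nj->fij", mobile_centered, target_centered)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    U[:, :, -1] *= d[:, None]
    R = np.einsum("fij,fjk->fik", U, Vt)
    return np.einsum("fni,fij->fnj", mobile_centered, R)


def superpose_frames(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``coords`` (F,N,3) onto ``target`` (N,3)."""
    coords = np.asarray(coords, dtype=float)
    target = np.asarray(target, dtype=float)
    centered = coords - coords.mean(axis=1, keepdims=True)
    tmean = target.mean(axis=0)
    return _rotate_onto(centered, target - tmean) + tmean


def radius_of_gyration(coords: np.ndarray) -> float:
    """Uniform-weight Rg: RMS distance of atoms from their centroid (Å)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("empty selection")
    d2 = np.sum((coords - coords.mean(axis=0)) ** 2, axis=-1)
    return float(np.sqrt(np.mean(d2)))


def rg_series(replicate: Replicate) -> ScalarSeries:
    c = replicate.coords
    d2 = np.sum((c - c.mean(axis=1, keepdims=True)) ** 2, axis=-1)
    return ScalarSeries(np.sqrt(d2.mean(axis=1)), replicate.times_ps)


def rmsd_series(replicate: Replicate, reference: np.ndarray | None = None) -> ScalarSeries:
    """Per-frame minimised RMSD to a reference (default: the starting frame)."""
    ref = replicate.coords[0] if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != replicate.coords.shape[1:]:
        raise ValueError("reference atom count mismatch")
    moved = superpose_frames(replicate.coords, ref)
    rmsd = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=-1), axis=-1))
    return ScalarSeries(rmsd, replicate.times_ps)


def rmsf_profile(replicate: Replicate, reference: str = "start") -> np.ndarray:
    """Per-residue RMSF about the time-average position (Å).

    Frames are first superposed to the replicate's starting structure
    (``reference="start"``, default) or to the mean structure
    (``reference="mean"``, one extra pass).
    """
    if replicate.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    moved = superpose_frames(replicate.coords, replicate.coords[0])
    if reference == "mean":
        moved = superpose_frames(moved, moved.mean(axis=0))
    elif reference != "start":
        raise ValueError("reference must be 'start' or 'mean'")
    mean_pos = moved.mean(axis=0)
    return np.sqrt(np.mean(np.sum((moved - mean_pos) ** 2, axis=-1), axis=0))


def aggregate_rmsf(replicates: list[Replicate], reference: str = "start") -> ResidueProfile:
    """RMSF per replicate stacked into a cross-replicate ResidueProfile."""
    if not replicates:
        raise ValueError("no replicates")
    ids = replicates[0].residue_ids
    for rep in replicates[1:]:
        if not np.array_equal(rep.residue_ids, ids):
            raise ValueError("replicates disagree on residue IDs")
    return ResidueProfile(ids, np.vstack([rmsf_profile(r, reference) for r in replicates]))


def trim_equilibration(replicate: Replicate, burn_in="auto", delta: float = 0.5) -> Replicate:
    """Drop burn-in frames.

    ``burn_in`` is a time in ns (frames with time < burn_in are dropped) or
    ``"auto"``: the smallest time from which the forward (frame-to-end)
    running mean of the RMSD-to-start series stays within ``delta`` Å of the
    final-20% mean.
    """
    if burn_in == "auto":
        series = rmsd_series(replicate).values
        tail = series[int(np.floor(0.8 * len(series))):]
        suffix = np.cumsum(series[::-1])[::-1] / np.arange(len(series), 0, -1)
        off = np.abs(suffix - tail.mean()) > delta
        first_ok = int(np.max(np.nonzero(off)[0])) + 1 if off.any() else 0
        if first_ok >= replicate.n_frames:
            raise ValueError("auto burn-in consumed the whole trajectory")
        return Replicate(replicate.coords[first_ok:], replicate.times_ps[first_ok:],
                         replicate.residue_ids)
    burn_ps = float(burn_in) * 1000.0
    keep = replicate.times_ps >= burn_ps
    if not keep.any():
        raise ValueError("burn-in not shorter than the trajectory")
    return Replicate(replicate.coords[keep], replicate.times_ps[keep],
                     replicate.residue_ids)


def sem_of_max_dif(series_by_system: dict[str, np.ndarray],
                   axis: np.ndarray | None = None) -> tuple[int | float, float]:
    """Location of the maximum cross-system spread of means, and the SEM there.

    ``series_by_system`` maps system label to a mean series on a shared axis
    (time for RMSD, residue ID for RMSF). Returns (axis location, SD across
    system means at that location divided by √n_systems).
    """
    labels = list(series_by_system)
    if len(labels) < 2:
        raise ValueError("need at least 2 systems")
    mat = np.vstack([np.asarray(series_by_system[k], dtype=float) for k in labels])
    if axis is not None and len(axis) != mat.shape[1]:
        raise ValueError("axis length mismatch")
    spread = mat.max(axis=0) - mat.min(axis=0)
    loc = int(np.argmax(spread))
    vals = mat[:, loc]
    sem = float(np.std(vals, ddof=1) / np.sqrt(len(labels)))
    where = axis[loc] if axis is not None else loc
    return where, sem
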