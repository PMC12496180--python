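"""Synthetic inputs with known ground truth for every downstream stage.

Three generators: Gaussian-fluctuation Cα trajectory ensembles (planted
per-residue amplitudes, optional decaying burn-in drift), diploid allele sets
with planted per-population deletion frequencies (deterministic carrier
counts, so recovery is exact), and MSAs with planted per-column conservation
targets. All randomness flows from explicit seeds via ``numpy`` generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_core import Replicate, TrajectoryEnsemble
from .variants import AlleleSet, Haplotype

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one codon per residue type; enough for synthetic CDS construction
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


# ---------------------------------------------------------------- trajectories

@dataclass
class TrajectorySpec:
    """Recipe for a Gaussian-fluctuation trajectory ensemble.

    ``amplitude_profile`` maps each system label to a per-residue fluctuation
    scale σ_i (Å, per coordinate); residue IDs absent from
    ``residue_ids_per_system`` emulate deletions. ``burn_in_drift`` adds a
    linearly decaying x-displacement of the first half of the chain over the
    first ``length_ns`` (a block shift, so RMSD-to-start sees it).
    """

    n_residues: int
    duration_ns: float
    frame_interval_ps: float
    n_replicates: int
    amplitude_profile: dict[str, np.ndarray]
    residue_ids_per_system: dict[str, np.ndarray] | None = None
    burn_in_drift: tuple[float, float] | None = None  # (length_ns, displacement_A)
    reference_coords: np.ndarray | None = None
    seed: int = 0

    @property
    def systems(self) -> list[str]:
        return list(self.amplitude_profile)

    @property
    def n_frames(self) -> int:
        frames = self.duration_ns * 1000.0 / self.frame_interval_ps
        if frames <= 0 or abs(frames - round(frames)) > 1e-9:
            raise ValueError("duration/frame_interval must be a positive integer frame count")
        return int(round(frames))

    def validate(self) -> None:
        self.n_frames  # noqa: B018 - raises on bad bookkeeping
        for label, sigma in self.amplitude_profile.items():
            sigma = np.asarray(sigma, dtype=float)
            if sigma.shape != (self.n_residues,):
                raise ValueError(f"amplitude profile for {label!r} has wrong length")
            if np.any(sigma < 0):
                raise ValueError(f"negative fluctuation scale in system {label!r}")


def _default_reference(n_residues: int, seed: int) -> np.ndarray:
    """A well-conditioned compact blob used as the common starting structure."""
    rng = np.random.default_rng(seed)
    # self-avoiding-ish walk: Cα spacing ~3.8 Å with random direction
    steps = rng.normal(size=(n_residues, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(3.8 * steps, axis=0)


def generate_trajectories(spec: TrajectorySpec) -> TrajectoryEnsemble:
    """Emit an ensemble where frame f = reference + iid Gaussian noise (sd σ_i).

    Noise is isotropic and frame-independent; with ``burn_in_drift`` set,
    frames inside the burn-in window additionally carry a rigid displacement
    that decays linearly to zero. Deterministic under ``spec.seed``.
    """
    spec.validate()
    n_frames = spec.n_frames
    ref = (spec.reference_coords if spec.reference_coords is not None
           else _default_reference(spec.n_residues, spec.seed))
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (spec.n_residues, 3):
        raise ValueError("reference_coords must be (n_residues, 3)")
    times = np.arange(n_frames, dtype=float) * spec.frame_interval_ps

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(spec.systems) * spec.n_replicates)
    systems: dict[str, list[Replicate]] = {}
    for s_idx, label in enumerate(spec.systems):
        sigma = np.asarray(spec.amplitude_profile[label], dtype=float)
        if spec.residue_ids_per_system and label in spec.residue_ids_per_system:
            ids = np.asarray(spec.residue_ids_per_system[label], dtype=int)
        else:
            ids = np.arange(1, spec.n_residues + 1)
        mask = np.isin(np.arange(1, spec.n_residues + 1), ids)
        reps = []
        for r in range(spec.n_replicates):
            rng = np.random.default_rng(children[s_idx * spec.n_replicates + r])
            noise = rng.normal(size=(n_frames, spec.n_residues, 3)) * sigma[None, :, None]
            coords = ref[None] + noise
            if spec.burn_in_drift is not None:
                # displace the first half of the chain only: a whole-molecule
                # rigid shift would be removed by superposition and invisible
                # to every RMSD-based convergence check
                length_ns, disp = spec.burn_in_drift
                frac = np.clip(1.0 - times / (length_ns * 1000.0), 0.0, None)
                half = spec.n_residues // 2
                coords[:, :half, 0] += disp * frac[:, None]
            reps.append(Replicate(coords[:, mask], times, ids))
        systems[label] = reps
    return TrajectoryEnsemble(systems)


# -------------------------------------------------------------------- alleles

@dataclass
class AlleleSimSpec:
    """Recipe for a diploid allele survey with one planted in-frame deletion."""

    reference_cds: str
    populations: list[tuple[str, int, float]]  # (label, n_individuals, deletion freq)
    deletion: tuple[int, int]  # (aa_start, aa_end), 1-based inclusive
    subspecies: dict[str, str] = field(default_factory=dict)  # population -> label
    recombinant_rate: float = 0.0  # fraction of carrier haplotypes flagged
    seed: int = 0

    def validate(self) -> None:
        if len(self.reference_cds) % 3 != 0:
            raise ValueError("reference CDS length must be divisible by 3")
        for label, n, f in self.populations:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency for {label!r} outside [0, 1]")
            if n <= 0:
                raise ValueError(f"population {label!r} has no individuals")
        aa_start, aa_end = self.deletion
        n_aa = len(self.reference_cds) // 3
        if not 1 <= aa_start <= aa_end <= n_aa:
            raise ValueError("deletion outside the coding sequence")


def random_cds(n_codons: int, seed: int = 0,
               protein_constraints: dict[int, str] | None = None) -> str:
    """Random CDS of ``n_codons`` codons; optionally pin residues at positions.

    ``protein_constraints`` maps 1-based amino-acid positions to residue
    letters, handy for planting a recognisable HGVS name.
    """
    rng = np.random.default_rng(seed)
    aas = [_AA20[i] for i in rng.integers(0, 20, size=n_codons)]
    for pos, letter in (protein_constraints or {}).items():
        aas[pos - 1] = letter
    return "".join(_CODON[a] for a in aas)


def generate_alleles(spec: AlleleSimSpec) -> AlleleSet:
    """Diploid haplotypes with exactly round(2·n·f) deletion carriers per population.

    Carrier slots are assigned deterministically, then which individuals they
    land on is a seeded shuffle; homozygotes arise when both slots of one
    individual are carriers. Recovered frequencies are therefore exact.
    """
    spec.validate()
    aa_start, aa_end = spec.deletion
    nt_lo, nt_hi = 3 * (aa_start - 1), 3 * aa_end  # 0-based half-open
    deleted_cds = spec.reference_cds[:nt_lo] + spec.reference_cds[nt_hi:]
    rng = np.random.default_rng(spec.seed)
    haplotypes: list[Haplotype] = []
    for label, n, f in spec.populations:
        n_slots = 2 * n
        n_carriers = int(round(n_slots * f))
        carrier = np.zeros(n_slots, dtype=bool)
        carrier[:n_carriers] = True
        carrier = carrier[rng.permutation(n_slots)]
        n_recomb = int(round(spec.recombinant_rate * n_carriers))
        recomb_slots = set(np.flatnonzero(carrier)[:n_recomb].tolist())
        for i in range(n):
            for hap_idx in (1, 2):
                slot = 2 * i + hap_idx - 1
                haplotypes.append(Haplotype(
                    individual_id=f"{label}_ind{i + 1}",
                    haplotype_index=hap_idx,
                    population_id=label,
                    subspecies=spec.subspecies.get(label, "unknown"),
                    cds=deleted_cds if carrier[slot] else spec.reference_cds,
                    recombinant=slot in recomb_slots))
    return AlleleSet(reference_cds=spec.reference_cds, haplotypes=haplotypes)


def planted_counts(spec: AlleleSimSpec) -> dict[str, int]:
    """Exact carrier haplotype count per population implied by the spec."""
    return {label: int(round(2 * n * f)) for label, n, f in spec.populations}


# ------------------------------------------------------------------------ MSA

@dataclass
class MsaSimSpec:
    """Recipe for an MSA with planted per-column conservation targets."""

    n_sequences: int
    length: int
    conservation_profile: np.ndarray  # per-column target in [0, 1]
    gap_rate: float | np.ndarray = 0.0  # per-column gap probability
    seed: int = 0

    def validate(self) -> None:
        prof = np.asarray(self.conservation_profile, dtype=float)
        if prof.shape != (self.length,):
            raise ValueError("conservation_profile length mismatch")
        if np.any((prof < 0) | (prof > 1)):
            raise ValueError("conservation targets must lie in [0, 1]")
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")


def generate_msa(spec: "MsaSimSpec"):
    """Columns mix a consensus residue with uniform noise, monotone in target.

    A column with target s draws the consensus with probability s and a
    uniform residue otherwise; target 1.0 columns are single-residue and
    gap-free, target 0.0 columns are uniform over the 20 residues.
    """
    from .conservation import MSA  # deferred: conservation imports the aligner

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    prof = np.asarray(spec.conservation_profile, dtype=float)
    gaps = np.broadcast_to(np.asarray(spec.gap_rate, dtype=float), (spec.length,))
    consensus = rng.integers(0, 20, size=spec.length)
    rows = np.empty((spec.n_sequences, spec.length), dtype="<U1")
    for c in range(spec.length):
        uniform = rng.integers(0, 20, size=spec.n_sequences)
        take_cons = rng.random(spec.n_sequences) < prof[c]
        letters = np.where(take_cons, consensus[c], uniform)
        col = np.array([_AA20[i] for i in letters])
        if prof[c] < 1.0 and gaps[c] > 0:
            col[rng.random(spec.n_sequences) < gaps[c]] = "-"
        rows[:, c] = col
    seqs = [(f"seq{i + 1}", "".join(rows[i])) for i in range(spec.n_sequences)]
    return MSA(seqs)
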