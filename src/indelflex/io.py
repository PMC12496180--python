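"""Plain-text readers and writers for every format the pipeline touches.

Residue and nucleotide coordinates in all outputs are 1-based inclusive.
Haplotype FASTA headers follow ``>individual|haplotype|population|subspecies``
(a trailing ``|recombinant`` marks flagged haplotypes). Trajectories travel
either as Cα-only multi-model PDB or as the CACOORDS text container:

    # CACOORDS 1
    n_atoms <N>
    frame_interval_ps <dt>
    residue_ids <id> <id> ...
    frame <time_ps>
    <x> <y> <z>          (N lines, Å, full precision)
    ...
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import MSA
from .traj_core import Replicate
from .variants import AlleleSet, Haplotype

log = logging.getLogger("indelflex")


# ---------------------------------------------------------------------- FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_haplotype_fasta(path, alleles: AlleleSet) -> None:
    records = []
    for h in alleles.haplotypes:
        name = f"{h.individual_id}|{h.haplotype_index}|{h.population_id}|{h.subspecies}"
        if h.recombinant:
            name += "|recombinant"
        records.append((name, h.cds))
    write_fasta(path, records)


def read_haplotype_fasta(path, reference_cds: str) -> AlleleSet:
    haplotypes = []
    for name, seq in read_fasta(path):
        parts = name.split("|")
        if len(parts) < 4:
            raise ValueError(f"malformed haplotype header: {name!r}")
        haplotypes.append(Haplotype(
            individual_id=parts[0], haplotype_index=int(parts[1]),
            population_id=parts[2], subspecies=parts[3],
            recombinant=len(parts) > 4 and parts[4] == "recombinant",
            cds=seq))
    return AlleleSet(reference_cds=reference_cds, haplotypes=haplotypes)


def read_msa_fasta(path) -> MSA:
    return MSA(read_fasta(path))


def write_msa_fasta(path, msa: MSA) -> None:
    write_fasta(path, msa.sequences)


# ----------------------------------------------------------------- sample sheet

SAMPLE_SHEET_COLUMNS = ["individual", "haplotype", "population", "subspecies",
                        "recombinant"]


def write_sample_sheet(path, alleles: AlleleSet) -> None:
    rows = [{"individual": h.individual_id, "haplotype": h.haplotype_index,
             "population": h.population_id, "subspecies": h.subspecies,
             "recombinant": int(h.recombinant)} for h in alleles.haplotypes]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


# ----------------------------------------------------------------- trajectories

def write_coords(path, replicate: Replicate) -> None:
    """Write the CACOORDS text container (round-trips bit-exactly)."""
    dt = (replicate.times_ps[1] - replicate.times_ps[0]
          if replicate.n_frames > 1 else 0.0)
    with open(path, "w") as fh:
        fh.write("# CACOORDS 1\n")
        fh.write(f"n_atoms {replicate.n_atoms}\n")
        fh.write(f"frame_interval_ps {float(dt)!r}\n")
        fh.write("residue_ids " + " ".join(str(int(r)) for r in replicate.residue_ids)
                 + "\n")
        for f in range(replicate.n_frames):
            fh.write(f"frame {float(replicate.times_ps[f])!r}\n")
            for x, y, z in replicate.coords[f]:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_coords(path) -> Replicate:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# CACOORDS"):
            raise ValueError("unreadable header: not a CACOORDS file")
        n_atoms = int(fh.readline().split()[1])
        fh.readline()  # frame_interval_ps (recoverable from times)
        residue_ids = np.array([int(t) for t in fh.readline().split()[1:]])
        if residue_ids.size != n_atoms:
            raise ValueError("residue_ids length does not match n_atoms")
        times, frames = [], []
        for line in fh:
            tokens = line.split()
            if tokens[0] == "frame":
                times.append(float(tokens[1]))
                frames.append(np.empty((n_atoms, 3)))
                row = 0
            else:
                frames[-1][row] = [float(tokens[0]), float(tokens[1]), float(tokens[2])]
                row += 1
    return Replicate(np.array(frames), np.array(times), residue_ids)


def write_trajectory_pdb(path, replicate: Replicate) -> None:
    """Cα-only multi-model PDB; frame times go to REMARK records."""
    with open(path, "w") as fh:
        for f in range(replicate.n_frames):
            fh.write(f"MODEL     {f + 1:>4}\n")
            fh.write(f"REMARK   6 TIME_PS {replicate.times_ps[f]:.3f}\n")
            for i, rid in enumerate(replicate.residue_ids):
                x, y, z = replicate.coords[f, i]
                fh.write(
                    f"ATOM  {i + 1:>5}  CA  ALA A{int(rid):>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory_pdb(path) -> Replicate:
    """Read Cα atoms from a multi-model PDB; other atoms are skipped (logged)."""
    frames: list[list[list[float]]] = []
    ids_per_model: list[list[int]] = []
    times: list[float] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                frames.append([])
                ids_per_model.append([])
                times.append(float(len(times)))
            elif line.startswith("REMARK   6 TIME_PS") and frames:
                times[-1] = float(line.split()[-1])
            elif line.startswith(("ATOM", "HETATM")):
                if line[12:16].strip() != "CA":
                    skipped += 1
                    continue
                if not frames:  # single-model file without MODEL cards
                    frames.append([])
                    ids_per_model.append([])
                    times.append(0.0)
                frames[-1].append([float(line[30:38]), float(line[38:46]),
                                   float(line[46:54])])
                ids_per_model[-1].append(int(line[22:26]))
    if not frames:
        raise ValueError("no models found in PDB")
    if skipped:
        log.info("skipped %d non-CA atoms while reading %s", skipped, path)
    first = ids_per_model[0]
    for m, ids in enumerate(ids_per_model[1:], start=2):
        if ids != first:
            diff = set(first).symmetric_difference(ids)
            raise ValueError(
                f"model {m} residue mismatch vs model 1 (residues {sorted(diff)})")
    return Replicate(np.array(frames), np.array(times), np.array(first))


# ------------------------------------------------------------------- SS labels

def write_ss_labels(path, frames: list[str]) -> None:
    Path(path).write_text("\n".join(frames) + "\n")


def read_ss_labels(path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len({len(ln) for ln in lines}) > 1:
        raise ValueError("inconsistent label row lengths")
    return lines
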