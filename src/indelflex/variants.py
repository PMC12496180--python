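"""Indel discovery in allelic coding sequences and population summaries.

Coordinates are 1-based inclusive throughout: nucleotide positions refer to
the ungapped reference CDS, amino-acid positions to the reference protein.
Ambiguously placed indels (inside repeats) are normalised to their 3'-most
equivalent placement before naming.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from ._align import Alignment, global_align

_NT = set("ACGTN")


@dataclass(frozen=True)
class Haplotype:
    """One of a diploid individual's two allele sequences."""

    individual_id: str
    haplotype_index: int  # 1 or 2
    population_id: str
    subspecies: str
    cds: str
    recombinant: bool = False
    aligned_row: str | None = None

    def __post_init__(self) -> None:
        if self.haplotype_index not in (1, 2):
            raise ValueError("haplotype_index must be 1 or 2")


@dataclass
class AlleleSet:
    """Reference CDS plus a set of allelic haplotype sequences."""

    reference_cds: str
    haplotypes: list[Haplotype]
    reference_protein: str = ""

    def __post_init__(self) -> None:
        if len(self.reference_cds) % 3 != 0:
            raise ValueError("reference CDS length must be divisible by 3")
        if not self.reference_protein:
            self.reference_protein = str(Seq(self.reference_cds).translate())
        counts: dict[str, int] = defaultdict(int)
        for h in self.haplotypes:
            counts[h.individual_id] += 1
        bad = [k for k, v in counts.items() if v > 2]
        if bad:
            raise ValueError(f"individuals with >2 haplotypes: {bad}")


@dataclass(frozen=True)
class IndelCall:
    kind: str  # "deletion" | "insertion"
    nt_start: int
    nt_end: int
    aa_start: int
    aa_end: int
    aa_letters: str
    in_frame: bool
    hgvs: str
    nt_length: int


@dataclass
class FrequencyTable:
    """Per-population and per-indel tallies of indel carriers."""

    per_population: pd.DataFrame  # population, hgvs, carriers, total, frequency (+ excl-recombinant)
    per_indel: pd.DataFrame  # hgvs, carriers, homozygotes (+ excl-recombinant)


def _validate_nt(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - _NT
    if bad:
        raise ValueError(f"{name} contains non-nucleotide symbols: {sorted(bad)}")


def align_to_reference(reference: str, haplotype: str, *, match: float = 2.0,
                       mismatch: float = -3.0, gap_open: float = 11.0,
                       gap_extend: float = 1.0) -> Alignment:
    """Global affine-gap alignment of a haplotype against the reference CDS.

    Defaults strongly prefer one contiguous gap over split gaps, so a clean
    codon deletion aligns as a single gap run. ``N`` never counts as a match.
    Ties break deterministically: diagonal, then gap in the haplotype, then
    gap in the reference.
    """
    _validate_nt(reference, "reference")
    _validate_nt(haplotype, "haplotype")
    return global_align(reference, haplotype, match=match, mismatch=mismatch,
                        gap_open=gap_open, gap_extend=gap_extend, wildcard="N")


def _shift_deletion_right(reference: str, start: int, end: int) -> tuple[int, int]:
    # 1-based inclusive; shifting by one is equivalence-preserving iff the
    # base entering the gap equals the base leaving it.
    while end < len(reference) and reference[start - 1] == reference[end]:
        start += 1
        end += 1
    return start, end


def _shift_insertion_right(reference: str, after: int, ins: str) -> tuple[int, str]:
    while after < len(reference) and ins[0] == reference[after]:
        ins = ins[1:] + reference[after]
        after += 1
    return after, ins


def _aa_span(nt_start: int, nt_end: int) -> tuple[int, int]:
    return (nt_start + 2) // 3, (nt_end + 2) // 3


def _protein_deletion_span(ref_prot: str, mut_prot: str, k: int) -> tuple[int, int] | None:
    """1-based span of a clean k-residue deletion explaining mut_prot, 3'-most."""
    i = 0
    while i < len(mut_prot) and ref_prot[i] == mut_prot[i]:
        i += 1
    if ref_prot[:i] + ref_prot[i + k:] != mut_prot:
        return None
    start, end = i + 1, i + k
    while end < len(ref_prot) and ref_prot[start - 1] == ref_prot[end]:
        start += 1
        end += 1
    return start, end


def _deletion_hgvs(protein: str, aa_start: int, aa_end: int) -> str:
    first = protein[aa_start - 1] if aa_start <= len(protein) else "X"
    if aa_start == aa_end:
        return f"p.{first}{aa_start}del"
    last = protein[aa_end - 1] if aa_end <= len(protein) else "X"
    return f"p.{first}{aa_start}_{last}{aa_end}del"


def call_indels(reference_row: str, haplotype_row: str,
                reference_protein: str | None = None) -> list[IndelCall]:
    """Call one indel per maximal gap run in an aligned reference/haplotype pair.

    Gap runs in the haplotype row are deletions, runs in the reference row
    insertions. Calls are right-normalised (3'-most placement) and named in
    HGVS protein style for deletions; the amino-acid span covers every codon
    overlapping the nucleotide span.
    """
    if len(reference_row) != len(haplotype_row):
        raise ValueError("aligned rows differ in length")
    reference = reference_row.replace("-", "")
    if reference_protein is None:
        reference_protein = str(Seq(reference).translate())

    calls: list[IndelCall] = []
    col = 0
    ref_pos = 0  # ungapped reference position consumed so far
    n_cols = len(reference_row)
    while col < n_cols:
        r, h = reference_row[col], haplotype_row[col]
        if r != "-" and h == "-":  # deletion run
            run = 0
            start_pos = ref_pos + 1
            while col < n_cols and reference_row[col] != "-" and haplotype_row[col] == "-":
                run += 1
                ref_pos += 1
                col += 1
            nt_start, nt_end = _shift_deletion_right(reference, start_pos, start_pos + run - 1)
            aa_start, aa_end = _aa_span(nt_start, nt_end)
            if run % 3 == 0:
                # in-frame: name at the protein level (3'-most residue span)
                mut_prot = str(Seq(reference[:nt_start - 1] + reference[nt_end:])
                               .translate())
                span = _protein_deletion_span(reference_protein, mut_prot, run // 3)
                if span is not None:
                    aa_start, aa_end = span
            calls.append(IndelCall(
                kind="deletion", nt_start=nt_start, nt_end=nt_end,
                aa_start=aa_start, aa_end=aa_end,
                aa_letters=reference_protein[aa_start - 1:aa_end],
                in_frame=(run % 3 == 0),
                hgvs=_deletion_hgvs(reference_protein, aa_start, aa_end),
                nt_length=run))
        elif r == "-" and h != "-":  # insertion run
            ins = []
            after = ref_pos  # inserted between reference positions after, after+1
            while col < n_cols and reference_row[col] == "-":
                ins.append(haplotype_row[col])
                col += 1
            ins_seq = "".join(c for c in ins if c != "-")
            after, ins_seq = _shift_insertion_right(reference, after, ins_seq)
            run = len(ins_seq)
            nt_start, nt_end = after, after + 1
            aa_start, aa_end = _aa_span(max(nt_start, 1), min(nt_end, len(reference)))
            calls.append(IndelCall(
                kind="insertion", nt_start=nt_start, nt_end=nt_end,
                aa_start=aa_start, aa_end=aa_end, aa_letters="",
                in_frame=(run % 3 == 0),
                hgvs=f"c.{after}_{after + 1}ins{ins_seq}",
                nt_length=run))
        else:
            if r != "-":
                ref_pos += 1
            col += 1
    calls.sort(key=lambda c: (c.nt_start, c.nt_end, c.kind))
    return calls


def call_allele_set(alleles: AlleleSet, **aligner_kwargs) -> dict[tuple[str, int], list[IndelCall]]:
    """Align every haplotype to the reference and call indels.

    Pre-aligned rows (from a generator or an external aligner) are used as-is.
    Returns calls keyed by (individual_id, haplotype_index).
    """
    out: dict[tuple[str, int], list[IndelCall]] = {}
    for h in alleles.haplotypes:
        if h.aligned_row is not None:
            ref_row = aligner_kwargs.get("reference_row")
            if ref_row is None:
                raise ValueError("pre-aligned rows need reference_row")
            calls = call_indels(ref_row, h.aligned_row, alleles.reference_protein)
        else:
            aln = align_to_reference(alleles.reference_cds, h.cds)
            calls = call_indels(aln.a, aln.b, alleles.reference_protein)
        out[(h.individual_id, h.haplotype_index)] = calls
    return out


def allele_frequency(alleles: AlleleSet,
                     calls: dict[tuple[str, int], list[IndelCall]]) -> FrequencyTable:
    """Tabulate per-population allele frequencies and homozygote counts.

    Emits both all-haplotype tallies and tallies excluding haplotypes with
    the recombinant flag set; frequencies are carriers / observed haplotypes.
    """
    haps_by_key = {(h.individual_id, h.haplotype_index): h for h in alleles.haplotypes}
    missing = set(calls) - set(haps_by_key)
    if missing:
        raise KeyError(f"calls for unknown haplotypes: {sorted(missing)}")

    all_hgvs = sorted({c.hgvs for cl in calls.values() for c in cl})
    populations = sorted({h.population_id for h in alleles.haplotypes})
    pop_rows = []
    for pop in populations:
        pop_haps = [h for h in alleles.haplotypes if h.population_id == pop]
        pop_nr = [h for h in pop_haps if not h.recombinant]
        for hgvs in all_hgvs:
            def carries(h: Haplotype) -> bool:
                key = (h.individual_id, h.haplotype_index)
                return any(c.hgvs == hgvs for c in calls.get(key, []))
            carriers = sum(carries(h) for h in pop_haps)
            carriers_nr = sum(carries(h) for h in pop_nr)
            pop_rows.append({
                "population": pop, "hgvs": hgvs,
                "carriers": carriers, "total": len(pop_haps),
                "frequency": carriers / len(pop_haps) if pop_haps else 0.0,
                "carriers_excl_recombinant": carriers_nr,
                "total_excl_recombinant": len(pop_nr),
                "frequency_excl_recombinant":
                    carriers_nr / len(pop_nr) if pop_nr else 0.0,
            })

    indel_rows = []
    for hgvs in all_hgvs:
        carrier_keys = [k for k, cl in calls.items() if any(c.hgvs == hgvs for c in cl)]
        by_ind: dict[str, int] = defaultdict(int)
        by_ind_nr: dict[str, int] = defaultdict(int)
        n_nr = 0
        for k in carrier_keys:
            h = haps_by_key[k]
            by_ind[h.individual_id] += 1
            if not h.recombinant:
                by_ind_nr[h.individual_id] += 1
                n_nr += 1
        indel_rows.append({
            "hgvs": hgvs,
            "carriers": len(carrier_keys),
            "homozygotes": sum(1 for v in by_ind.values() if v == 2),
            "carriers_excl_recombinant": n_nr,
            "homozygotes_excl_recombinant":
                sum(1 for v in by_ind_nr.values() if v == 2),
        })

    return FrequencyTable(
        per_population=pd.DataFrame(
            pop_rows, columns=["population", "hgvs", "carriers", "total", "frequency",
                               "carriers_excl_recombinant", "total_excl_recombinant",
                               "frequency_excl_recombinant"]),
        per_indel=pd.DataFrame(
            indel_rows, columns=["hgvs", "carriers", "homozygotes",
                                 "carriers_excl_recombinant",
                                 "homozygotes_excl_recombinant"]))
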