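"""Neoepitope extraction and tandem-minigene (TMG) design.

Each protein-altering somatic variant is turned into a *minigene*: the
mutant residue(s) flanked by up to 12 wild-type amino acids on either
side.  For a missense SNV this yields a 25-mer (shorter near a protein
terminus — the maximum available flank is used).  For a frameshift the
minigene is the (<=12-aa) wild-type prefix followed by every novel
residue up to, but excluding, the first stop codon; when no stop is
reached, translation continues past the CDS into the 3' cDNA and the
peptide runs to the transcript end.

Minigenes are concatenated, in order, into tandem minigenes (TMGs) and
given a deterministic nucleotide realization whose translation equals
the peptide string and which is free of the EcoRI (GAATTC) and BamHI
(GGATCC) sites used for cloning.

Coordinates in this module are 1-based, inclusive, in CDS space.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DataError,
    DesignError,
    FormatError,
    NonsenseVariantError,
    ReferenceMismatchError,
    SynonymousVariantError,
)
from .variants import VariantClass

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "CodingVariant",
    "NeoepitopePeptide",
    "TandemMinigene",
    "MinimalEpitope",
    "TranslationResult",
    "DEFAULT_FLANK",
    "DEFAULT_TMG_CAPACITY",
    "DEFAULT_FORBIDDEN_SITES",
    "apply_variant_to_cdna",
    "translate_cds",
    "extract_neoepitope",
    "assemble_tmgs",
    "back_translate",
    "dedupe_peptides",
    "read_transcripts_fasta",
    "write_transcripts_fasta",
    "write_peptides_fasta",
    "write_tmg_fasta",
    "write_peptide_report",
]

DEFAULT_FLANK = 12
DEFAULT_TMG_CAPACITY = 16  # ceil(201/16) = 13 TMGs for the 201-minigene design
DEFAULT_FORBIDDEN_SITES = ("GAATTC", "GGATCC")  # EcoRI, BamHI
DEFAULT_STOP_CODON = "TAA"

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE.stop_codons})
AA_TO_CODONS: dict = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

#: Deterministic fallback codon per residue (most-used human codon).
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "*": "TGA",
}

_DNA = set("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """A coding transcript on its coding strand, with CDS bounds in cDNA
    coordinates (1-based, inclusive)."""

    transcript_id: str
    cdna: str
    cds_start: int
    cds_end: int
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        bad = set(self.cdna) - _DNA
        if bad:
            raise DataError(
                f"{self.transcript_id}: cDNA contains non-ACGT symbol(s) "
                f"{sorted(bad)} (uppercase ACGT required, N rejected)"
            )
        if not (1 <= self.cds_start <= self.cds_end <= len(self.cdna)):
            raise DataError(f"{self.transcript_id}: CDS bounds outside cDNA")
        if self.cds_end - self.cds_start + 1 < 3:
            raise DataError(f"{self.transcript_id}: CDS shorter than one codon")

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]

    @property
    def three_prime_utr(self) -> str:
        return self.cdna[self.cds_end :]


@dataclass(frozen=True)
class CodingVariant:
    """A somatic variant lifted to CDS space (VCF-style anchored alleles)."""

    transcript_id: str
    cds_position: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    variant_key: str = ""

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise DataError(f"{self.variant_key}: cds_position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"{self.variant_key}: ref and alt are identical")
        if self.variant_class is VariantClass.SNV and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise DataError(f"{self.variant_key}: SNV alleles must be single bases")

    @property
    def frameshift(self) -> bool:
        return (len(self.alt_allele) - len(self.ref_allele)) % 3 != 0


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    hit_stop: bool
    stop_codon_index: Optional[int]  # 1-based codon number of the stop
    partial_codon: bool  # trailing <3 nt were dropped


@dataclass(frozen=True)
class NeoepitopePeptide:
    """A mutant peptide with flank bookkeeping.

    ``mutant_start``/``mutant_end`` are 1-based positions of the mutated
    residue block within ``peptide``.  ``right_flank_len`` is ``None`` for
    frameshift tails, which have no wild-type right flank.
    """

    variant_key: str
    peptide: str
    mutant_start: int
    mutant_end: int
    left_flank_len: int
    right_flank_len: Optional[int]
    truncated_at_terminus: bool = False
    hit_stop: bool = False
    reached_transcript_end: bool = False
    gene_symbol: str = ""
    protein_change: str = ""
    source_nt: str = ""  # native codons from the edited transcript

    def __post_init__(self) -> None:
        if not self.peptide:
            raise DataError(f"{self.variant_key}: empty peptide")
        if not (1 <= self.mutant_start <= self.mutant_end <= len(self.peptide)):
            raise DataError(f"{self.variant_key}: mutant block outside peptide")
        if self.left_flank_len > DEFAULT_FLANK:
            raise DataError(f"{self.variant_key}: left flank exceeds {DEFAULT_FLANK}")
        if self.right_flank_len is not None and self.right_flank_len > DEFAULT_FLANK:
            raise DataError(f"{self.variant_key}: right flank exceeds {DEFAULT_FLANK}")


@dataclass(frozen=True)
class MinimalEpitope:
    """An externally predicted 8-11-mer HLA-binding core within a long
    peptide.  Prediction itself is out of scope; this is an input stub."""

    variant_key: str
    peptide: str
    hla_allele: str = ""

    def locate_in(self, long_peptide: NeoepitopePeptide) -> Optional[int]:
        """1-based start of the minimal epitope within the long peptide,
        or None if absent."""
        idx = long_peptide.peptide.find(self.peptide)
        return idx + 1 if idx >= 0 else None


@dataclass(frozen=True)
class TandemMinigene:
    tmg_id: str
    peptides: tuple
    aa_sequence: str
    nt_sequence: str
    capacity_used: int

    def __post_init__(self) -> None:
        if self.aa_sequence != "".join(p.peptide for p in self.peptides):
            raise DataError(f"{self.tmg_id}: aa_sequence is not the concatenation")


# ---------------------------------------------------------------------------
# Sequence editing and translation
# ---------------------------------------------------------------------------

def _edit_sequence(seq: str, position: int, ref: str, alt: str, label: str) -> str:
    observed = seq[position - 1 : position - 1 + len(ref)]
    if observed != ref:
        raise ReferenceMismatchError(
            f"{label}: reference check failed at position {position}: "
            f"expected {ref!r}, observed {observed!r}"
        )
    return seq[: position - 1] + alt + seq[position - 1 + len(ref) :]


def apply_variant_to_cdna(transcript: Transcript, variant: CodingVariant) -> str:
    """Apply the variant to the CDS and return the mutant CDS.

    Pure function: the transcript is never modified.  SNVs preserve
    length; indels shift it by the net allele-length difference.
    """
    if variant.transcript_id != transcript.transcript_id:
        raise DataError(
            f"{variant.variant_key}: variant targets {variant.transcript_id}, "
            f"not {transcript.transcript_id}"
        )
    cds = transcript.cds
    if variant.cds_position > len(cds):
        raise DataError(
            f"{variant.variant_key}: cds_position {variant.cds_position} outside "
            f"CDS of length {len(cds)}"
        )
    return _edit_sequence(
        cds, variant.cds_position, variant.ref_allele, variant.alt_allele,
        variant.variant_key or variant.transcript_id,
    )


def translate_cds(cds: str) -> TranslationResult:
    """Translate with the standard genetic code, stopping at the first
    stop codon.  A trailing partial codon is dropped and flagged."""
    if len(cds) < 3:
        raise DataError("sequence shorter than one codon")
    bad = set(cds) - _DNA
    if bad:
        raise DataError(f"non-ACGT symbol(s) in sequence: {sorted(bad)}")
    residues = []
    for codon_index in range(len(cds) // 3):
        codon = cds[3 * codon_index : 3 * codon_index + 3]
        aa = CODON_TO_AA[codon]
        if aa == "*":
            return TranslationResult(
                "".join(residues), True, codon_index + 1, False
            )
        residues.append(aa)
    return TranslationResult("".join(residues), False, None, len(cds) % 3 != 0)


# ---------------------------------------------------------------------------
# Neoepitope extraction
# ---------------------------------------------------------------------------

def _mutant_reading_frame(transcript: Transcript, variant: CodingVariant) -> str:
    """Edited sequence from the CDS start through the transcript 3' end,
    so frameshift translation can run past the original stop."""
    mutant_cds = apply_variant_to_cdna(transcript, variant)
    return mutant_cds + transcript.three_prime_utr


def _divergence(wt: str, mut: str) -> int:
    """Index of the first differing residue (== min length when one is a
    prefix of the other)."""
    limit = min(len(wt), len(mut))
    for i in range(limit):
        if wt[i] != mut[i]:
            return i
    return limit


def _matching_suffix(wt: str, mut: str, start: int) -> int:
    """Number of trailing residues shared by wt and mut, not reaching back
    before ``start``."""
    count = 0
    while (
        count < len(wt) - start
        and count < len(mut) - start
        and wt[len(wt) - 1 - count] == mut[len(mut) - 1 - count]
    ):
        count += 1
    return count


def extract_neoepitope(
    transcript: Transcript, variant: CodingVariant, flank: int = DEFAULT_FLANK
) -> NeoepitopePeptide:
    """Build the mutant minigene peptide for a protein-altering variant.

    Raises :class:`SynonymousVariantError` for silent variants and
    :class:`NonsenseVariantError` when the variant leaves no mutant
    residue to present (stop-gain at the mutated position).
    """
    wt = translate_cds(transcript.cds)
    mutant_frame = _mutant_reading_frame(transcript, variant)
    mut = translate_cds(mutant_frame)
    wt_protein, mut_protein = wt.protein, mut.protein

    if variant.variant_class is VariantClass.SNV:
        protein_pos = (variant.cds_position - 1) // 3 + 1
        if protein_pos == len(wt_protein) + 1:
            # stop-loss: read-through produces a novel C-terminal tail,
            # handled like a frameshift tail (and flagged the same way)
            if mut_protein == wt_protein:
                raise SynonymousVariantError(
                    f"{variant.variant_key}: substitution exchanges one stop "
                    "codon for another"
                )
            return _extract_frameshift(variant, wt_protein, mut, mutant_frame, flank)
        return _extract_snv(transcript, variant, wt_protein, mutant_frame, flank)
    if variant.frameshift:
        return _extract_frameshift(variant, wt_protein, mut, mutant_frame, flank)
    return _extract_inframe_indel(variant, wt_protein, mut, mutant_frame, flank)


def _extract_snv(
    transcript: Transcript,
    variant: CodingVariant,
    wt_protein: str,
    mutant_frame: str,
    flank: int,
) -> NeoepitopePeptide:
    protein_pos = (variant.cds_position - 1) // 3 + 1
    if protein_pos > len(wt_protein):
        raise DataError(
            f"{variant.variant_key}: codon {protein_pos} lies at or beyond the "
            "wild-type stop codon"
        )
    codon_start = 3 * (protein_pos - 1)
    mut_aa = CODON_TO_AA[mutant_frame[codon_start : codon_start + 3]]
    wt_aa = wt_protein[protein_pos - 1]
    if mut_aa == wt_aa:
        raise SynonymousVariantError(
            f"{variant.variant_key}: synonymous substitution ({wt_aa}{protein_pos}=)"
        )
    if mut_aa == "*":
        raise NonsenseVariantError(
            f"{variant.variant_key}: stop-gain {wt_aa}{protein_pos}* leaves no "
            "mutant residue to present"
        )
    length = len(wt_protein)
    left = min(flank, protein_pos - 1)
    right = min(flank, length - protein_pos)
    start = protein_pos - 1 - left  # 0-based in protein space
    peptide = (
        wt_protein[start : protein_pos - 1]
        + mut_aa
        + wt_protein[protein_pos : protein_pos + right]
    )
    return NeoepitopePeptide(
        variant_key=variant.variant_key,
        peptide=peptide,
        mutant_start=left + 1,
        mutant_end=left + 1,
        left_flank_len=left,
        right_flank_len=right,
        truncated_at_terminus=(left < flank or right < flank),
        gene_symbol=transcript.gene_symbol,
        protein_change=f"{wt_aa}{protein_pos}{mut_aa}",
        source_nt=mutant_frame[3 * start : 3 * (start + len(peptide))],
    )


def _extract_frameshift(
    variant: CodingVariant,
    wt_protein: str,
    mut: TranslationResult,
    mutant_frame: str,
    flank: int,
) -> NeoepitopePeptide:
    d = _divergence(wt_protein, mut.protein)
    tail = mut.protein[d:]
    if not tail:
        raise NonsenseVariantError(
            f"{variant.variant_key}: frameshift stops at the first shifted codon; "
            "no novel residue to present"
        )
    left = min(flank, d)
    start = d - left
    peptide = mut.protein[start:d] + tail
    return NeoepitopePeptide(
        variant_key=variant.variant_key,
        peptide=peptide,
        mutant_start=left + 1,
        mutant_end=len(peptide),
        left_flank_len=left,
        right_flank_len=None,
        truncated_at_terminus=(left < flank),
        hit_stop=mut.hit_stop,
        reached_transcript_end=not mut.hit_stop,
        protein_change=f"{wt_protein[d] if d < len(wt_protein) else '*'}{d + 1}fs",
        source_nt=mutant_frame[3 * start : 3 * (start + len(peptide))],
    )


def _extract_inframe_indel(
    variant: CodingVariant,
    wt_protein: str,
    mut: TranslationResult,
    mutant_frame: str,
    flank: int,
) -> NeoepitopePeptide:
    mut_protein = mut.protein
    d = _divergence(wt_protein, mut_protein)
    suffix = _matching_suffix(wt_protein, mut_protein, d)
    block_start, block_end = d, len(mut_protein) - suffix  # 0-based, half-open
    if block_start >= block_end:
        if len(mut_protein) == len(wt_protein):
            raise SynonymousVariantError(
                f"{variant.variant_key}: in-frame indel leaves the protein unchanged"
            )
        if len(mut_protein) < len(wt_protein) and block_start == len(mut_protein):
            # pure loss of trailing residues (or early stop): nothing novel
            raise NonsenseVariantError(
                f"{variant.variant_key}: in-frame deletion truncates the protein "
                "without a novel junction residue"
            )
        # deleted block is flanked by identical residues: present the
        # junction residue (the residue now spanning the deletion site)
        block_start = max(0, block_start - 1)
        block_end = block_start + 1
    left = min(flank, block_start)
    right = min(flank, len(mut_protein) - block_end)
    start = block_start - left
    peptide = mut_protein[start : block_end + right]
    label = "ins" if variant.variant_class is VariantClass.INSERTION else "del"
    return NeoepitopePeptide(
        variant_key=variant.variant_key,
        peptide=peptide,
        mutant_start=left + 1,
        mutant_end=left + (block_end - block_start),
        left_flank_len=left,
        right_flank_len=right,
        truncated_at_terminus=(left < flank or right < flank),
        hit_stop=mut.hit_stop,
        reached_transcript_end=not mut.hit_stop,
        protein_change=f"{block_start + 1}{label}{mut_protein[block_start:block_end]}",
        source_nt=mutant_frame[3 * start : 3 * (start + len(peptide))],
    )


# ---------------------------------------------------------------------------
# Back-translation and TMG assembly
# ---------------------------------------------------------------------------

def _naive_codons(aa_sequence: str, source_nt: str, codon_policy: str) -> list:
    if (
        codon_policy == "native"
        and len(source_nt) == 3 * len(aa_sequence)
        and all(
            CODON_TO_AA.get(source_nt[3 * i : 3 * i + 3]) == aa
            for i, aa in enumerate(aa_sequence)
        )
    ):
        return [source_nt[3 * i : 3 * i + 3] for i in range(len(aa_sequence))]
    try:
        return [PREFERRED_CODON[aa] for aa in aa_sequence]
    except KeyError as exc:
        raise DataError(f"unknown residue {exc} in peptide") from exc


def back_translate(
    aa_sequence: str,
    codon_policy: str = "native",
    source_nt: str = "",
    forbidden_sites: Sequence[str] = DEFAULT_FORBIDDEN_SITES,
    add_start: bool = True,
    stop_codon: str = DEFAULT_STOP_CODON,
) -> str:
    """Deterministic nucleotide realization of a peptide.

    Codons come from the native edited transcript when ``codon_policy`` is
    ``"native"`` and ``source_nt`` maps onto the peptide; otherwise from a
    fixed preferred-codon table.  An ATG is prepended when ``add_start``
    is set and the first residue is not M; one stop codon is appended
    (empty ``stop_codon`` suppresses it).  Forbidden restriction motifs
    are then removed by synonymous codon swaps scanning left to right.
    """
    if not aa_sequence:
        raise DataError("cannot back-translate an empty peptide")
    codons = _naive_codons(aa_sequence, source_nt, codon_policy)
    prefix = "ATG" if add_start and aa_sequence[0] != "M" else ""
    suffix = stop_codon
    mutable = [False] * (len(prefix) // 3) + [True] * len(codons)
    units = ([prefix] if prefix else []) + codons
    residues = ([None] if prefix else []) + list(aa_sequence)

    for _ in range(10 * len(units) + 10):
        seq = "".join(units) + suffix
        hit = min(
            (pos for pos in (seq.find(m) for m in forbidden_sites) if pos >= 0),
            default=-1,
        )
        if hit < 0:
            return seq
        motif_len = next(
            len(m) for m in forbidden_sites if seq.startswith(m, hit)
        )
        if not _break_motif(units, residues, mutable, hit, motif_len, forbidden_sites, suffix):
            raise DesignError(
                f"cannot remove forbidden motif at position {hit} by synonymous swaps"
            )
    raise DesignError("motif removal did not converge")


def _break_motif(
    units, residues, mutable, hit, motif_len, forbidden_sites, suffix
) -> bool:
    """Try synonymous replacements in codons overlapping seq[hit:hit+motif_len]."""
    first = hit // 3
    last = min((hit + motif_len - 1) // 3, len(units) - 1)
    for idx in range(first, last + 1):
        if idx >= len(units) or not mutable[idx]:
            continue
        for candidate in AA_TO_CODONS[residues[idx]]:
            if candidate == units[idx]:
                continue
            trial = units[:]
            trial[idx] = candidate
            window = "".join(trial) + suffix
            if not any(window.startswith(m, hit) for m in forbidden_sites):
                units[idx] = candidate
                return True
    return False


def assemble_tmgs(
    peptides: Sequence[NeoepitopePeptide],
    capacity: int = DEFAULT_TMG_CAPACITY,
    codon_policy: str = "native",
    forbidden_sites: Sequence[str] = DEFAULT_FORBIDDEN_SITES,
    stop_codon: str = DEFAULT_STOP_CODON,
) -> list:
    """Chunk minigene peptides, in order, into ceil(n/capacity) TMGs.

    The nucleotide realization carries no initiator ATG of its own (the
    expression vector supplies translation context), so the translation
    of ``nt_sequence`` equals ``aa_sequence`` plus the terminal stop.
    """
    if capacity < 1:
        raise DataError("TMG capacity must be >= 1")
    if not peptides:
        logger.warning("assemble_tmgs called with no peptides")
        return []
    tmgs = []
    for k in range(ceil(len(peptides) / capacity)):
        members = tuple(peptides[k * capacity : (k + 1) * capacity])
        aa = "".join(p.peptide for p in members)
        nt = back_translate(
            aa,
            codon_policy=codon_policy,
            source_nt="".join(p.source_nt for p in members),
            forbidden_sites=forbidden_sites,
            add_start=False,
            stop_codon=stop_codon,
        )
        tmgs.append(
            TandemMinigene(
                tmg_id=f"TMG-{k + 1}",
                peptides=members,
                aa_sequence=aa,
                nt_sequence=nt,
                capacity_used=len(members),
            )
        )
    return tmgs


def dedupe_peptides(peptides: Iterable[NeoepitopePeptide]) -> list:
    """Drop exact duplicate peptide strings, keeping the first occurrence
    (e.g. the same mutation reached through two transcripts of a gene)."""
    seen: set = set()
    unique = []
    for peptide in peptides:
        if peptide.peptide not in seen:
            seen.add(peptide.peptide)
            unique.append(peptide)
    return unique


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_transcripts_fasta(path) -> list:
    """Read transcripts from FASTA with ``id|gene|cds_start|cds_end`` headers."""
    transcripts = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 4:
            raise FormatError(
                f"{path}: header {record.id!r} is not transcript_id|gene|cds_start|cds_end"
            )
        transcript_id, gene, cds_start, cds_end = parts
        transcripts.append(
            Transcript(
                transcript_id=transcript_id,
                cdna=str(record.seq).upper(),
                cds_start=int(cds_start),
                cds_end=int(cds_end),
                gene_symbol=gene,
            )
        )
    if not transcripts:
        raise FormatError(f"{path}: no FASTA records found")
    return transcripts


def write_transcripts_fasta(transcripts: Sequence[Transcript], path) -> None:
    records = [
        SeqRecord(
            Seq(t.cdna),
            id=f"{t.transcript_id}|{t.gene_symbol}|{t.cds_start}|{t.cds_end}",
            description="",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peptides_fasta(peptides: Sequence[NeoepitopePeptide], path) -> None:
    records = [
        SeqRecord(
            Seq(p.peptide),
            id=f"{p.variant_key}|{p.gene_symbol}|{p.protein_change}",
            description="",
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tmg_fasta(tmgs: Sequence[TandemMinigene], aa_path, nt_path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(t.aa_sequence), id=t.tmg_id, description="") for t in tmgs],
        str(aa_path),
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(t.nt_sequence), id=t.tmg_id, description="") for t in tmgs],
        str(nt_path),
        "fasta",
    )


def write_peptide_report(tmgs: Sequence[TandemMinigene], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "variant_key",
                "gene",
                "protein_change",
                "peptide",
                "length",
                "mutant_start",
                "mutant_end",
                "left_flank_len",
                "right_flank_len",
                "truncated_at_terminus",
                "hit_stop",
                "reached_transcript_end",
                "tmg_id",
                "position_in_tmg",
            ]
        )
        for tmg in tmgs:
            for position, p in enumerate(tmg.peptides, start=1):
                writer.writerow(
                    [
                        p.variant_key,
                        p.gene_symbol,
                        p.protein_change,
                        p.peptide,
                        len(p.peptide),
                        p.mutant_start,
                        p.mutant_end,
                        p.left_flank_len,
                        "" if p.right_flank_len is None else p.right_flank_len,
                        int(p.truncated_at_terminus),
                        int(p.hit_stop),
                        int(p.reached_transcript_end),
                        tmg.tmg_id,
                        position,
                    ]
                )
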