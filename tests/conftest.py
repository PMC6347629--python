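"""Shared fixtures and independent oracles.

The oracles here (codon table literal, brute-force filter rule, direct
entropy) are deliberately written from scratch, without importing the
implementation paths they check.
"""

import math

import numpy as np
import pytest

# Standard genetic code, written out independently of the implementation.
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
ORACLE_CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq):
    """Codon-by-codon walk; returns (protein, hit_stop)."""
    protein = []
    for i in range(len(seq) // 3):
        aa = ORACLE_CODON_TABLE[seq[3 * i : 3 * i + 3]]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def oracle_filter_passes(ev, thresholds):
    """The five consensus rules as one boolean expression."""
    evidence_ok = (
        ev.tumor_coverage >= thresholds.min_tumor_coverage
        and ev.normal_coverage >= thresholds.min_normal_coverage
        and ev.tumor_variant_reads >= thresholds.min_variant_reads
        and ev.tumor_vaf >= thresholds.min_vaf
        and (
            ev.variant_class.value != "snv"
            or len(ev.callers) >= thresholds.min_callers_snv
        )
    )
    return evidence_ok or ev.in_cosmic


def oracle_entropy(frequencies):
    return -sum(p * math.log(p) for p in frequencies if p > 0)


def oracle_frameshift_peptide(transcript, variant, flank=12):
    """Translate the fully edited cDNA from the CDS start, find the first
    residue diverging from the wild-type protein, and slice up to `flank`
    wild-type residues before it plus the whole novel tail."""
    cds = transcript.cds
    edited = (
        cds[: variant.cds_position - 1]
        + variant.alt_allele
        + cds[variant.cds_position - 1 + len(variant.ref_allele) :]
        + transcript.three_prime_utr
    )
    wt, _ = oracle_translate(cds)
    mut, hit_stop = oracle_translate(edited)
    d = 0
    while d < min(len(wt), len(mut)) and wt[d] == mut[d]:
        d += 1
    return mut[max(0, d - flank) :], hit_stop


@pytest.fixture
def rng():
    return np.random.default_rng(20190125)


@pytest.fixture
def toy_transcript():
    """60-codon CDS (incl. stop) with short UTRs, built from a fixed seed."""
    from neoscreen import Transcript

    generator = np.random.default_rng(42)
    sense = [c for c, aa in ORACLE_CODON_TABLE.items() if aa != "*"]
    body = "".join(
        sense[i] for i in generator.integers(0, len(sense), size=58)
    )
    cds = "ATG" + body + "TAA"
    utr5, utr3 = "GGGACCTTC", "".join(
        "ACGT"[i] for i in generator.integers(0, 4, size=45)
    )
    return Transcript(
        transcript_id="TOY1",
        cdna=utr5 + cds + utr3,
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + len(cds),
        gene_symbol="TOY",
    )


def make_transcript(rng, n_codons=120, utr3="", transcript_id="TX"):
    """Random internal-stop-free transcript for property tests."""
    from neoscreen import Transcript

    sense = [c for c, aa in ORACLE_CODON_TABLE.items() if aa != "*"]
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2))
    cds = "ATG" + body + "TAA"
    return Transcript(
        transcript_id=transcript_id,
        cdna=cds + utr3,
        cds_start=1,
        cds_end=len(cds),
        gene_symbol="G",
    )
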