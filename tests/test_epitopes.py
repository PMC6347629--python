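"""Neoepitope extraction, back-translation and TMG assembly tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen.epitopes import (
    CodingVariant,
    Transcript,
    apply_variant_to_cdna,
    assemble_tmgs,
    back_translate,
    dedupe_peptides,
    extract_neoepitope,
    read_transcripts_fasta,
    translate_cds,
    write_transcripts_fasta,
)
from neoscreen.errors import (
    DataError,
    NonsenseVariantError,
    ReferenceMismatchError,
    SynonymousVariantError,
)
from neoscreen.variants import VariantClass

from conftest import (
    ORACLE_CODON_TABLE,
    make_transcript,
    oracle_frameshift_peptide,
    oracle_translate,
)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def _snv(transcript, cds_position, alt, ref=None):
    ref = ref if ref is not None else transcript.cds[cds_position - 1]
    return CodingVariant(
        transcript_id=transcript.transcript_id,
        cds_position=cds_position,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=VariantClass.SNV,
        variant_key=f"{transcript.transcript_id}:{cds_position}:{ref}>{alt}",
    )


def _indel(transcript, cds_position, ref, alt):
    cls = VariantClass.INSERTION if len(alt) > len(ref) else VariantClass.DELETION
    return CodingVariant(
        transcript_id=transcript.transcript_id,
        cds_position=cds_position,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=cls,
        variant_key=f"{transcript.transcript_id}:{cds_position}:{ref}>{alt}",
    )


class TestCdnaEditing:
    def test_snv_substitutes_in_place(self):
        t = Transcript("T", "ATGGGTGGTTAA", 1, 12)
        assert apply_variant_to_cdna(t, _snv(t, 4, "A")) == "ATGAGTGGTTAA"

    def test_insertion_extends_by_net_length(self):
        t = Transcript("T", "ATGGGTGGTTAA", 1, 12)
        mutant = apply_variant_to_cdna(t, _indel(t, 6, "T", "TGAT"))
        assert len(mutant) == 15
        assert mutant == "ATGGGTGATGGTTAA"

    def test_reference_mismatch_cites_position_and_base(self):
        t = Transcript("T", "ATGGGTGGTTAA", 1, 12)
        with pytest.raises(ReferenceMismatchError, match="position 4.*'G'"):
            apply_variant_to_cdna(t, _snv(t, 4, "T", ref="C"))


class TestTranslate:
    def test_stops_at_first_stop_codon(self):
        result = translate_cds("ATGGCTTAA")
        assert (result.protein, result.hit_stop, result.stop_codon_index) == ("MA", True, 3)

    def test_trailing_partial_codon_flagged(self):
        result = translate_cds("ATGGCTGG")
        assert (result.protein, result.hit_stop, result.partial_codon) == ("MA", False, True)

    def test_rejects_non_acgt(self):
        with pytest.raises(DataError, match="non-ACGT"):
            translate_cds("ATGNNNTAA")

    def test_matches_independent_codon_walk(self, rng):
        for _ in range(50):
            length = int(rng.integers(3, 120))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            if length < 3:
                continue
            expected_protein, expected_stop = oracle_translate(seq)
            result = translate_cds(seq)
            assert result.protein == expected_protein
            assert result.hit_stop == expected_stop


class TestSnvPeptides:
    def test_interior_snv_gives_25mer_mutant_at_13(self, rng):
        t = make_transcript(rng, n_codons=501)
        position = 3 * 99 + 1  # protein position 100
        peptide = _nonsyn_peptide(t, position, rng)
        assert len(peptide.peptide) == 25
        assert peptide.mutant_start == 13
        assert (peptide.left_flank_len, peptide.right_flank_len) == (12, 12)
        assert not peptide.truncated_at_terminus

    def test_position_12_snv_gives_24mer(self, rng):
        # the classic G12 hotspot geometry: only 11 residues precede it
        t = make_transcript(rng, n_codons=200)
        peptide = _nonsyn_peptide(t, 3 * 11 + 1, rng)  # protein position 12
        assert len(peptide.peptide) == 24
        assert peptide.mutant_start == 12
        assert peptide.left_flank_len == 11
        assert peptide.truncated_at_terminus

    def test_position_5_snv_gives_17mer(self, rng):
        t = make_transcript(rng, n_codons=200)
        peptide = _nonsyn_peptide(t, 3 * 4 + 1, rng)  # protein position 5
        assert len(peptide.peptide) == 17
        assert (peptide.left_flank_len, peptide.right_flank_len) == (4, 12)

    def test_length_law_and_wildtype_restoration(self, rng):
        for _ in range(100):
            t = make_transcript(rng, n_codons=int(rng.integers(20, 200)))
            wt_protein, _ = oracle_translate(t.cds)
            length = len(wt_protein)
            protein_pos = int(rng.integers(1, length + 1))
            position = 3 * (protein_pos - 1) + 1 + int(rng.integers(0, 3))
            peptide = _nonsyn_peptide(t, position, rng)
            if peptide is None:
                continue
            expected = min(12, protein_pos - 1) + 1 + min(12, length - protein_pos)
            assert len(peptide.peptide) == expected
            mutant_residue = peptide.peptide[peptide.mutant_start - 1]
            assert mutant_residue != wt_protein[protein_pos - 1]
            restored = (
                peptide.peptide[: peptide.mutant_start - 1]
                + wt_protein[protein_pos - 1]
                + peptide.peptide[peptide.mutant_start :]
            )
            assert restored in wt_protein

    def test_synonymous_rejected(self):
        t = Transcript("T", "ATGTTATTGGCTCATTAA", 1, 18)  # M L L A H *
        with pytest.raises(SynonymousVariantError):
            extract_neoepitope(t, _snv(t, 6, "G"))  # TTA->TTG, both Leu

    def test_stop_gain_rejected(self):
        t = Transcript("T", "ATGTTATGGGCTCATTAA", 1, 18)  # M L W A H *
        with pytest.raises(NonsenseVariantError):
            extract_neoepitope(t, _snv(t, 8, "A"))  # TGG -> TAG stop

    def test_stop_loss_read_through_flagged_like_frameshift(self):
        # stop TAA -> CAA(Q); downstream UTR provides the tail and a stop
        t = Transcript("T", "ATGGCTCATTAAGCTGCTTGA", 1, 12)
        peptide = extract_neoepitope(t, _snv(t, 10, "C"))
        assert peptide.peptide.endswith("QAA")
        assert peptide.hit_stop and not peptide.reached_transcript_end


def _nonsyn_peptide(transcript, cds_position, rng):
    ref = transcript.cds[cds_position - 1]
    for alt in "ACGT":
        if alt == ref:
            continue
        try:
            return extract_neoepitope(transcript, _snv(transcript, cds_position, alt))
        except (SynonymousVariantError, NonsenseVariantError, DataError):
            continue
    return None


class TestFrameshiftPeptides:
    def test_toy_deletion_prefix_plus_novel_tail(self, rng):
        # engineer a 1-bp deletion mid-CDS; compare against the oracle
        t = make_transcript(rng, n_codons=60)
        position = 90  # codon 30
        ref = t.cds[position - 1 : position + 1]
        variant = _indel(t, position, ref, ref[0])
        peptide = extract_neoepitope(t, variant)
        expected_tail, hit_stop = oracle_frameshift_peptide(t, variant)
        assert peptide.peptide == expected_tail
        assert peptide.hit_stop == hit_stop
        assert peptide.right_flank_len is None
        assert peptide.left_flank_len <= 12

    def test_no_downstream_stop_runs_to_transcript_end(self):
        # 3'UTR chosen stop-free in the shifted frame
        cds = "ATG" + "GCT" * 20 + "TAA"
        utr3 = "GCAGCAGCAGCAGCA"
        t = Transcript("T", cds + utr3, 1, len(cds))
        position = 10
        ref = t.cds[position - 1 : position + 1]
        variant = _indel(t, position, ref, ref[0])
        peptide = extract_neoepitope(t, variant)
        expected_tail, hit_stop = oracle_frameshift_peptide(t, variant)
        assert not hit_stop
        assert peptide.reached_transcript_end and not peptide.hit_stop
        assert peptide.peptide == expected_tail

    def test_random_frameshifts_match_edited_cdna_translation(self, rng):
        matches = 0
        for _ in range(80):
            t = make_transcript(
                rng,
                n_codons=int(rng.integers(25, 120)),
                utr3="".join("ACGT"[i] for i in rng.integers(0, 4, size=60)),
            )
            cds_len = t.cds_end - t.cds_start + 1
            position = int(rng.integers(4, cds_len - 9))
            if rng.random() < 0.5:
                ref = t.cds[position - 1]
                alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.choice([1, 2, 4]))))
            else:
                span = int(rng.choice([1, 2, 4]))
                ref = t.cds[position - 1 : position + span]
                alt = ref[0]
            variant = _indel(t, position, ref, alt)
            expected_tail, hit_stop = oracle_frameshift_peptide(t, variant)
            try:
                peptide = extract_neoepitope(t, variant)
            except NonsenseVariantError:
                # frameshift straight into a stop: oracle tail has no novel aa
                assert len(expected_tail) <= 12
                continue
            assert peptide.peptide == expected_tail
            assert peptide.hit_stop == hit_stop
            matches += 1
        assert matches > 50


class TestInframeIndels:
    def test_insertion_block_with_flanks(self, rng):
        t = make_transcript(rng, n_codons=60)
        position = 30  # codon boundary: position 30 ends codon 10
        ref = t.cds[position - 1]
        variant = _indel(t, position, ref, ref + "GATCCTAAG")  # +3 residues
        peptide = extract_neoepitope(t, variant)
        block = peptide.peptide[peptide.mutant_start - 1 : peptide.mutant_end]
        wt_protein, _ = oracle_translate(t.cds)
        assert len(block) >= 3
        assert peptide.left_flank_len <= 12 and peptide.right_flank_len <= 12
        # removing the block restores a wild-type substring
        restored = (
            peptide.peptide[: peptide.mutant_start - 1]
            + peptide.peptide[peptide.mutant_end :]
        )
        assert restored in wt_protein

    def test_clean_codon_deletion_presents_junction_residue(self):
        cds = "ATGGCTCATAAGTGGTAA"  # M A H K W *
        t = Transcript("T", cds, 1, len(cds))
        variant = _indel(t, 6, "TCAT", "T")  # removes His codon exactly
        peptide = extract_neoepitope(t, variant)
        assert peptide.mutant_end - peptide.mutant_start == 0  # single junction residue
        assert "H" not in peptide.peptide


class TestBackTranslate:
    def test_single_methionine(self):
        assert back_translate("M") == "ATG" + "TAA"

    def test_forbidden_site_from_naive_codons_is_recoded(self):
        # native codons GAA TTC spell an EcoRI site
        nt = back_translate("EF", source_nt="GAATTC", add_start=False)
        assert "GAATTC" not in nt
        protein, hit_stop = oracle_translate(nt)
        assert protein == "EF" and hit_stop

    def test_bamhi_site_across_start_codon_is_recoded(self):
        # ATG + GAT CC... contains GGATCC spanning the fixed start
        nt = back_translate("DP", source_nt="GATCCT")
        assert "GGATCC" not in nt
        protein, _ = oracle_translate(nt)
        assert protein == "MDP"

    @given(st.text(alphabet=AA_LETTERS, min_size=1, max_size=100))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_translation(self, peptide):
        nt = back_translate(peptide, add_start=False)
        protein, hit_stop = oracle_translate(nt)
        assert protein == peptide and hit_stop
        assert "GAATTC" not in nt and "GGATCC" not in nt


class TestTmgAssembly:
    def _peptides(self, n, rng):
        peptides = []
        for index in range(50):
            t = make_transcript(rng, n_codons=400, transcript_id=f"TX{index}")
            for position in range(40, 1150, 30):
                peptide = _nonsyn_peptide(t, position, rng)
                if peptide is not None:
                    peptides.append(peptide)
                if len(peptides) == n:
                    return peptides
        raise AssertionError("could not build enough peptides")

    @pytest.mark.parametrize("n, capacity, expected", [(201, 16, 13), (16, 16, 1), (17, 16, 2)])
    def test_packing_arithmetic(self, n, capacity, expected, rng):
        base = self._peptides(25, rng)
        peptides = [base[i % len(base)] for i in range(n)]
        tmgs = assemble_tmgs(peptides, capacity=capacity)
        assert len(tmgs) == expected
        assert [t.capacity_used for t in tmgs][-1] == n - capacity * (expected - 1)
        # conservation and order
        assert [p.peptide for t in tmgs for p in t.peptides] == [p.peptide for p in peptides]

    def test_nt_realization_translates_and_avoids_sites(self, rng):
        tmgs = assemble_tmgs(self._peptides(40, rng), capacity=16)
        for tmg in tmgs:
            protein, hit_stop = oracle_translate(tmg.nt_sequence)
            assert protein == tmg.aa_sequence and hit_stop
            assert "GAATTC" not in tmg.nt_sequence
            assert "GGATCC" not in tmg.nt_sequence

    def test_empty_input_empty_output(self):
        assert assemble_tmgs([]) == []

    def test_dedupe_keeps_first(self, rng):
        peptides = self._peptides(5, rng)
        assert dedupe_peptides(peptides + peptides) == peptides


def test_transcripts_fasta_round_trip(tmp_path, rng):
    transcripts = [make_transcript(rng, n_codons=30, transcript_id=f"TX{i}") for i in range(3)]
    path = tmp_path / "tx.fasta"
    write_transcripts_fasta(transcripts, path)
    assert read_transcripts_fasta(path) == transcripts
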