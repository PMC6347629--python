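"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes,
so each stage is testable offline:

* random coding transcripts (ATG start, internal-stop-free CDS, UTRs);
* planted somatic variants (SNV / insertion / deletion) with negative
  binomial tumor/normal depth and Beta-distributed clonal VAF, observed
  by an ensemble of four SNV callers (two of which also call indels),
  each with its own sensitivity and false-positive rate — false calls
  carry weak evidence (<= 3 supporting reads, one caller) by design;
* sorted-subset TCR-beta repertoires whose clone sizes follow a
  subset-specific Zipf law, ordering expected clonality
  TEMRA >= TEM > TCM > TN, with known reactive clonotypes spiked into
  memory subsets only, at frequencies of 0.0007%-0.02% of productive
  templates, and template counts drawn multinomially at the configured
  sequencing depth (defaults within the 2x10^4 - 1x10^6 cell range of
  real sorted samples).

Everything is driven by one integer seed; identical configuration and
seed reproduce identical outputs byte for byte.  Callers are simulated
independently of each other (real inter-caller evidence correlation is
unknown), and no read-level data (FASTQ/BAM) is produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .epitopes import CODON_TO_AA, Transcript, translate_cds
from .errors import DataError
from .repertoire import Clonotype, KnownTCR, RepertoireSample, Subset, write_repertoire
from .variants import Caller, CallerCall, INDEL_CALLERS, VariantClass, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "CallerProfile",
    "SubsetProfile",
    "SimulationConfig",
    "TrueVariant",
    "SimulatedCalls",
    "SpikeTruth",
    "RepertoireSimulation",
    "gen_transcriptome",
    "gen_variants_and_calls",
    "gen_repertoires",
    "write_caller_vcf",
    "write_ground_truth",
    "write_known_tcrs",
    "read_known_tcrs",
]

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")
_BASES = np.array(list("ACGT"))

TRBV_GENES = tuple(f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 10, 11, 12, 19, 20, 28))
TRBJ_GENES = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 5))


@dataclass(frozen=True)
class CallerProfile:
    """Detection behaviour of one caller: per-true-variant sensitivity and
    expected false positives per true-variant slot."""

    sensitivity: float
    fp_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and self.fp_rate >= 0.0):
            raise DataError("sensitivity must be in [0,1] and fp_rate >= 0")


@dataclass(frozen=True)
class SubsetProfile:
    """Repertoire structure of one sorted subset: unique clones, sequencing
    depth (templates), and the Zipf exponent of the clone-size law."""

    n_clones: int
    depth: int
    zipf_alpha: float

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.depth < 1 or self.zipf_alpha <= 0:
            raise DataError("subset profile values must be positive")


def _default_caller_profiles() -> Dict[Caller, CallerProfile]:
    return {
        Caller.MUTECT: CallerProfile(0.95, 0.03),
        Caller.STRELKA: CallerProfile(0.95, 0.03),
        Caller.VARSCAN2: CallerProfile(0.90, 0.05),
        Caller.SOMATIC_SNIPER: CallerProfile(0.80, 0.08),
    }


def _default_subset_profiles() -> Dict[Subset, SubsetProfile]:
    # Richness falls and clonal dominance rises with differentiation;
    # depth sits inside the 2e4-1e6 template range of sorted samples.
    return {
        Subset.TN: SubsetProfile(20_000, 100_000, 1.05),
        Subset.TCM: SubsetProfile(8_000, 100_000, 1.25),
        Subset.TEM: SubsetProfile(4_000, 100_000, 1.50),
        Subset.TEMRA: SubsetProfile(2_000, 100_000, 1.60),
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    # transcriptome
    n_transcripts: int = 30
    cds_length_range: Tuple[int, int] = (150, 900)  # nt, incl. stop codon
    utr5_length_range: Tuple[int, int] = (9, 30)
    utr3_length_range: Tuple[int, int] = (30, 120)
    # variants
    n_snv: int = 60
    n_insertion: int = 12
    n_deletion: int = 12
    caller_profiles: Dict[Caller, CallerProfile] = field(
        default_factory=_default_caller_profiles
    )
    tumor_mean_depth: float = 80.0
    normal_mean_depth: float = 60.0
    depth_dispersion: float = 8.0  # negative binomial size parameter
    vaf_beta: Tuple[float, float] = (20.0, 30.0)  # clonal tumor VAF ~ Beta(20,30)
    cosmic_fraction: float = 0.05
    rna_support_fraction: float = 0.7
    # repertoires
    subset_profiles: Dict[Subset, SubsetProfile] = field(
        default_factory=_default_subset_profiles
    )
    spike_frequency_range: Tuple[float, float] = (7e-6, 2e-4)  # 0.0007%-0.02%
    n_spikes: int = 3
    spike_subsets: Tuple[str, ...] = ("TCM", "TEM", "TEMRA")
    nonproductive_fraction: float = 0.15
    cdr3_codon_range: Tuple[int, int] = (8, 14)  # body codons between C...F
    n_patients: int = 6

    def __post_init__(self) -> None:
        # accept plain mappings (e.g. parsed from YAML) for nested profiles
        self.caller_profiles = {
            Caller(k): (v if isinstance(v, CallerProfile) else CallerProfile(**v))
            for k, v in self.caller_profiles.items()
        }
        self.subset_profiles = {
            Subset(k): (v if isinstance(v, SubsetProfile) else SubsetProfile(**v))
            for k, v in self.subset_profiles.items()
        }
        for probability in (
            self.cosmic_fraction,
            self.rna_support_fraction,
            self.nonproductive_fraction,
        ):
            if not 0.0 <= probability <= 1.0:
                raise DataError("fractions must lie in [0, 1]")
        lo, hi = self.spike_frequency_range
        if not (0.0 < lo <= hi < 1.0):
            raise DataError("spike_frequency_range must lie within (0, 1)")
        if self.n_transcripts < 1 or self.n_patients < 1:
            raise DataError("sizes must be positive")


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def gen_transcriptome(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> List[Transcript]:
    """Random transcripts: UTR5 + (ATG ... internal-stop-free ... stop) + UTR3."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sense = np.array(SENSE_CODONS)
    transcripts = []
    lo, hi = cfg.cds_length_range
    for index in range(cfg.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))  # incl. stop codon
        body = "".join(sense[rng.integers(0, len(sense), size=n_codons - 2)])
        cds = "ATG" + body + STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
        utr5 = _random_dna(rng, int(rng.integers(*cfg.utr5_length_range)))
        utr3 = _random_dna(rng, int(rng.integers(*cfg.utr3_length_range)))
        transcripts.append(
            Transcript(
                transcript_id=f"TX{index + 1:04d}",
                cdna=utr5 + cds + utr3,
                cds_start=len(utr5) + 1,
                cds_end=len(utr5) + len(cds),
                gene_symbol=f"GENE{index + 1}",
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# Variants and ensemble caller output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueVariant:
    key: VariantKey
    transcript_id: str
    cds_position: int
    variant_class: VariantClass
    protein_effect: str  # missense|synonymous|nonsense|frameshift|inframe
    in_cosmic: bool
    rna_supported: bool
    tumor_coverage: int
    normal_coverage: int
    true_vaf: float
    detected_by: Tuple[Caller, ...]


@dataclass
class SimulatedCalls:
    calls: List[CallerCall]
    cosmic_keys: set
    rna_keys: set
    true_variants: List[TrueVariant]
    false_positive_keys: set


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    return int(rng.negative_binomial(dispersion, dispersion / (dispersion + mean)))


def _snv_effect(transcript: Transcript, cds_position: int, alt: str) -> str:
    cds = transcript.cds
    codon_index = (cds_position - 1) // 3
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    offset = (cds_position - 1) % 3
    mutant = codon[:offset] + alt + codon[offset + 1 :]
    wt_aa, mut_aa = CODON_TO_AA[codon], CODON_TO_AA[mutant]
    if mut_aa == wt_aa:
        return "synonymous"
    if mut_aa == "*":
        return "nonsense"
    return "missense"


def gen_variants_and_calls(
    cfg: SimulationConfig,
    transcripts: Sequence[Transcript],
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCalls:
    """Plant true variants and emit the ensemble caller call tables.

    Each caller detects each true variant independently with its
    configured sensitivity (indels only from the two indel callers) and
    contributes Poisson-many false positives with weak evidence (one
    caller, <= 3 variant reads).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    occupied: set = set()
    true_variants: List[TrueVariant] = []
    calls: List[CallerCall] = []
    cosmic_keys: set = set()
    rna_keys: set = set()
    alpha, beta = cfg.vaf_beta
    snv_callers = sorted(cfg.caller_profiles, key=lambda c: c.value)
    indel_callers = [c for c in snv_callers if c in INDEL_CALLERS]

    def _place(margin: int) -> Tuple[Transcript, int]:
        # rejection-sample a free CDS position, away from start/stop codons
        for _ in range(10_000):
            transcript = transcripts[int(rng.integers(0, len(transcripts)))]
            cds_len = transcript.cds_end - transcript.cds_start + 1
            position = int(rng.integers(4, cds_len - 2 - margin))
            span = {(transcript.transcript_id, position + d) for d in range(-6, margin + 7)}
            if not span & occupied:
                occupied.update(span)
                return transcript, position
        raise DataError("could not place variant; transcriptome too small")

    def _emit(transcript, cds_position, ref, alt, variant_class, effect, callers):
        key = VariantKey(
            transcript.transcript_id,
            transcript.cds_start + cds_position - 1,
            ref,
            alt,
        )
        tumor_cov = _negbin(rng, cfg.tumor_mean_depth, cfg.depth_dispersion)
        normal_cov = _negbin(rng, cfg.normal_mean_depth, cfg.depth_dispersion)
        vaf = float(rng.beta(alpha, beta))
        in_cosmic = bool(rng.random() < cfg.cosmic_fraction)
        rna = bool(rng.random() < cfg.rna_support_fraction)
        detected = []
        for caller in callers:
            profile = cfg.caller_profiles[caller]
            reads = int(rng.binomial(tumor_cov, vaf)) if tumor_cov > 0 else 0
            if reads > 0 and rng.random() < profile.sensitivity:
                detected.append(caller)
                calls.append(
                    CallerCall(
                        key=key,
                        caller=caller,
                        variant_class=variant_class,
                        tumor_coverage=tumor_cov,
                        normal_coverage=normal_cov,
                        tumor_variant_reads=reads,
                    )
                )
        if in_cosmic:
            cosmic_keys.add(key)
        if rna:
            rna_keys.add(key)
        true_variants.append(
            TrueVariant(
                key=key,
                transcript_id=transcript.transcript_id,
                cds_position=cds_position,
                variant_class=variant_class,
                protein_effect=effect,
                in_cosmic=in_cosmic,
                rna_supported=rna,
                tumor_coverage=tumor_cov,
                normal_coverage=normal_cov,
                true_vaf=vaf,
                detected_by=tuple(detected),
            )
        )

    for _ in range(cfg.n_snv):
        transcript, position = _place(margin=0)
        ref = transcript.cds[position - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        _emit(
            transcript,
            position,
            ref,
            alt,
            VariantClass.SNV,
            _snv_effect(transcript, position, alt),
            snv_callers,
        )

    for _ in range(cfg.n_insertion):
        transcript, position = _place(margin=0)
        length = int(rng.integers(1, 7))
        ref = transcript.cds[position - 1]
        alt = ref + _random_dna(rng, length)
        effect = "inframe" if length % 3 == 0 else "frameshift"
        _emit(transcript, position, ref, alt, VariantClass.INSERTION, effect, indel_callers)

    for _ in range(cfg.n_deletion):
        transcript, position = _place(margin=6)
        length = int(rng.integers(1, 7))
        ref = transcript.cds[position - 1 : position + length]
        alt = ref[0]
        effect = "inframe" if length % 3 == 0 else "frameshift"
        _emit(transcript, position, ref, alt, VariantClass.DELETION, effect, indel_callers)

    # false positives: weak evidence by construction (single caller, <=3 reads)
    false_positive_keys: set = set()
    n_true = len(true_variants)
    for caller in snv_callers:
        n_fp = int(rng.poisson(cfg.caller_profiles[caller].fp_rate * n_true))
        for _ in range(n_fp):
            transcript, position = _place(margin=0)
            ref = transcript.cds[position - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            key = VariantKey(
                transcript.transcript_id,
                transcript.cds_start + position - 1,
                ref,
                alt,
            )
            tumor_cov = max(4, _negbin(rng, cfg.tumor_mean_depth, cfg.depth_dispersion))
            calls.append(
                CallerCall(
                    key=key,
                    caller=caller,
                    variant_class=VariantClass.SNV,
                    tumor_coverage=tumor_cov,
                    normal_coverage=_negbin(rng, cfg.normal_mean_depth, cfg.depth_dispersion),
                    tumor_variant_reads=int(rng.integers(1, 4)),
                )
            )
            false_positive_keys.add(key)

    return SimulatedCalls(
        calls=calls,
        cosmic_keys=cosmic_keys,
        rna_keys=rna_keys,
        true_variants=true_variants,
        false_positive_keys=false_positive_keys,
    )


# ---------------------------------------------------------------------------
# Repertoires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTruth:
    label: str
    patient_id: str
    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    subset_frequencies: Tuple[Tuple[str, float], ...]  # (subset, productive freq)


@dataclass
class RepertoireSimulation:
    samples: List[RepertoireSample]
    known: Dict[str, List[KnownTCR]]  # patient -> known reactive TCRs
    truth: List[SpikeTruth]


def _random_cdr3s(rng: np.random.Generator, n: int, codon_range: Tuple[int, int]) -> List[str]:
    lo, hi = codon_range
    lengths = rng.integers(lo, hi + 1, size=n)
    flat = rng.integers(0, len(SENSE_CODONS), size=int(lengths.sum()))
    codons = np.array(SENSE_CODONS)[flat]
    out, start = [], 0
    for length in lengths:
        body = "".join(codons[start : start + int(length)])
        out.append("TGC" + body + "TTC")  # canonical C...F bounds
        start += int(length)
    return out


def _zipf_weights(n: int, alpha: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-alpha)
    return weights / weights.sum()


def gen_repertoires(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> RepertoireSimulation:
    """Simulate sorted-subset repertoires with spiked reactive clonotypes.

    Spikes are inserted only into the configured memory subsets (never
    TN) at true frequencies sampled from the configured range, expressed
    relative to productive templates; background clone sizes follow the
    subset's Zipf law, and template counts are multinomial at depth.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    spike_subsets = {Subset(s) for s in cfg.spike_subsets}
    samples: List[RepertoireSample] = []
    known: Dict[str, List[KnownTCR]] = {}
    truth: List[SpikeTruth] = []

    for patient_index in range(cfg.n_patients):
        patient_id = f"P{patient_index + 1}"
        spike_nts = _random_cdr3s(rng, cfg.n_spikes, cfg.cdr3_codon_range)
        spikes = []
        for spike_index, nt in enumerate(spike_nts):
            v = TRBV_GENES[int(rng.integers(0, len(TRBV_GENES)))]
            j = TRBJ_GENES[int(rng.integers(0, len(TRBJ_GENES)))]
            frequencies = tuple(
                (subset.value, float(rng.uniform(*cfg.spike_frequency_range)))
                for subset in sorted(spike_subsets, key=lambda s: s.value)
            )
            label = f"{patient_id}-NeoTCR{spike_index + 1}"
            spikes.append((label, nt, translate_cds(nt).protein, v, j, dict(frequencies)))
            truth.append(
                SpikeTruth(label, patient_id, nt, translate_cds(nt).protein, v, j, frequencies)
            )
        known[patient_id] = [
            KnownTCR(label=label, cdr3_nt=nt, cdr3_aa=aa, v_gene=v)
            for label, nt, aa, v, _, _ in spikes
        ]
        spike_nt_set = {nt for _, nt, _, _, _, _ in spikes}

        for subset in sorted(cfg.subset_profiles, key=lambda s: s.value):
            profile = cfg.subset_profiles[subset]
            clones = _random_cdr3s(rng, profile.n_clones, cfg.cdr3_codon_range)
            clones = [c for c in clones if c not in spike_nt_set]
            v_idx = rng.integers(0, len(TRBV_GENES), size=len(clones))
            j_idx = rng.integers(0, len(TRBJ_GENES), size=len(clones))
            n_nonproductive = int(round(len(clones) * cfg.nonproductive_fraction))
            # nonproductive clones: shifted frame, no amino-acid annotation
            depth_np = int(rng.binomial(profile.depth, cfg.nonproductive_fraction))
            depth_p = profile.depth - depth_np

            productive_clones = clones[n_nonproductive:]
            spike_list = [s for s in spikes if subset in spike_subsets]
            spike_mass = sum(s[5][subset.value] for s in spike_list)
            weights = _zipf_weights(len(productive_clones), profile.zipf_alpha)
            weights = weights * (1.0 - spike_mass)
            full_weights = np.concatenate(
                [[s[5][subset.value] for s in spike_list], weights]
            )
            counts_p = rng.multinomial(depth_p, full_weights / full_weights.sum())

            np_clones = clones[:n_nonproductive]
            counts_np = (
                rng.multinomial(
                    depth_np, _zipf_weights(len(np_clones), profile.zipf_alpha)
                )
                if np_clones and depth_np > 0
                else np.zeros(len(np_clones), dtype=int)
            )

            merged: Dict[tuple, int] = {}
            records: Dict[tuple, tuple] = {}
            for spike_offset, spike in enumerate(spike_list):
                count = int(counts_p[spike_offset])
                if count > 0:
                    identity = (spike[1], spike[3], spike[4], True)
                    merged[identity] = merged.get(identity, 0) + count
                    records[identity] = (spike[2],)
            offset = len(spike_list)
            for clone_index, nt in enumerate(productive_clones):
                count = int(counts_p[offset + clone_index])
                if count > 0:
                    identity = (
                        nt,
                        TRBV_GENES[int(v_idx[n_nonproductive + clone_index])],
                        TRBJ_GENES[int(j_idx[n_nonproductive + clone_index])],
                        True,
                    )
                    merged[identity] = merged.get(identity, 0) + count
                    records.setdefault(identity, (translate_cds(nt).protein,))
            for clone_index, nt in enumerate(np_clones):
                count = int(counts_np[clone_index])
                if count > 0:
                    identity = (
                        nt + "A",  # frame-shifted rearrangement
                        TRBV_GENES[int(v_idx[clone_index])],
                        TRBJ_GENES[int(j_idx[clone_index])],
                        False,
                    )
                    merged[identity] = merged.get(identity, 0) + count
                    records.setdefault(identity, ("",))

            clonotypes = [
                Clonotype(
                    cdr3_nt=identity[0],
                    cdr3_aa=records[identity][0],
                    v_gene=identity[1],
                    j_gene=identity[2],
                    productive=identity[3],
                    templates=count,
                )
                for identity, count in sorted(merged.items())
            ]
            samples.append(
                RepertoireSample(
                    sample_id=f"{patient_id}-{subset.value}",
                    patient_id=patient_id,
                    subset=subset,
                    clonotypes=clonotypes,
                )
            )
    return RepertoireSimulation(samples=samples, known=known, truth=truth)


# ---------------------------------------------------------------------------
# Writers (the exact dialects the upstream stages consume)
# ---------------------------------------------------------------------------

def write_caller_vcf(calls: Sequence[CallerCall], path) -> None:
    """Minimal VCF dialect: fixed 8 columns, INFO keys TCOV/NCOV/TVR."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for key, desc in (
            ("TCOV", "Tumor coverage"),
            ("NCOV", "Normal coverage"),
            ("TVR", "Tumor variant reads"),
        ):
            handle.write(
                f'##INFO=<ID={key},Number=1,Type=Integer,Description="{desc}">\n'
            )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: c.key):
            info = (
                f"TCOV={call.tumor_coverage};NCOV={call.normal_coverage};"
                f"TVR={call.tumor_variant_reads}"
            )
            handle.write(
                f"{call.key.chrom}\t{call.key.pos}\t.\t{call.key.ref}\t"
                f"{call.key.alt}\t.\tPASS\t{info}\n"
            )


def write_ground_truth(simulated: SimulatedCalls, path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "variant_key\ttranscript_id\tcds_position\tvariant_class\t"
            "protein_effect\tin_cosmic\trna_supported\ttumor_coverage\t"
            "normal_coverage\ttrue_vaf\tdetected_by\tis_true\n"
        )
        for tv in simulated.true_variants:
            handle.write(
                f"{tv.key}\t{tv.transcript_id}\t{tv.cds_position}\t"
                f"{tv.variant_class.value}\t{tv.protein_effect}\t"
                f"{int(tv.in_cosmic)}\t{int(tv.rna_supported)}\t"
                f"{tv.tumor_coverage}\t{tv.normal_coverage}\t{tv.true_vaf:.6f}\t"
                f"{','.join(c.value for c in tv.detected_by)}\t1\n"
            )
        for key in sorted(simulated.false_positive_keys):
            handle.write(f"{key}\t\t\t\t\t0\t0\t\t\t\t\t0\n")


def write_known_tcrs(known: Dict[str, List[KnownTCR]], path) -> None:
    with open(path, "w") as handle:
        handle.write("patient_id\tlabel\tcdr3_nt\tcdr3_aa\tv_gene\n")
        for patient_id in sorted(known):
            for tcr in known[patient_id]:
                handle.write(
                    f"{patient_id}\t{tcr.label}\t{tcr.cdr3_nt}\t{tcr.cdr3_aa}\t"
                    f"{tcr.v_gene}\n"
                )


def read_known_tcrs(path) -> Dict[str, List[KnownTCR]]:
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    known: Dict[str, List[KnownTCR]] = {}
    for row in table.itertuples():
        known.setdefault(row.patient_id, []).append(
            KnownTCR(
                label=row.label,
                cdr3_nt=row.cdr3_nt,
                cdr3_aa=row.cdr3_aa,
                v_gene=row.v_gene,
            )
        )
    return known
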