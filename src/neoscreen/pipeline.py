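"""End-to-end orchestration: simulate -> filter -> design -> track.

A single YAML config drives the run.  Stages execute in a fixed order,
every output is a deterministic function of the inputs and the seed, and
a JSON manifest records the config snapshot, per-stage record counts and
wall-clock times.  Stage failures abort with the stage name attached and
leave a partial manifest on disk.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .epitopes import (
    CodingVariant,
    assemble_tmgs,
    dedupe_peptides,
    extract_neoepitope,
    read_transcripts_fasta,
    write_peptide_report,
    write_peptides_fasta,
    write_tmg_fasta,
    write_transcripts_fasta,
)
from .errors import ConfigError, DataError, NeoscreenError, VariantRejected
from .repertoire import (
    Subset,
    compare_subset_clonality,
    productive_clonality,
    read_repertoire,
    track_known_tcrs,
)
from .simulate import (
    SimulationConfig,
    gen_repertoires,
    gen_transcriptome,
    gen_variants_and_calls,
    read_known_tcrs,
    write_caller_vcf,
    write_ground_truth,
    write_known_tcrs,
)
from .variants import (
    FilterThresholds,
    VariantKey,
    apply_filters,
    classify_alleles,
    merge_calls,
    parse_caller_table,
    write_decisions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "validate_config",
    "run_pipeline",
    "simulate_inputs",
]


class ThresholdSettings(BaseModel):
    min_tumor_coverage: int = Field(10, ge=0)
    min_normal_coverage: int = Field(10, ge=0)
    min_variant_reads: int = Field(4, ge=0)
    min_vaf: float = Field(0.07, ge=0.0, le=1.0)
    min_callers_snv: int = Field(2, ge=0)

    def to_thresholds(self) -> FilterThresholds:
        return FilterThresholds(**self.model_dump())


class CallerTableEntry(BaseModel):
    path: str
    caller: str
    dialect: str = "minimal_vcf"


class RepertoireEntry(BaseModel):
    path: str
    sample_id: str
    patient_id: str
    subset: str
    dialect: str = "immunoseq_tsv"


class PipelineConfig(BaseModel):
    outdir: str = "neoscreen-run"
    seed: int = 0
    log_level: str = "INFO"
    thresholds: ThresholdSettings = ThresholdSettings()
    tmg_capacity: int = Field(16, ge=1)
    forbidden_sites: List[str] = ["GAATTC", "GGATCC"]
    codon_policy: str = "native"
    match_mode: str = "nt"
    # either a simulate block (inputs are generated) or explicit input paths
    simulate: Optional[Dict] = None
    transcripts_fasta: Optional[str] = None
    caller_tables: List[CallerTableEntry] = []
    cosmic_keys: Optional[str] = None
    rna_keys: Optional[str] = None
    repertoire_samples: List[RepertoireEntry] = []
    known_tcrs: Optional[str] = None


class RunManifest(dict):
    """Config snapshot plus per-stage counts and timings (a JSON object)."""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, sort_keys=True) + "\n")


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config; problems are aggregated, not
    reported first-failure.  Defaulted fields are logged with their
    defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot read config {path}: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: config must be a mapping"])
    problems: List[str] = []
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        problems.extend(
            f"{'.'.join(str(part) for part in error['loc'])}: {error['msg']}"
            for error in exc.errors()
        )
        raise ConfigError(problems)
    for name, field_info in PipelineConfig.model_fields.items():
        if name not in raw:
            logger.info("config: %s defaulted to %r", name, getattr(cfg, name))
    if cfg.simulate is None:
        if cfg.transcripts_fasta is None:
            problems.append("transcripts_fasta required when simulate is absent")
        elif not Path(cfg.transcripts_fasta).exists():
            problems.append(f"transcripts_fasta not found: {cfg.transcripts_fasta}")
        if not cfg.caller_tables:
            problems.append("caller_tables required when simulate is absent")
        for entry in cfg.caller_tables:
            if not Path(entry.path).exists():
                problems.append(f"caller table not found: {entry.path}")
        for entry in cfg.repertoire_samples:
            if not Path(entry.path).exists():
                problems.append(f"repertoire file not found: {entry.path}")
        for attribute in ("cosmic_keys", "rna_keys", "known_tcrs"):
            value = getattr(cfg, attribute)
            if value is not None and not Path(value).exists():
                problems.append(f"{attribute} not found: {value}")
    if cfg.match_mode not in ("nt", "aa_v"):
        problems.append(f"match_mode must be 'nt' or 'aa_v', got {cfg.match_mode!r}")
    if cfg.codon_policy not in ("native", "preferred"):
        problems.append(f"codon_policy must be 'native' or 'preferred', got {cfg.codon_policy!r}")
    if problems:
        raise ConfigError(problems)
    return cfg


# ---------------------------------------------------------------------------
# Simulation stage (writes the exact dialects the later stages consume)
# ---------------------------------------------------------------------------

def simulate_inputs(cfg: PipelineConfig) -> PipelineConfig:
    """Generate inputs under <outdir>/sim and return a config pointing at
    them."""
    sim_dir = Path(cfg.outdir) / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", cfg.seed)
    sim_cfg = SimulationConfig(**overrides)

    transcripts = gen_transcriptome(sim_cfg)
    write_transcripts_fasta(transcripts, sim_dir / "transcripts.fasta")
    simulated = gen_variants_and_calls(sim_cfg, transcripts)
    caller_tables = []
    for caller in sorted({c.caller for c in simulated.calls}, key=lambda c: c.value):
        table_path = sim_dir / f"{caller.value}.vcf"
        write_caller_vcf([c for c in simulated.calls if c.caller is caller], table_path)
        caller_tables.append(
            CallerTableEntry(path=str(table_path), caller=caller.value)
        )
    (sim_dir / "cosmic_keys.txt").write_text(
        "".join(f"{key}\n" for key in sorted(simulated.cosmic_keys))
    )
    (sim_dir / "rna_keys.txt").write_text(
        "".join(f"{key}\n" for key in sorted(simulated.rna_keys))
    )
    write_ground_truth(simulated, sim_dir / "ground_truth.tsv")

    repertoires = gen_repertoires(sim_cfg)
    entries = []
    for sample in repertoires.samples:
        sample_path = sim_dir / f"{sample.sample_id}.repertoire.tsv"
        from .repertoire import write_repertoire

        write_repertoire(sample, sample_path)
        entries.append(
            RepertoireEntry(
                path=str(sample_path),
                sample_id=sample.sample_id,
                patient_id=sample.patient_id,
                subset=sample.subset.value,
            )
        )
    write_known_tcrs(repertoires.known, sim_dir / "known_tcrs.tsv")

    return cfg.model_copy(
        update={
            "simulate": None,
            "transcripts_fasta": str(sim_dir / "transcripts.fasta"),
            "caller_tables": caller_tables,
            "cosmic_keys": str(sim_dir / "cosmic_keys.txt"),
            "rna_keys": str(sim_dir / "rna_keys.txt"),
            "repertoire_samples": entries,
            "known_tcrs": str(sim_dir / "known_tcrs.tsv"),
        }
    )


def _read_key_file(path) -> set:
    if path is None:
        return set()
    return {
        VariantKey.parse(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_filter(cfg: PipelineConfig, outdir: Path, manifest: RunManifest):
    calls, parse_errors = [], 0
    cosmic = _read_key_file(cfg.cosmic_keys)
    rna = _read_key_file(cfg.rna_keys) if cfg.rna_keys else None
    for entry in cfg.caller_tables:
        result = parse_caller_table(entry.path, entry.caller, entry.dialect)
        calls.extend(result.calls)
        parse_errors += len(result.row_errors)
        cosmic |= result.cosmic_keys
        if result.rna_keys:
            rna = (rna or set()) | result.rna_keys
    evidence = merge_calls(calls, cosmic, rna)
    decisions = apply_filters(evidence, cfg.thresholds.to_thresholds())
    write_decisions(evidence, decisions, outdir / "decisions.tsv")
    manifest["variant_consensus"] = {
        "caller_calls": len(calls),
        "parse_row_errors": parse_errors,
        "variants_merged": len(evidence),
        "variants_passed": sum(d.passed for d in decisions),
        "variants_rescued": sum(d.rescue for d in decisions),
    }
    return evidence, decisions


def _stage_epitopes(cfg: PipelineConfig, outdir: Path, manifest: RunManifest, decisions):
    transcripts = {
        t.transcript_id: t for t in read_transcripts_fasta(cfg.transcripts_fasta)
    }
    peptides, rejected, outside_cds, unknown_transcript = [], 0, 0, 0
    for decision in decisions:
        if not decision.passed:
            continue
        key = decision.key
        transcript = transcripts.get(key.chrom)
        if transcript is None:
            unknown_transcript += 1
            continue
        cds_position = key.pos - transcript.cds_start + 1
        cds_length = transcript.cds_end - transcript.cds_start + 1
        if not (1 <= cds_position <= cds_length):
            outside_cds += 1
            continue
        variant = CodingVariant(
            transcript_id=transcript.transcript_id,
            cds_position=cds_position,
            ref_allele=key.ref,
            alt_allele=key.alt,
            variant_class=classify_alleles(key.ref, key.alt),
            variant_key=str(key),
        )
        try:
            peptides.append(extract_neoepitope(transcript, variant))
        except VariantRejected as exc:
            logger.info("variant rejected: %s", exc)
            rejected += 1
    unique = dedupe_peptides(peptides)
    tmgs = assemble_tmgs(
        unique,
        capacity=cfg.tmg_capacity,
        codon_policy=cfg.codon_policy,
        forbidden_sites=tuple(cfg.forbidden_sites),
    )
    write_peptides_fasta(unique, outdir / "neoepitopes.fasta")
    write_tmg_fasta(tmgs, outdir / "tmg_aa.fasta", outdir / "tmg_nt.fasta")
    write_peptide_report(tmgs, outdir / "peptide_report.tsv")
    manifest["epitope_design"] = {
        "variants_considered": sum(1 for d in decisions if d.passed),
        "unknown_transcript": unknown_transcript,
        "outside_cds": outside_cds,
        "rejected_not_protein_altering": rejected,
        "peptides": len(unique),
        "duplicates_removed": len(peptides) - len(unique),
        "tmgs": len(tmgs),
        "tmg_members": sum(t.capacity_used for t in tmgs),
    }
    return unique, tmgs


def _stage_repertoire(cfg: PipelineConfig, outdir: Path, manifest: RunManifest):
    if not cfg.repertoire_samples:
        manifest["repertoire_tracking"] = {"samples": 0}
        return
    samples = [
        read_repertoire(e.path, e.sample_id, e.patient_id, e.subset, e.dialect)
        for e in cfg.repertoire_samples
    ]
    known = read_known_tcrs(cfg.known_tcrs) if cfg.known_tcrs else {}
    by_patient: Dict[str, list] = {}
    for sample in samples:
        by_patient.setdefault(sample.patient_id, []).append(sample)

    clonality_rows, matches = [], 0
    per_patient_clonality: Dict[str, Dict] = {}
    for patient_id in sorted(by_patient):
        patient_samples = by_patient[patient_id]
        if known.get(patient_id):
            report = track_known_tcrs(
                patient_samples, known[patient_id], cfg.match_mode
            )
            report.write(outdir / f"tracking.{patient_id}.tsv")
            matches += sum(v is not None for v in report.frequencies.values())
        for sample in patient_samples:
            result = productive_clonality(sample)
            per_patient_clonality.setdefault(patient_id, {})[sample.subset] = (
                result.clonality
            )
            clonality_rows.append(
                f"{sample.sample_id}\t{patient_id}\t{sample.subset.value}\t"
                f"{result.richness}\t{result.shannon_entropy:.6f}\t"
                f"{result.clonality:.6f}\n"
            )
    with open(outdir / "clonality.tsv", "w") as handle:
        handle.write(
            "sample_id\tpatient_id\tsubset\trichness\tshannon_entropy\tclonality\n"
        )
        handle.writelines(clonality_rows)

    stats = {"samples": len(samples), "known_tcr_detections": matches}
    eligible = [
        p
        for p, values in per_patient_clonality.items()
        if Subset.TEM in values and Subset.TN in values
    ]
    if len(eligible) >= 2:
        test = compare_subset_clonality(per_patient_clonality, (Subset.TEM, Subset.TN))
        stats["tem_vs_tn"] = {
            "n": test.n,
            "t": test.t,
            "df": test.df,
            "p": test.p,
            "degenerate": test.degenerate,
        }
    manifest["repertoire_tracking"] = stats


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order and write the run manifest.

    Re-running with unchanged inputs and seed reproduces identical
    outputs.  Manifest invariants: peptides <= passing protein-altering
    variants; TMG member total equals peptide count.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool="neoscreen", version=__version__)
    manifest_path = outdir / "manifest.json"
    stage = "configuration"
    try:
        if cfg.simulate is not None:
            stage = "synthetic_data"
            started = time.perf_counter()
            cfg = simulate_inputs(cfg)
            manifest["synthetic_data"] = {
                "seconds": round(time.perf_counter() - started, 3)
            }
        manifest["config"] = json.loads(cfg.model_dump_json())

        stage = "variant_consensus"
        started = time.perf_counter()
        _, decisions = _stage_filter(cfg, outdir, manifest)
        manifest["variant_consensus"]["seconds"] = round(
            time.perf_counter() - started, 3
        )

        stage = "epitope_design"
        started = time.perf_counter()
        _stage_epitopes(cfg, outdir, manifest, decisions)
        manifest["epitope_design"]["seconds"] = round(time.perf_counter() - started, 3)

        stage = "repertoire_tracking"
        started = time.perf_counter()
        _stage_repertoire(cfg, outdir, manifest)
        manifest["repertoire_tracking"]["seconds"] = round(
            time.perf_counter() - started, 3
        )
    except NeoscreenError as exc:
        manifest["failed_stage"] = stage
        manifest.write(manifest_path)
        raise DataError(f"stage {stage}: {exc}") from exc
    design = manifest["epitope_design"]
    if design["tmg_members"] != design["peptides"]:
        raise DataError("manifest invariant violated: TMG members != peptides")
    manifest.write(manifest_path)
    return manifest
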