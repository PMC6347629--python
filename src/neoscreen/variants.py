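"""Consensus filtering of ensemble somatic variant calls.

A tumor/normal exome is typically processed with several somatic callers
whose call sets only partly overlap.  This module merges per-caller call
tables into a single evidence record per distinct variant and applies the
consensus pass/fail rules that nominate variants for neoepitope design:

* tumor coverage >= 10 and normal coverage >= 10,
* tumor variant read count >= 4,
* tumor variant-allele fraction (VAF) >= 7%,
* for SNVs only: called by >= 2 callers.

Insertions and deletions are exempt from the caller-count rule because
only two of the four callers emit indel calls.  Any variant catalogued in
COSMIC passes regardless of the evidence rules; such a pass is flagged as
a *rescue* when the variant failed at least one rule.  RNA support is
carried as an annotation and never gates filtering.

All thresholds are inclusive ("or greater").
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Caller",
    "VariantClass",
    "VariantKey",
    "CallerCall",
    "VariantEvidence",
    "FilterThresholds",
    "FilterDecision",
    "ParseResult",
    "RowError",
    "SNV_CALLERS",
    "INDEL_CALLERS",
    "EVIDENCE_PRIORITY",
    "normalize_variant",
    "classify_alleles",
    "parse_caller_table",
    "merge_calls",
    "apply_filters",
    "write_decisions",
]


class Caller(str, Enum):
    STRELKA = "strelka"
    SOMATIC_SNIPER = "somatic_sniper"
    VARSCAN2 = "varscan2"
    MUTECT = "mutect"


#: All four callers emit SNVs; only Strelka and Varscan2 emit indels.
SNV_CALLERS = frozenset(Caller)
INDEL_CALLERS = frozenset({Caller.STRELKA, Caller.VARSCAN2})

#: When callers disagree on read counts, the first caller present in this
#: order supplies the merged record's evidence (deterministic tie-break).
EVIDENCE_PRIORITY = (
    Caller.MUTECT,
    Caller.STRELKA,
    Caller.VARSCAN2,
    Caller.SOMATIC_SNIPER,
)


class VariantClass(str, Enum):
    SNV = "snv"
    INSERTION = "insertion"
    DELETION = "deletion"


class VariantKey(NamedTuple):
    """Identity of a variant: contig (or transcript), 1-based position,
    reference allele, alternate allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # compact key used in reports and key files
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, alleles = text.rsplit(":", 2)
        ref, alt = alleles.split(">")
        return cls(chrom, int(pos), ref, alt)


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce an allele pair to minimal representation.

    Trims the shared suffix, then the shared prefix (keeping one anchor
    base on each side and advancing ``pos``).  This is the reference-free
    part of VCF indel normalization; full left-alignment needs the genome
    and is out of scope here.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def classify_alleles(ref: str, alt: str) -> VariantClass:
    if ref == alt:
        raise DataError(f"ref and alt alleles are identical ({ref!r})")
    if len(ref) == len(alt):
        if len(ref) != 1:
            raise DataError(
                f"multi-nucleotide substitution {ref}>{alt} not supported"
            )
        return VariantClass.SNV
    return VariantClass.INSERTION if len(alt) > len(ref) else VariantClass.DELETION


@dataclass(frozen=True)
class CallerCall:
    """One caller's report of one variant, with its tumor/normal evidence."""

    key: VariantKey
    caller: Caller
    variant_class: VariantClass
    tumor_coverage: int
    normal_coverage: int
    tumor_variant_reads: int

    def __post_init__(self) -> None:
        expected = classify_alleles(self.key.ref, self.key.alt)
        if expected is not self.variant_class:
            raise DataError(
                f"{self.key}: declared class {self.variant_class.value} but "
                f"alleles imply {expected.value}"
            )
        if self.variant_class is not VariantClass.SNV and self.caller not in INDEL_CALLERS:
            raise DataError(
                f"{self.key}: indel caller restriction — {self.caller.value} "
                "does not emit indel calls (only strelka and varscan2 do)"
            )
        for name in ("tumor_coverage", "normal_coverage", "tumor_variant_reads"):
            if getattr(self, name) < 0:
                raise DataError(f"{self.key}: {name} must be >= 0")


@dataclass(frozen=True)
class VariantEvidence:
    """Merged per-variant evidence: the unit the consensus filter judges."""

    key: VariantKey
    variant_class: VariantClass
    tumor_coverage: int
    normal_coverage: int
    tumor_variant_reads: int
    tumor_vaf: float
    callers: frozenset
    in_cosmic: bool = False
    rna_supported: Optional[bool] = None  # tri-state: None = unknown
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.callers:
            raise DataError(f"{self.key}: caller set must be non-empty")
        if self.tumor_variant_reads > self.tumor_coverage:
            raise DataError(
                f"{self.key}: tumor_variant_reads ({self.tumor_variant_reads}) "
                f"exceeds tumor_coverage ({self.tumor_coverage})"
            )
        if self.tumor_coverage > 0:
            implied = self.tumor_variant_reads / self.tumor_coverage
            if abs(implied - self.tumor_vaf) > 1e-9:
                raise DataError(
                    f"{self.key}: tumor_vaf {self.tumor_vaf} inconsistent with "
                    f"{self.tumor_variant_reads}/{self.tumor_coverage}"
                )


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive evidence cutoffs for the consensus filter."""

    min_tumor_coverage: int = 10
    min_normal_coverage: int = 10
    min_variant_reads: int = 4
    min_vaf: float = 0.07
    min_callers_snv: int = 2

    def __post_init__(self) -> None:
        if min(
            self.min_tumor_coverage,
            self.min_normal_coverage,
            self.min_variant_reads,
            self.min_callers_snv,
        ) < 0:
            raise DataError("thresholds must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise DataError("min_vaf must lie in [0, 1]")


RULE_TUMOR_COVERAGE = "min_tumor_coverage"
RULE_NORMAL_COVERAGE = "min_normal_coverage"
RULE_VARIANT_READS = "min_variant_reads"
RULE_VAF = "min_vaf"
RULE_CALLERS = "min_callers"


@dataclass(frozen=True)
class FilterDecision:
    key: VariantKey
    passed: bool
    rescue: bool  # passed solely because the variant is in COSMIC
    failed_rules: tuple

    def __post_init__(self) -> None:
        if self.rescue and not self.passed:
            raise DataError(f"{self.key}: rescue implies passed")
        if self.passed and not self.rescue and self.failed_rules:
            raise DataError(f"{self.key}: non-rescue pass must have no failed rules")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RowError:
    line_number: int
    message: str
    raw: str


@dataclass
class ParseResult:
    """Calls plus per-row problems; malformed rows are reported, never
    silently dropped.  TSV rows may also carry COSMIC / RNA flags."""

    calls: list = field(default_factory=list)
    row_errors: list = field(default_factory=list)
    cosmic_keys: set = field(default_factory=set)
    rna_keys: set = field(default_factory=set)


_VCF_FIELDS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")
_REQUIRED_INFO = ("TCOV", "NCOV", "TVR")
_TSV_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "caller",
    "tumor_coverage",
    "normal_coverage",
    "tumor_variant_reads",
    "in_cosmic",
    "rna_supported",
)
_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n", ""}


def _parse_bool(text: str, column: str, line_number: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise FormatError(f"line {line_number}: unparseable boolean {text!r} in {column}")


def _calls_from_row(
    chrom: str,
    pos: int,
    ref: str,
    alt_field: str,
    caller: Caller,
    tcov: int,
    ncov: int,
    tvr: int,
) -> list:
    """Split multi-allelic ALT into biallelic records and normalize."""
    calls = []
    for alt in alt_field.split(","):
        key = normalize_variant(chrom, pos, ref, alt)
        calls.append(
            CallerCall(
                key=key,
                caller=caller,
                variant_class=classify_alleles(key.ref, key.alt),
                tumor_coverage=tcov,
                normal_coverage=ncov,
                tumor_variant_reads=tvr,
            )
        )
    return calls


def parse_caller_table(
    path, caller_name: Optional[str] = None, dialect: str = "minimal_vcf"
) -> ParseResult:
    """Read one caller's call table.

    ``minimal_vcf``: the 8 fixed VCF columns with integer INFO keys
    TCOV/NCOV/TVR; the caller identity comes from ``caller_name``.
    ``tsv``: a headered table carrying the caller per row (plus COSMIC and
    RNA-support flags); ``caller_name``, if given, must agree.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"caller table not found: {path}")
    if dialect == "minimal_vcf":
        if caller_name is None:
            raise DataError("minimal_vcf dialect requires caller_name")
        result = _parse_minimal_vcf(path, Caller(caller_name))
    elif dialect == "tsv":
        result = _parse_tsv(path, Caller(caller_name) if caller_name else None)
    else:
        raise DataError(f"unknown dialect {dialect!r}")
    if not result.calls and not result.row_errors:
        logger.warning("%s: no variant rows found", path)
    return result


def _parse_minimal_vcf(path: Path, caller: Caller) -> ParseResult:
    result = ParseResult()
    with open(path) as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(_VCF_FIELDS):
                missing = _VCF_FIELDS[len(fields)]
                result.row_errors.append(
                    RowError(line_number, f"missing mandatory column {missing}", line)
                )
                continue
            info = {}
            for item in fields[7].split(";"):
                if "=" in item:
                    k, _, v = item.partition("=")
                    info[k] = v
            try:
                values = {}
                for key in _REQUIRED_INFO:
                    if key not in info:
                        raise FormatError(f"missing mandatory INFO key {key}")
                    values[key] = int(info[key])
                result.calls.extend(
                    _calls_from_row(
                        fields[0],
                        int(fields[1]),
                        fields[3].upper(),
                        fields[4].upper(),
                        caller,
                        values["TCOV"],
                        values["NCOV"],
                        values["TVR"],
                    )
                )
            except (DataError, ValueError) as exc:
                result.row_errors.append(RowError(line_number, str(exc), line))
    return result


def _parse_tsv(path: Path, caller: Optional[Caller]) -> ParseResult:
    result = ParseResult()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("%s: empty file", path)
            return result
        missing = [c for c in _TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
        for line_number, row in enumerate(reader, start=2):
            try:
                row_caller = Caller(row["caller"].strip().lower())
                if caller is not None and row_caller is not caller:
                    raise FormatError(
                        f"row caller {row_caller.value} disagrees with requested "
                        f"{caller.value}"
                    )
                calls = _calls_from_row(
                    row["chrom"],
                    int(row["pos"]),
                    row["ref"].upper(),
                    row["alt"].upper(),
                    row_caller,
                    int(row["tumor_coverage"]),
                    int(row["normal_coverage"]),
                    int(row["tumor_variant_reads"]),
                )
                result.calls.extend(calls)
                if _parse_bool(row["in_cosmic"], "in_cosmic", line_number):
                    result.cosmic_keys.update(c.key for c in calls)
                if _parse_bool(row["rna_supported"], "rna_supported", line_number):
                    result.rna_keys.update(c.key for c in calls)
            except (DataError, ValueError) as exc:
                result.row_errors.append(
                    RowError(line_number, str(exc), "\t".join(row.values()))
                )
    return result


# ---------------------------------------------------------------------------
# Merge and filter
# ---------------------------------------------------------------------------

def merge_calls(
    calls: Iterable[CallerCall],
    cosmic_keys: Iterable[VariantKey] = (),
    rna_calls: Optional[Iterable[VariantKey]] = None,
) -> list:
    """Collapse per-caller calls into one :class:`VariantEvidence` per key.

    Caller sets are unioned; read counts come from the highest-priority
    caller present (:data:`EVIDENCE_PRIORITY`).  ``rna_calls`` only
    annotates exome variants — an RNA-only key never creates a record.
    ``rna_calls=None`` leaves RNA support unknown on every record.
    """
    cosmic = set(cosmic_keys)
    rna = None if rna_calls is None else set(rna_calls)
    by_key: dict = {}
    for call in calls:
        by_key.setdefault(call.key, []).append(call)

    merged = []
    for key in sorted(by_key):
        group = by_key[key]
        rank = {caller: i for i, caller in enumerate(EVIDENCE_PRIORITY)}
        primary = min(group, key=lambda c: rank[c.caller])
        vaf = (
            primary.tumor_variant_reads / primary.tumor_coverage
            if primary.tumor_coverage > 0
            else 0.0
        )
        merged.append(
            VariantEvidence(
                key=key,
                variant_class=primary.variant_class,
                tumor_coverage=primary.tumor_coverage,
                normal_coverage=primary.normal_coverage,
                tumor_variant_reads=primary.tumor_variant_reads,
                tumor_vaf=vaf,
                callers=frozenset(c.caller for c in group),
                in_cosmic=key in cosmic,
                rna_supported=None if rna is None else key in rna,
            )
        )
    return merged


def apply_filters(
    evidence: Sequence[VariantEvidence],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list:
    """Judge each variant against the consensus rules.

    SNVs must satisfy all five rules; indels are exempt from the caller
    rule.  COSMIC membership forces a pass; if the variant failed any rule
    the decision is flagged ``rescue`` and the violated rules are listed.
    """
    decisions = []
    for ev in evidence:
        failed = []
        if ev.tumor_coverage < thresholds.min_tumor_coverage:
            failed.append(RULE_TUMOR_COVERAGE)
        if ev.normal_coverage < thresholds.min_normal_coverage:
            failed.append(RULE_NORMAL_COVERAGE)
        if ev.tumor_variant_reads < thresholds.min_variant_reads:
            failed.append(RULE_VARIANT_READS)
        if ev.tumor_vaf < thresholds.min_vaf:
            failed.append(RULE_VAF)
        if (
            ev.variant_class is VariantClass.SNV
            and len(ev.callers) < thresholds.min_callers_snv
        ):
            failed.append(RULE_CALLERS)
        passed = not failed
        rescue = False
        if ev.in_cosmic and failed:
            passed, rescue = True, True
        decisions.append(
            FilterDecision(
                key=ev.key, passed=passed, rescue=rescue, failed_rules=tuple(failed)
            )
        )
    return decisions


def write_decisions(
    evidence: Sequence[VariantEvidence],
    decisions: Sequence[FilterDecision],
    path,
) -> None:
    """Write the decisions TSV (one row per variant, evidence included)."""
    by_key = {ev.key: ev for ev in evidence}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "variant_key",
                "chrom",
                "pos",
                "ref",
                "alt",
                "variant_class",
                "callers",
                "tumor_coverage",
                "normal_coverage",
                "tumor_variant_reads",
                "tumor_vaf",
                "in_cosmic",
                "rna_supported",
                "passed",
                "rescue",
                "failed_rules",
            ]
        )
        for decision in decisions:
            ev = by_key[decision.key]
            writer.writerow(
                [
                    str(ev.key),
                    ev.key.chrom,
                    ev.key.pos,
                    ev.key.ref,
                    ev.key.alt,
                    ev.variant_class.value,
                    ",".join(sorted(c.value for c in ev.callers)),
                    ev.tumor_coverage,
                    ev.normal_coverage,
                    ev.tumor_variant_reads,
                    f"{ev.tumor_vaf:.6f}",
                    int(ev.in_cosmic),
                    "" if ev.rna_supported is None else int(ev.rna_supported),
                    int(decision.passed),
                    int(decision.rescue),
                    ",".join(decision.failed_rules),
                ]
            )
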