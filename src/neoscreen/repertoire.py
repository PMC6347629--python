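"""TCR-beta repertoire tracking across sorted T-cell subsets.

Deep-sequenced TCR-beta repertoires from sorted subsets (naive TN,
central-memory TCM, effector-memory TEM, terminally differentiated
TEMRA, bulk PBL, TIL) are loaded from immunoSEQ-style or AIRR
rearrangement TSVs, known neoantigen-reactive clonotypes are quantified
in each subset as a percentage of productive templates, and per-sample
*productive clonality* is computed as

    clonality = 1 - H / ln(R)

where H is the Shannon entropy (nats) of productive clone frequencies
and R the number of unique productive rearrangements (Pielou-normalized
evenness, subtracted from 1).  A monoclonal sample (R = 1) is defined as
clonality 1.0, the limit of maximal dominance.  Only productive
rearrangements enter frequencies and clonality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .epitopes import translate_cds
from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Subset",
    "Clonotype",
    "RepertoireSample",
    "KnownTCR",
    "TrackingReport",
    "ClonalityResult",
    "PairedTTestResult",
    "SingleCellWell",
    "NOT_DETECTED",
    "read_repertoire",
    "write_repertoire",
    "track_known_tcrs",
    "productive_clonality",
    "compare_subset_clonality",
    "aggregate_sc_wells",
    "shared_clonotypes",
]

NOT_DETECTED = "−"  # minus sign rendered for absent clonotypes
UNDEFINED = "n/a"  # subset with zero productive templates


class Subset(str, Enum):
    TN = "TN"
    TCM = "TCM"
    TEM = "TEM"
    TEMRA = "TEMRA"
    BULK_PBL = "bulk_PBL"
    TIL = "TIL"


@dataclass(frozen=True)
class Clonotype:
    """A unique TCR-beta rearrangement with its template count."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    productive: bool
    templates: int

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise DataError("observed clonotype must have templates >= 1")
        if self.productive:
            if len(self.cdr3_nt) % 3 != 0:
                raise DataError(
                    f"productive rearrangement {self.cdr3_nt} not divisible by 3"
                )
            translated = translate_cds(self.cdr3_nt)
            if translated.hit_stop or translated.protein != self.cdr3_aa:
                raise DataError(
                    f"productive rearrangement {self.cdr3_nt}: CDR3 amino-acid "
                    f"sequence {self.cdr3_aa!r} does not match translation"
                )


@dataclass
class RepertoireSample:
    """One sorted-subset repertoire from one patient."""

    sample_id: str
    patient_id: str
    subset: Subset
    clonotypes: list

    @property
    def total_templates(self) -> int:
        return sum(c.templates for c in self.clonotypes)

    @property
    def total_productive_templates(self) -> int:
        return sum(c.templates for c in self.clonotypes if c.productive)

    @property
    def productive_clonotypes(self) -> list:
        return [c for c in self.clonotypes if c.productive]


@dataclass(frozen=True)
class KnownTCR:
    """A previously identified reactive clonotype to look for."""

    label: str
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    v_gene: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_nt and not self.cdr3_aa:
            raise DataError(f"{self.label}: need cdr3_nt or cdr3_aa")


@dataclass(frozen=True)
class ClonalityResult:
    sample_id: str
    richness: int
    shannon_entropy: float  # nats
    clonality: float


@dataclass(frozen=True)
class PairedTTestResult:
    n: int
    t: Optional[float]
    df: Optional[int]
    p: Optional[float]
    degenerate: bool  # zero variance of paired differences


@dataclass(frozen=True)
class SingleCellWell:
    """One sorted single cell: possibly multiple alpha/beta chain calls,
    possibly none (dropout)."""

    well_id: str
    subset: Subset
    alpha_calls: tuple = ()
    beta_calls: tuple = ()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_IMMUNOSEQ_COLUMNS = (
    "rearrangement",
    "amino_acid",
    "v_gene",
    "j_gene",
    "frame_type",
    "templates",
)
_AIRR_COLUMNS = (
    "junction",
    "junction_aa",
    "v_call",
    "j_call",
    "productive",
    "duplicate_count",
)


def read_repertoire(
    path,
    sample_id: str,
    patient_id: str,
    subset,
    dialect: str = "immunoseq_tsv",
) -> RepertoireSample:
    """Load a rearrangement TSV and aggregate to unique clonotypes.

    Rows are aggregated by (cdr3_nt, v_gene, j_gene) with template counts
    summed.  Out-of-frame / stop-containing rearrangements are retained
    with ``productive=False``; they count toward total templates but not
    toward frequencies or clonality.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty repertoire file") from exc
    table = table.fillna("")
    if dialect == "immunoseq_tsv":
        required = _IMMUNOSEQ_COLUMNS
        rename = {}
        productive = lambda s: s == "In"  # noqa: E731
        count_col = "templates"
    elif dialect == "airr":
        required = _AIRR_COLUMNS
        rename = {
            "junction": "rearrangement",
            "junction_aa": "amino_acid",
            "v_call": "v_gene",
            "j_call": "j_gene",
            "duplicate_count": "templates",
        }
        productive = lambda s: str(s).upper() in {"T", "TRUE", "1"}  # noqa: E731
        count_col = "duplicate_count"
    else:
        raise DataError(f"unknown repertoire dialect {dialect!r}")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    if table.empty:
        raise FormatError(f"{path}: repertoire file has a header but no rows")

    is_productive = (
        table["frame_type"].map(productive)
        if dialect == "immunoseq_tsv"
        else table["productive"].map(productive)
    )
    table = table.assign(
        productive_flag=is_productive, template_count=table[count_col].astype(int)
    )
    table = table.rename(columns=rename)
    grouped = (
        table.groupby(
            ["rearrangement", "v_gene", "j_gene", "amino_acid", "productive_flag"],
            sort=True,
        )["template_count"]
        .sum()
        .reset_index()
    )
    clonotypes = [
        Clonotype(
            cdr3_nt=row.rearrangement,
            cdr3_aa=row.amino_acid,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            productive=bool(row.productive_flag),
            templates=int(row.template_count),
        )
        for row in grouped.itertuples()
    ]
    sample = RepertoireSample(
        sample_id=sample_id,
        patient_id=patient_id,
        subset=Subset(subset),
        clonotypes=clonotypes,
    )
    if sample.total_productive_templates == 0:
        logger.warning("%s: no productive templates", sample_id)
    return sample


def write_repertoire(sample: RepertoireSample, path, dialect: str = "immunoseq_tsv") -> None:
    rows = []
    for c in sorted(
        sample.clonotypes, key=lambda c: (c.cdr3_nt, c.v_gene, c.j_gene)
    ):
        if dialect == "immunoseq_tsv":
            frame = "In" if c.productive else "Out"
            rows.append(
                {
                    "rearrangement": c.cdr3_nt,
                    "amino_acid": c.cdr3_aa,
                    "v_gene": c.v_gene,
                    "j_gene": c.j_gene,
                    "frame_type": frame,
                    "templates": c.templates,
                }
            )
        elif dialect == "airr":
            rows.append(
                {
                    "junction": c.cdr3_nt,
                    "junction_aa": c.cdr3_aa,
                    "v_call": c.v_gene,
                    "j_call": c.j_gene,
                    "productive": "T" if c.productive else "F",
                    "duplicate_count": c.templates,
                }
            )
        else:
            raise DataError(f"unknown repertoire dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matching and tracking
# ---------------------------------------------------------------------------

def _clonotype_match_key(clonotype: Clonotype, match_mode: str):
    if match_mode == "nt":
        return clonotype.cdr3_nt
    if match_mode == "aa_v":
        return (clonotype.cdr3_aa, clonotype.v_gene)
    raise DataError(f"unknown match_mode {match_mode!r}")


def _known_match_key(known: KnownTCR, match_mode: str):
    if match_mode == "nt":
        if not known.cdr3_nt:
            raise DataError(f"{known.label}: nt matching requires cdr3_nt")
        return known.cdr3_nt
    if match_mode == "aa_v":
        if not known.cdr3_aa or not known.v_gene:
            raise DataError(f"{known.label}: aa_v matching requires cdr3_aa and v_gene")
        return (known.cdr3_aa, known.v_gene)
    raise DataError(f"unknown match_mode {match_mode!r}")


@dataclass
class TrackingReport:
    """Known-TCR frequencies (percent of productive templates) per subset.

    ``frequencies[(label, subset)]`` is a percentage in (0, 100], or
    ``None`` when the clonotype was not detected (rendered as a minus
    sign).  Subsets with zero productive templates are listed in
    ``undefined_subsets`` and rendered ``n/a``.
    """

    known_labels: list
    subsets: list
    frequencies: dict
    undefined_subsets: set = field(default_factory=set)
    match_mode: str = "nt"

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for subset in self.subsets:
            column = []
            for label in self.known_labels:
                if subset in self.undefined_subsets:
                    column.append(UNDEFINED)
                else:
                    freq = self.frequencies.get((label, subset))
                    column.append(NOT_DETECTED if freq is None else f"{freq:.4g}")
            data[subset.value] = column
        return pd.DataFrame(data, index=self.known_labels)

    def write(self, path) -> None:
        self.to_dataframe().rename_axis("known_tcr").to_csv(path, sep="\t")


def track_known_tcrs(
    samples: Sequence[RepertoireSample],
    known: Sequence[KnownTCR],
    match_mode: str = "nt",
) -> TrackingReport:
    """Quantify each known clonotype in each subset.

    Frequency = 100 x matched productive templates / productive templates
    in the subset.  ``nt`` matches on exact CDR3 nucleotide identity;
    ``aa_v`` on CDR3 amino-acid plus V-gene identity (for Sanger-derived
    receptors).  Non-productive copies of a matching sequence never count.
    """
    if not known:
        raise DataError("known TCR list must be non-empty")
    patients = {s.patient_id for s in samples}
    if len(patients) > 1:
        raise DataError(f"samples span multiple patients: {sorted(patients)}")
    subsets = [s.subset for s in samples]
    if len(set(subsets)) != len(subsets):
        raise DataError("duplicate subset among samples")

    frequencies: dict = {}
    undefined: set = set()
    for sample in samples:
        denominator = sample.total_productive_templates
        if denominator == 0:
            undefined.add(sample.subset)
            continue
        counts: dict = {}
        for clonotype in sample.productive_clonotypes:
            key = _clonotype_match_key(clonotype, match_mode)
            counts[key] = counts.get(key, 0) + clonotype.templates
        for tcr in known:
            matched = counts.get(_known_match_key(tcr, match_mode), 0)
            if matched > 0:
                frequencies[(tcr.label, sample.subset)] = 100.0 * matched / denominator
    return TrackingReport(
        known_labels=[t.label for t in known],
        subsets=subsets,
        frequencies=frequencies,
        undefined_subsets=undefined,
        match_mode=match_mode,
    )


def productive_clonality(sample: RepertoireSample) -> ClonalityResult:
    """Clonality = 1 - H/ln(R) over unique productive rearrangements."""
    counts = np.array(
        [c.templates for c in sample.productive_clonotypes], dtype=float
    )
    if counts.size == 0:
        raise DataError(f"{sample.sample_id}: no productive clonotypes")
    richness = int(counts.size)
    if richness == 1:
        return ClonalityResult(sample.sample_id, 1, 0.0, 1.0)
    entropy = float(stats.entropy(counts))  # normalizes and uses natural log
    clonality = 1.0 - entropy / np.log(richness)
    return ClonalityResult(sample.sample_id, richness, entropy, float(clonality))


def compare_subset_clonality(
    per_patient: Mapping[str, Mapping],
    pair: Tuple,
) -> PairedTTestResult:
    """Classical paired t-test of clonality between two subsets.

    ``per_patient`` maps patient -> {subset: clonality}; only patients
    with both subsets enter.  Zero variance of the paired differences is
    flagged degenerate and no p value is reported.
    """
    subset_a, subset_b = Subset(pair[0]), Subset(pair[1])
    a, b = [], []
    for patient in sorted(per_patient):
        values = per_patient[patient]
        if subset_a in values and subset_b in values:
            a.append(values[subset_a])
            b.append(values[subset_b])
    n = len(a)
    if n < 2:
        raise DataError(f"paired t-test needs >= 2 patients with both subsets, got {n}")
    differences = np.asarray(a) - np.asarray(b)
    if np.allclose(differences.var(ddof=0), 0.0):
        return PairedTTestResult(n=n, t=None, df=None, p=None, degenerate=True)
    result = stats.ttest_rel(a, b)
    return PairedTTestResult(
        n=n, t=float(result.statistic), df=n - 1, p=float(result.pvalue), degenerate=False
    )


# ---------------------------------------------------------------------------
# Single-cell wells and shared clonotypes
# ---------------------------------------------------------------------------

def aggregate_sc_wells(wells: Sequence[SingleCellWell]) -> pd.DataFrame:
    """Group single-cell wells by beta clonotype.

    Returns one row per beta call with total well count, per-subset well
    counts, the most frequent co-occurring alpha call(s) — all ties are
    reported, joined by ``|`` — and the number of wells lacking an alpha.
    """
    groups: dict = {}
    for well in wells:
        for beta in well.beta_calls:
            record = groups.setdefault(
                beta, {"wells": 0, "subsets": {}, "alphas": {}, "no_alpha": 0}
            )
            record["wells"] += 1
            record["subsets"][well.subset] = record["subsets"].get(well.subset, 0) + 1
            if well.alpha_calls:
                for alpha in well.alpha_calls:
                    record["alphas"][alpha] = record["alphas"].get(alpha, 0) + 1
            else:
                record["no_alpha"] += 1
    rows = []
    for beta in sorted(groups):
        record = groups[beta]
        alphas = record["alphas"]
        if alphas:
            top = max(alphas.values())
            dominant = sorted(a for a, c in alphas.items() if c == top)
        else:
            dominant = []
        rows.append(
            {
                "beta": beta,
                "n_wells": record["wells"],
                "n_subsets": len(record["subsets"]),
                "subsets": ",".join(
                    f"{s.value}:{c}" for s, c in sorted(record["subsets"].items())
                ),
                "dominant_alpha": "|".join(dominant) if dominant else "unknown",
                "alpha_ambiguous": len(dominant) > 1,
                "n_wells_without_alpha": record["no_alpha"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "beta",
            "n_wells",
            "n_subsets",
            "subsets",
            "dominant_alpha",
            "alpha_ambiguous",
            "n_wells_without_alpha",
        ],
    )


def shared_clonotypes(
    a: Iterable[Clonotype], b: Iterable[Clonotype], match_mode: str = "nt"
) -> pd.DataFrame:
    """Symmetric intersection of two clonotype sets under a match mode,
    with per-set template counts."""
    def _totals(clonotypes):
        totals: dict = {}
        for c in clonotypes:
            key = _clonotype_match_key(c, match_mode)
            totals[key] = totals.get(key, 0) + c.templates
        return totals

    totals_a, totals_b = _totals(a), _totals(b)
    shared = sorted(set(totals_a) & set(totals_b), key=str)
    return pd.DataFrame(
        {
            "match_key": [str(k) for k in shared],
            "templates_a": [totals_a[k] for k in shared],
            "templates_b": [totals_b[k] for k in shared],
        }
    )
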