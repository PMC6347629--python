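# Methods

This note documents the models and procedures `neoscreen` implements,
the parameters that matter, the design choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Consensus variant filtering

A variant's identity is its (contig-or-transcript, 1-based position,
ref allele, alt allele) tuple after allele minimalization: the shared
suffix is trimmed, then the shared prefix (keeping one anchor base and
advancing the position). Full left-alignment against the genome is out
of scope — the module never sees a reference sequence — so trimming is
the reference-free portion of the VCF normalization convention.
Multi-allelic rows are split into biallelic records before merging.

Merged evidence takes the caller set as the union over callers
reporting the variant. When callers disagree on read counts, the
counts come from a fixed priority order, Mutect > Strelka > Varscan2 >
SomaticSniper; any fixed order makes the merge deterministic, and this
one prefers the callers that model tumor/normal read evidence most
directly. VAF is defined at the merged record as tumor variant reads /
tumor coverage. Supplied depths are treated as authoritative; whether
they were computed pre- or post-base-quality recalibration is the
caller pipeline's concern, not this module's.

The filter itself applies five inclusive rules (tumor coverage ≥ 10,
normal coverage ≥ 10, variant reads ≥ 4, VAF ≥ 0.07, and ≥ 2 callers
for SNVs; indels are exempt from the caller rule because only two
callers emit them). COSMIC membership is supplied as a key set rather
than queried live, keeping results independent of catalogue version; a
COSMIC variant that fails any rule still passes, flagged `rescue`,
with its violated rules listed. RNA support (from a no-cutoff RNA
caller) is annotation only: it never gates filtering, and RNA-only
variants never create exome records. COSMIC rescue does not waive the
downstream requirement that a variant be protein-altering; epitope
design still rejects synonymous rescues.

## Neoepitope extraction

All coordinates are 1-based, inclusive, in CDS space; mapping genomic
or cDNA coordinates into the CDS is the caller's duty (the pipeline
does it from the transcript's CDS bounds). Editing is pure string
substitution with a reference check that reports the position and the
observed base on mismatch.

For a missense SNV at protein position p in a protein of length L, the
peptide is the mutant residue with min(12, p−1) wild-type residues to
the left and min(12, L−p) to the right — 25 residues in the interior,
truncated at the termini (position 12 gives the familiar 24-mer
hotspot geometry). Synonymous substitutions are rejected; stop-gains
are rejected with a warning, since they leave no mutant residue to
present.

Frameshifts are handled by translating the edited sequence from the
CDS start through the 3′ end of the transcript, so translation can run
past the original stop. The peptide is the ≤ 12-residue wild-type
prefix before the first residue that diverges from the wild-type
protein, plus every residue up to but excluding the first stop; if no
stop occurs, the peptide runs to the transcript end and is flagged
(`reached_transcript_end`, with any trailing partial codon dropped).
A frameshift whose first shifted codon is already a stop contributes no
novel residue and is rejected like a stop-gain. Stop-loss SNVs are the
same situation in reverse — a novel C-terminal tail — and reuse the
frameshift path, flagged identically.

In-frame indels present the changed residue block (all inserted
residues, located by divergence from both ends of the protein) with up
to 12 wild-type residues on each side. A clean codon deletion whose
junction residues match the wild type presents the single junction
residue. Only frameshift and missense geometries are fully pinned down
by prior practice; the in-frame block definition is this package's
choice and is stated here for that reason.

## Tandem minigenes and back-translation

Peptides are concatenated in input order into ⌈n/capacity⌉ TMGs.
Capacity defaults to 16, the smallest uniform chunk size for which 201
minigenes fill exactly 13 constructs; it is configurable. Duplicate
peptide strings (one mutation reached through several transcripts) are
deduplicated before assembly, first occurrence winning; input order is
otherwise preserved.

The nucleotide realization is deterministic. Codon policy `native`
(default) reuses the codons of the edited transcript wherever the
peptide maps onto it, falling back to a fixed preferred-human-codon
table for anything else (policy `preferred` uses the table throughout).
EcoRI (GAATTC) and BamHI (GGATCC) sites — the cloning sites of the
destination vector — are removed by synonymous codon swaps scanning
left to right; with the standard code these two motifs can always be
broken, but the code verifies it and raises a design error otherwise.
A single TAA stop (configurable) terminates each construct. The TMG
nucleotide sequence carries no initiator ATG of its own — translation
context belongs to the expression vector — so translate(nt) equals the
peptide concatenation plus the terminal stop exactly, which is the
invariant the tests assert. `back_translate` called directly defaults
to prepending ATG when the first residue is not methionine.

## Repertoire statistics

Clonotypes are identified by CDR3β nucleotide sequence plus V and J
gene; rows of an input TSV are aggregated by that identity with
template counts summed. Out-of-frame or stop-containing rearrangements
are retained as non-productive: they count toward total templates but
are excluded from every frequency and clonality computation.

Known-TCR tracking reports 100 × matched productive templates / total
productive templates per subset, with a dash for zero matches and an
explicit n/a marker for a subset with no productive templates. Two
match modes are provided because deep-sequencing-derived and
Sanger-derived reference TCRs carry different information: `nt`
(default) requires exact CDR3 nucleotide identity — the natural mode
when the known clones come from deep sequencing of the same subject —
while `aa_v` requires CDR3 amino-acid plus V-gene identity. `nt` is
never more sensitive than `aa_v` on consistent data. Detection floor
is one template; no imputation for sampling depth is attempted —
reported percentages are raw.

Productive clonality is 1 − H/ln R with H the Shannon entropy (nats)
of productive clone frequencies and R the productive richness — one
minus Pielou evenness, the standard repertoire-analysis definition; a
monoclonal sample (R = 1, where the ratio is 0/0) is defined as
clonality 1, the limit of maximal dominance. Clonality is invariant to
uniform count rescaling and clone relabeling and increases when mass
moves from rare to dominant clones. Subset comparisons use the
classical two-sided paired t-test on per-patient differences; zero
variance of the differences is flagged degenerate and no p value is
reported rather than returning an ill-defined statistic.

## Synthetic data

The generator's defaults encode the study conditions the pipeline is
meant for, and were fixed once, up front:

- Transcripts: CDS of 150–900 nt (ATG start, internal-stop-free,
  stop-terminated) with short UTRs, 30 per run.
- Variant evidence: tumor/normal depth ~ negative binomial (means
  80/60, dispersion 8), clonal VAF ~ Beta(20, 30) (mean 0.4 — a clonal
  heterozygous variant with ~80% purity), variant reads binomial given
  depth and VAF. Simple and controllable; no claim of matching any
  particular sequencer's error process.
- Caller ensemble: per-caller sensitivities 0.95/0.95/0.90/0.80
  (Mutect, Strelka, Varscan2, SomaticSniper) applied independently per
  variant; indels only from Strelka and Varscan2. False positives are
  Poisson-many per caller (rates 0.03–0.08 per true-variant slot) and
  carry weak evidence by construction — a single caller and ≤ 3
  supporting reads — so the filter's precision/recall behaviour is
  visible against ground truth. Real callers' errors are correlated;
  simulating them independently is a documented simplification, so
  measured ensemble precision is optimistic.
- Repertoires: clone sizes follow a Zipf law with subset-specific
  exponent (TN 1.05, TCM 1.25, TEM 1.50, TEMRA 1.60) over decreasing
  richness (20 000 / 8 000 / 4 000 / 2 000 unique clones), sampled
  multinomially at 10⁵ templates per subset — inside the 2 × 10⁴ to
  10⁶ range typical of sorted-sample deep sequencing. These exponents
  reproduce the expected clonality hierarchy TEMRA ≥ TEM > TCM > TN.
  15% of template mass is non-productive. Reactive clonotypes are
  spiked only into the memory subsets, never TN, at true frequencies
  drawn uniformly from 0.0007%–0.02% of productive templates.
- Determinism: one integer seed drives everything; identical config
  and seed give byte-identical output files.

What passing tests on these data do **not** show: robustness to
correlated caller errors, to sequencing-error-derived CDR3 artifacts
(no error model is applied to rearrangements), to ambiguous V-gene
annotations, or to real VAF distributions distorted by subclonality
and copy number. Flow-cytometry gating is out of scope throughout;
subset labels are assigned, not inferred.

## Pipeline and numerical choices

Stages run in the fixed order consensus filter → epitope design →
repertoire tracking; re-runs on unchanged inputs are byte-identical,
and the JSON manifest records a config snapshot, per-stage counts
(with the invariants: peptides ≤ passing protein-altering variants;
TMG members = peptides) and wall-clock times. Config validation
aggregates all problems instead of stopping at the first, and logs
every defaulted field. Malformed input rows are collected and
reported, never silently dropped. VAF consistency between counts and
the stored fraction is enforced to 1 × 10⁻⁹; clonality closed forms
are tested to 1 × 10⁻¹²; all rule thresholds compare with ≥.

Problem sizes used by the validation harness (chosen to keep a full
run around a minute on one CPU): 1 000 planted variants for the
filter-oracle comparison, 500 random SNVs for the length law, 200
random frameshifts against direct translation of the edited cDNA, 100
seeded repertoire simulations (depth drawn from 10⁵–10⁶) for spike
recovery against the 95% binomial interval, and 50 seeds for the
clonality hierarchy. The acceptance script re-derives all oracle
values internally and never reads package test code.

## Known limitations

- MHC binding prediction is deliberately absent; externally predicted
  minimal epitopes are accepted through a stub type only.
- Genomic→transcript coordinate lift-over, annotation (gene models,
  functional consequence beyond the CDS edit) and caller execution are
  out of scope; inputs arrive already expressed against transcripts.
- The minimal-VCF dialect parser accepts only the fixed eight columns
  with TCOV/NCOV/TVR INFO keys; arbitrary VCF features (genotypes,
  symbolic alleles, phasing) are not supported.
- Clonotype error correction / collapsing of near-duplicate CDR3s is
  not performed; identity is exact.
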