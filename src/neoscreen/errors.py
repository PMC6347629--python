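"""Exception hierarchy shared across the pipeline stages.

``DataError`` (exit code 1 at the CLI) covers malformed or inconsistent
input data; ``ConfigError`` (exit code 2) covers invalid run configuration.
"""


class NeoscreenError(Exception):
    """Base class for all package-specific errors."""


class DataError(NeoscreenError):
    """Input data is malformed or violates a stage precondition."""


class FormatError(DataError):
    """A file does not conform to its declared dialect."""


class ReferenceMismatchError(DataError):
    """A variant's reference allele disagrees with the transcript sequence."""


class VariantRejected(DataError):
    """A variant cannot yield a presentable mutant peptide."""


class SynonymousVariantError(VariantRejected):
    """The variant does not change the protein sequence."""


class NonsenseVariantError(VariantRejected):
    """The variant introduces a stop with no mutant residue to present."""


class DesignError(NeoscreenError):
    """A sequence-design constraint (e.g. forbidden motif) cannot be met."""


class ConfigError(NeoscreenError):
    """Run configuration is invalid; carries one message per problem."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
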