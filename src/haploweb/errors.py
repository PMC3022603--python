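"""Exception hierarchy shared across the package.

All domain errors derive from :class:`HaplowebError` so callers (and the CLI)
can distinguish bad input from programming errors.
"""


class HaplowebError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HaplowebError):
    """Input file is malformed (bad FASTA/TSV structure, unknown columns...)."""


class AlignmentLengthError(FormatError):
    """Sequences within one marker do not share a common alignment length."""


class MultiplicityError(FormatError):
    """An individual carries more sequences than the marker's ploidy allows."""


class DuplicateRecordError(FormatError):
    """The same (individual, marker) pair occurs more than once in a table."""


class UniverseMismatchError(HaplowebError):
    """Markers were not sampled over the same set of individuals."""

    def __init__(self, message: str, missing: dict | None = None):
        super().__init__(message)
        self.missing = missing or {}


class PloidyError(HaplowebError):
    """Operation applied to a dataset of the wrong ploidy."""


class ConsistencyError(HaplowebError):
    """Cross-references between objects are broken (dangling haplotype id...)."""


class EnumerationCapError(HaplowebError):
    """Bipartition enumeration would exceed the configured block-count cap."""


class IncompatibleBipartitionsError(HaplowebError):
    """Kept bipartitions conflict pairwise and cannot be reconciled."""

    def __init__(self, conflicts):
        self.conflicts = list(conflicts)
        super().__init__(
            f"{len(self.conflicts)} pair(s) of retained bipartitions are "
            "mutually incompatible; lower the threshold or inspect the markers"
        )


class NonTerminationError(HaplowebError):
    """Iterative network construction exceeded its iteration cap."""


class ConfigError(HaplowebError):
    """A run or simulation configuration violates its invariants."""
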