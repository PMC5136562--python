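"""Exception hierarchy shared across the package."""


class BarcodeGapError(Exception):
    """Base class for all package-specific errors."""


class InputError(BarcodeGapError):
    """Malformed or empty input file."""


class AlignmentError(BarcodeGapError):
    """Sequences violate alignment invariants (unequal lengths, bad alphabet)."""


class LabelingError(BarcodeGapError):
    """A FASTA header does not parse to (species, sample_id), or labels conflict."""


class InsufficientDataError(BarcodeGapError):
    """Too few records/species/pairs for the requested statistic."""


class UndefinedSummaryError(InsufficientDataError):
    """A divergence or gap summary has an empty domain (e.g. no conspecific pairs)."""


class ThresholdError(BarcodeGapError):
    """A distance threshold cannot be derived (no intraspecific pairs)."""


class RootingError(BarcodeGapError):
    """Outgroup labels are invalid for rooting (missing or overlapping ingroup)."""


class ConfigError(BarcodeGapError):
    """Inconsistent simulation or pipeline configuration."""
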