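"""Exception hierarchy for the hamtbs toolkit."""


class HamTbsError(Exception):
    """Base class for all toolkit errors."""


class PanelFormatError(HamTbsError):
    """Malformed panel input (BED/FASTA) or invalid sequence characters."""


class CoordinateError(HamTbsError):
    """An interval falls outside its contig or is otherwise inconsistent."""


class ConfigurationError(HamTbsError):
    """Invalid simulation or analysis parameters."""


class PairingError(HamTbsError):
    """Read mates are inconsistent (e.g. mapped to different amplicons)."""


class UnknownAmpliconError(HamTbsError):
    """An alignment references an amplicon absent from the panel."""


class UndefinedConversionRateError(HamTbsError):
    """Conversion rate requested for a unit with no CHH observations."""


class InsufficientDesignError(HamTbsError):
    """Too few titration levels (or grid points) to fit the model."""


class ComparisonError(HamTbsError):
    """Condition comparison has an empty site intersection."""


class SamplingError(HamTbsError):
    """Requested subsample exceeds the fragment population."""


class DiagnosticError(HamTbsError):
    """A result failed an internal consistency diagnostic."""
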