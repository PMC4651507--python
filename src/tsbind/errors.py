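"""Exception hierarchy shared by all analysis stages."""


class TsbindError(Exception):
    """Base class for all tsbind errors."""


class PDBParseError(TsbindError):
    """Malformed or unsupported PDB content; message carries line/model context."""


class SchemaError(TsbindError):
    """A delimited table is missing required columns or has invalid values."""


class IntegrityError(TsbindError):
    """Inputs violate a cross-record consistency contract (ordering, alignment, duplicates)."""


class ValidationError(TsbindError):
    """A single value or object violates its own invariants."""


class ConfigurationError(TsbindError):
    """An analysis was requested with inconsistent or impossible settings."""


class DegenerateDataError(TsbindError):
    """The data carry no signal for the requested analysis (e.g. zero variance)."""
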