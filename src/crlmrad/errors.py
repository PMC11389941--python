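"""Exception hierarchy shared across the pipeline stages."""


class CrlmradError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrlmradError):
    """A configuration document or parameter set is invalid."""


class SchemaError(CrlmradError):
    """An input table violates the documented header/typing contract."""


class IntegrityError(CrlmradError):
    """Input data violates a uniqueness or consistency constraint."""


class DegenerateLesionError(CrlmradError):
    """A lesion mask is empty or too small for the requested features."""


class EstimationError(CrlmradError):
    """A model fit cannot be carried out (e.g. no events)."""


class ScoringError(CrlmradError):
    """A feature required for scoring is missing from the input."""


class UndefinedMetricError(CrlmradError):
    """A metric has no defined value on the given data (e.g. no comparable pairs)."""


class TaxonomyError(CrlmradError):
    """A feature has no role assignment in the geometric/texture taxonomy."""
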