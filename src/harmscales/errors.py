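"""Exception types raised across the package."""


class HarmScalesError(Exception):
    """Base class for package errors."""


class SchemaError(HarmScalesError):
    """A delimited-text file is missing mandatory columns or rows fail to parse."""


class IntegrityError(HarmScalesError):
    """Input data violate a uniqueness or consistency contract."""


class VocabularyError(HarmScalesError):
    """A scale definition names an item outside the registered vocabulary."""


class CalibrationError(HarmScalesError):
    """A generator target is unreachable for the supplied parameters."""


class UndefinedMetricError(HarmScalesError):
    """A requested quantity has no defined value (e.g. AUC with one outcome class)."""
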