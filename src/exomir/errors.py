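"""Exception hierarchy for the exomir pipeline."""


class ExomirError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ExomirError):
    """Input file is structurally malformed (e.g. ragged rows)."""


class ParseError(ExomirError):
    """A cell could not be interpreted as a Ct value or censoring token."""


class ValidationError(ExomirError):
    """Parsed data violate a documented invariant (duplicate ids, bad vocab...)."""


class CalibrationError(ExomirError):
    """Inter-plate calibration impossible (calibrator censored on some plate)."""


class QcError(ExomirError):
    """Spike-in quality control cannot be evaluated."""


class SelectionError(ExomirError):
    """Too few eligible reference candidates."""


class InsufficientDataError(ExomirError):
    """Not enough observations for the requested statistic."""


class DomainError(ExomirError):
    """Input outside the statistic's domain (e.g. non-positive mean Ct for a CV)."""


class CensoredInputError(ExomirError):
    """A censored Ct reached a computation that requires a finite value."""


class ConfigError(ExomirError):
    """Run configuration is invalid (unknown key, schema violation)."""


class PipelineError(ExomirError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
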