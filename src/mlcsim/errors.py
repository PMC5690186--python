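"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (config 2, data 3, analysis 4).
"""


class MlcsimError(Exception):
    """Base class for all package errors."""


class ConfigError(MlcsimError):
    """Invalid configuration (bad candidate lists, malformed YAML, ...)."""


class DataError(MlcsimError):
    """Invalid or inconsistent input data (schema violations, grid mismatches)."""


class AnalysisError(MlcsimError):
    """A computation cannot proceed (empty gamma mask, undefined FWHM, ...)."""


class CommissioningError(AnalysisError):
    """A commissioning stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
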