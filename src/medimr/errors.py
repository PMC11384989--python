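"""Exception hierarchy for the MR pipeline."""


class MedimrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MedimrError):
    """A file or configuration is malformed (e.g. a mandatory column is missing)."""


class NoInstrumentsError(MedimrError):
    """No genetic instruments are available for an MR leg."""


class InsufficientInstrumentsError(MedimrError):
    """Fewer instruments than the estimator's minimum (e.g. Egger needs k >= 3)."""


class LdMatrixError(MedimrError):
    """A SNP required for LD clumping is absent from the supplied LD matrix."""
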