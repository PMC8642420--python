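"""Exception hierarchy for targetmr."""


class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class ValidationError(TargetMRError):
    """A record or matrix violates one of its invariants."""


class FormatError(TargetMRError):
    """An input file does not conform to the expected dialect."""


class HarmonizationError(TargetMRError):
    """Exposure and outcome summary statistics cannot be reconciled."""


class EstimationError(TargetMRError):
    """An estimator was called on inputs it cannot handle."""
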