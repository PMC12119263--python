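"""Exception hierarchy shared across the pipeline."""


class QcascreenError(Exception):
    """Base class for all package errors."""


class ConfigError(QcascreenError):
    """Invalid configuration (bad marginals, thresholds, calibration specs...)."""


class ValidationError(QcascreenError):
    """Invalid data values (out-of-range items, wrong item counts...)."""


class DataError(QcascreenError):
    """Structurally unusable data (empty cohort, all rows missing...)."""
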