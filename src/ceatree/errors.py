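"""Exception types shared across the package."""


class ModelError(Exception):
    """A model is malformed, references unknown parameters, or cannot be evaluated."""


class ExpressionError(ModelError):
    """A payoff or branch-probability expression is invalid or cannot be evaluated."""


class CalibrationError(ModelError):
    """Calibration targets cannot be met with admissible payoff values."""
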