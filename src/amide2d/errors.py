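"""Package-specific exception types.

All inherit from ``ValueError`` so that callers who do not care about the
fine-grained category can catch a single base class.
"""


class ConfigurationError(ValueError):
    """A plan, config file or pipeline specification is inconsistent."""


class DegenerateDesignError(ValueError):
    """A statistical design is degenerate (single class, zero-variance target)."""


class AlignmentError(ValueError):
    """Spectra cannot be combined because their grids are incompatible."""


class IntegrityError(ValueError):
    """A library or frame violates an internal consistency requirement."""
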