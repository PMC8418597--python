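"""Package-specific error and warning types."""


class DataIntegrityError(ValueError):
    """An image, mask, or manifest record is internally inconsistent
    (shape mismatch, unknown label value, unjoinable patient record)."""


class UndefinedRatioError(ValueError):
    """A tumor-to-background ratio cannot be formed (healthy-region mean is zero)."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at the iteration cap before reaching tolerance."""
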