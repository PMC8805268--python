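"""Exception types raised by the pipeline."""


class FormatError(ValueError):
    """A file does not parse under its declared dialect."""


class ParameterError(ValueError):
    """An argument is outside its valid range."""


class ImputationError(RuntimeError):
    """Missing genotypes cannot be imputed (e.g. a fully missing SNP)."""


class DegenerateKernelError(RuntimeError):
    """A gene's sample kernel has no positive leading eigenvalue."""
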