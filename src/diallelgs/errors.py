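"""Exception hierarchy for diallelgs."""


class DiallelGSError(Exception):
    """Base class for all diallelgs errors."""


class DataError(DiallelGSError):
    """Malformed or inconsistent input data (genotypes, phenotypes, ids)."""


class QCError(DataError):
    """Quality-control filtering removed everything or hit invalid input."""


class NumericalError(DiallelGSError):
    """Numerical failure: singular system, indefinite kinship, diverged sampler."""
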