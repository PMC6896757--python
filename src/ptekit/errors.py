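"""Exception and warning hierarchy shared by all ptekit modules."""


class PTEError(Exception):
    """Base class for all ptekit errors."""


class ValidationError(PTEError):
    """Input data violates a structural invariant (bad study, bad partition)."""


class InputError(PTEError):
    """A file or stream could not be read or has the wrong shape."""


class ValidationWarning(UserWarning):
    """Non-fatal irregularity in input data (e.g. unusual pile counts)."""
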