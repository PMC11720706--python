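"""Exception hierarchy shared across the package."""


class NBTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NBTError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(NBTError):
    """Parsed data violates a domain invariant (e.g. negative survival time)."""


class ConvergenceError(NBTError):
    """An iterative fit failed to converge; carries diagnostics in args."""


class EmptySignatureError(NBTError):
    """Greedy selection reached an empty fixed point.

    Raised when no candidate gene survives the hindering/helpful iteration;
    usually a sign that the candidate pool carries no survival signal, or that
    the anchor threshold / pool size should be revisited.
    """
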