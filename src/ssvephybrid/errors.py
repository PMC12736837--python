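"""Exception types shared across the package."""


class SSVEPHybridError(Exception):
    """Base class for package errors."""


class LayoutError(SSVEPHybridError, ValueError):
    """Raised when an on-disk array does not match the declared tensor layout."""


class ShapeError(SSVEPHybridError, ValueError):
    """Raised on inconsistent array shapes (epochs, RBM states, model inputs)."""


class ChannelError(SSVEPHybridError, KeyError):
    """Raised when requested electrode labels are absent from a recording."""


class ArchitectureError(SSVEPHybridError, ValueError):
    """Raised when a network configuration is geometrically impossible."""


class DegenerateInputError(SSVEPHybridError, ValueError):
    """Raised on inputs that make the requested quantity undefined."""
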