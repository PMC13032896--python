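"""Exception types shared across the package."""


class UdpepError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(UdpepError, ValueError):
    """A peptide sequence contains an invalid residue or has the wrong length."""


class BalanceError(UdpepError, ValueError):
    """A design request cannot satisfy exact per-column level balance."""


class DomainError(UdpepError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class FormatError(UdpepError, ValueError):
    """A file does not conform to the expected tabular schema."""


class CapabilityError(UdpepError, RuntimeError):
    """An optional backend or dependency is unavailable."""


class ConfigError(UdpepError, ValueError):
    """A configuration object or file is invalid."""
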