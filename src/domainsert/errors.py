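"""Exception hierarchy for the domainsert package."""


class DomainsertError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DomainsertError, ValueError):
    """A textual field (family ID, residue-range string) could not be parsed."""


class ValidationError(DomainsertError, ValueError):
    """An in-memory object violates a structural invariant."""


class OverlapError(ValidationError):
    """Two domains of one protein overlap in residue space."""


class ConfigError(DomainsertError, ValueError):
    """A configuration (dialect options, generator parameters) is unusable."""


class ConsistencyError(DomainsertError, RuntimeError):
    """An internal invariant failed (e.g. a cycle in the nesting forest)."""
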