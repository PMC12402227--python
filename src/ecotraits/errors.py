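"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`EcotraitsError` so
callers (and the CLI) can map failures onto exit codes without matching on
message strings.
"""


class EcotraitsError(Exception):
    """Base class for all ecotraits errors."""


class SchemaError(EcotraitsError):
    """An input table is missing required columns or has malformed ones."""


class ReferentialError(EcotraitsError):
    """A link references a species id absent from the node table."""


class ValidationError(EcotraitsError):
    """A value violates a domain invariant (negative biomass, bad fraction...)."""


class ConfigError(EcotraitsError):
    """An index configuration is incomplete or inconsistent."""


class DegenerateNetworkError(EcotraitsError):
    """The web is too small or carries no flow for the requested index."""
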