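"""Exception hierarchy for petquant."""


class PetQuantError(Exception):
    """Base class for all petquant errors."""


class InvalidSpecError(PetQuantError, ValueError):
    """A parameter or configuration value violates its contract."""


class GeometryError(PetQuantError, ValueError):
    """An ROI/VOI or phantom layout is geometrically infeasible or empty."""


class UndefinedContrastError(PetQuantError, ValueError):
    """Hot-contrast recovery is undefined (true contrast ratio equals 1)."""


class ConfigError(InvalidSpecError):
    """A pipeline configuration file violates the schema.

    The message names the offending field with a dotted path.
    """
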