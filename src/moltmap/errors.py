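"""Exception types shared across the package."""


class MoltmapError(Exception):
    """Base class for all moltmap errors."""


class ConfigError(MoltmapError):
    """A configuration field is invalid; the message names the field."""


class InputError(MoltmapError):
    """An input table, sequence or argument violates a precondition."""
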