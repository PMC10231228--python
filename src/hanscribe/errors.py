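"""Exception hierarchy for hanscribe."""


class HanscribeError(Exception):
    """Base class for all hanscribe errors."""


class InputError(HanscribeError, ValueError):
    """Malformed or inconsistent user input (files, manifests, labels)."""


class EmptyDocumentError(InputError):
    """A document contained no usable text after cleaning/filtering."""


class FormatError(InputError):
    """A structured file (embedding table, manifest) violates its format."""


class ConfigError(HanscribeError, ValueError):
    """Invalid or inconsistent configuration values."""


class DimensionError(HanscribeError, ValueError):
    """Array shapes inconsistent with the declared model dimensions."""


class SplitError(HanscribeError, ValueError):
    """A data split left one side without documents of some class."""


class DivergenceError(HanscribeError, RuntimeError):
    """Training produced a non-finite loss."""
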