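"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input is outside the physical/mathematical domain of an operation."""


class PackingError(RuntimeError):
    """Synthetic cells could not be placed without overlap at the requested
    density within the retry budget."""


class FormatError(ValueError):
    """An input file is missing required columns or cannot be parsed."""
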