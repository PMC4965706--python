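"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised for invalid user-supplied inputs (files, tokens, bounds)."""


class VCFParseError(InputError):
    """Raised when a VCF cannot be parsed; names the file and record."""
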