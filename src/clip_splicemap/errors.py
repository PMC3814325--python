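"""Exception types shared across the package."""


class DataError(Exception):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class BedFormatError(DataError):
    """A BED record that violates the 6-column contract."""
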