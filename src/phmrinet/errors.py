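"""Exception types shared across the package."""


class DataError(ValueError):
    """Raised when input data violate a contract (non-finite values,
    zero-variance nodes, grid mismatches) as opposed to bad arguments."""
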