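"""Exception types shared across the pipeline."""


class ContractError(ValueError):
    """An input violates a documented precondition or invariant.

    Raised for malformed files, inconsistent metadata, and analysis
    preconditions (e.g. a dose-response fit requested without a dilution
    series).  The command-line layer maps this to exit code 2.
    """
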