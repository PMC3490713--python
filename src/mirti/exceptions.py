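"""Exception types shared across the package."""


class DegenerateDataError(ValueError):
    """Raised when the data are structurally unable to support a computation.

    Examples: an influence network with no positive scores, a constant
    feature matrix handed to clustering, a network too small to rewire.
    Distinct from plain input errors so callers (e.g. the CLI) can map it
    to a dedicated exit code.
    """
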