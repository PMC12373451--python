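"""Exception hierarchy shared across the package."""


class WayfindError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WayfindError):
    """A table is missing required columns or contains invalid values."""


class ConsistencyError(WayfindError):
    """Cross-table references are inconsistent (e.g. unknown level id)."""


class DegenerateInputError(WayfindError):
    """Input is valid but statistically degenerate (zero variance, empty class)."""


class FitError(WayfindError):
    """A model fit failed to converge; carries optimizer diagnostics in args."""
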