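"""Exception types shared across octflux."""


class OctfluxError(Exception):
    """Base class for octflux-specific failures."""


class InfeasibleRecipeError(OctfluxError, ValueError):
    """Requested flux cannot be realized in the trace window (too many peaks)."""


class DegenerateTraceError(OctfluxError, ValueError):
    """Operation requires a non-constant trace."""


class SchemaError(OctfluxError, ValueError):
    """Dataset or checkpoint file does not match the expected schema version."""
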