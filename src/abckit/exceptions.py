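"""Exception hierarchy for abckit.

All toolkit errors derive from :class:`ABCKitError` so callers can catch
everything the library raises with a single clause while still
distinguishing configuration problems from runtime simulation failures.
"""


class ABCKitError(Exception):
    """Base class for all abckit errors."""


class ConfigError(ABCKitError):
    """Malformed configuration file or invalid option value."""


class TableFormatError(ABCKitError):
    """Malformed simulation table or observed-statistics file."""


class SimulationError(ABCKitError):
    """A single simulator invocation failed (nonzero exit, bad output).

    Samplers treat this as a failed iteration, never as a fatal error:
    rejection and PMC redraw a fresh parameter vector, MCMC rejects the
    proposal.
    """


class EstimationError(ABCKitError):
    """Posterior estimation cannot proceed (rank deficiency, J too small...)."""


class TransformError(ABCKitError):
    """Invalid linear transform or transform/input mismatch."""
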