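"""Exception hierarchy shared across the package."""


class CapDropError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(CapDropError, ValueError):
    """A chip layout or one of its elements violates an invariant."""


class ConfigurationError(CapDropError, ValueError):
    """Missing or inconsistent configuration (fluid angles, pump, paths)."""


class SolverError(CapDropError, RuntimeError):
    """The hydraulic network cannot be solved (singular / inconsistent state)."""


class NoSpontaneousFilling(CapDropError, ValueError):
    """The fluid does not wet the channel: net advancing capillary pressure <= 0."""
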