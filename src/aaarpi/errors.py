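"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`AaaError` so the orchestrator can
report which stage failed and with which artifact.
"""


class AaaError(Exception):
    """Base class for all pipeline errors."""


class SpecError(AaaError):
    """A specification (phantom or run configuration) is invalid."""


class GeometryError(AaaError):
    """Surface/geometry construction failed (empty label, self-intersection, ...)."""


class MeshError(AaaError):
    """Tetrahedral meshing failed or produced an invalid mesh."""


class SolverError(AaaError):
    """The finite element solve failed (singular system, inverted element, ...)."""


class ConfigError(AaaError):
    """Run configuration file is malformed or inconsistent."""
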