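"""Exception hierarchy shared across the package."""


class ParattcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ParattcError, ValueError):
    """A domain object or argument violates its invariants."""


class GeometryError(ValidationError):
    """Kinematic input outside the valid flight domain."""


class DegenerateGeometryError(GeometryError):
    """The ball's ground track passes through the eye (rho = 0)."""


class InsideBallError(GeometryError):
    """The eye would be inside the ball (d <= ball radius)."""


class UndefinedPredictionError(ParattcError):
    """The TTC model is undefined at the requested state (cos(gamma) = 0)."""


class NoPrivilegedTimeError(ParattcError):
    """The prediction-error profile never crosses zero after launch."""


class DesignInfeasibleError(ParattcError):
    """No free-parameter value in the search interval yields a zero-error
    crossing at the requested flight fraction."""


class UndefinedRatioError(ParattcError):
    """A relative cue difference is undefined because the reference cue is zero."""


class FormatError(ParattcError, ValueError):
    """A file does not conform to the canonical CSV schema."""


class ConfigError(ParattcError, ValueError):
    """Invalid or incomplete run configuration."""


class PipelineStageError(ParattcError):
    """A stage of the end-to-end run failed; carries the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
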