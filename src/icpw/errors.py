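"""Exception hierarchy for the icpw package."""


class IcpwError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IcpwError, ValueError):
    """A simulation or analysis parameter violates its contract."""


class CalibrationInfeasibleError(IcpwError, ValueError):
    """No binormal parameterization satisfies the requested operating points."""


class NoPulsesError(IcpwError, ValueError):
    """No cardiac pulses could be located in the signal."""


class UndefinedRatioError(IcpwError, ZeroDivisionError):
    """P2/P1 is undefined because the P1 amplitude is zero (or negative)."""


class StageError(IcpwError, RuntimeError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
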