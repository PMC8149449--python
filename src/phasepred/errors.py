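"""Exception types shared across the package."""


class PhasepredError(Exception):
    """Base class for package errors."""


class FormatError(PhasepredError):
    """Malformed input file (non-uniform epochs, bad columns, ...)."""


class InsufficientDataError(PhasepredError):
    """Not enough valid data to produce a result (e.g. < 5 valid nights,
    no contiguous whole day of light)."""


class ConfigError(PhasepredError):
    """Invalid configuration value (e.g. bin width not dividing the span)."""


class UndeterminedDLMO(PhasepredError):
    """A melatonin profile with no qualifying threshold crossing."""


class DegenerateTrajectoryError(PhasepredError):
    """A pacemaker trajectory with no detectable oscillation."""
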