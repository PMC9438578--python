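"""Exception hierarchy for aortaflow.

All errors derive from :class:`AortaflowError` so callers can catch the
package's failures with a single except clause; the CLI maps
:class:`ConfigurationError` to exit code 1 and model/solver failures to 2.
"""


class AortaflowError(Exception):
    """Base class for all aortaflow errors."""


class DomainError(AortaflowError, ValueError):
    """An input lies outside the physical domain of an operation."""


class ConfigurationError(AortaflowError, ValueError):
    """Malformed configuration, unknown unit, or invalid parameter file."""


class ModelRegimeError(AortaflowError):
    """The model left its validity regime (e.g. dissipation exceeds drive)."""


class SolverError(AortaflowError):
    """A root-finder failed; carries diagnostics of the bracket endpoints."""


class FitError(AortaflowError):
    """A curve fit did not converge; carries optimizer diagnostics."""


class GeneratorError(AortaflowError):
    """A synthetic-data generator could not satisfy its invariants."""


class InterpolationError(AortaflowError, ValueError):
    """A requested point lies outside a tabulated curve (no extrapolation)."""


class CalibrationError(AortaflowError):
    """The frozen worked-example calibration is missing or corrupt."""
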