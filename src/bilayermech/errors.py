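"""Exception hierarchy for bilayermech.

All domain errors derive from :class:`BilayerMechError` so callers can
catch the package's failures with a single ``except`` clause; the ones
that signal bad arguments also derive from :class:`ValueError`.
"""


class BilayerMechError(Exception):
    """Base class for all bilayermech errors."""


class InvalidParameterError(BilayerMechError, ValueError):
    """A physical parameter is outside its admissible domain."""


class InvalidAngleError(InvalidParameterError):
    """A contact angle lies outside [0, 180) degrees."""


class InfeasibleTensionError(InvalidParameterError):
    """A bilayer tension exceeds twice the monolayer tension (cos > 1)."""


class UnidentifiableTensionError(BilayerMechError):
    """Drop shape carries no tension information (zero density contrast)."""


class NoPlateauError(BilayerMechError):
    """No terminal segment of a tension-time trace satisfies the slope criterion."""


class InsufficientReplicatesError(BilayerMechError):
    """Fewer than two replicate measurements were supplied."""


class UnderdeterminedFitError(BilayerMechError):
    """Too few data points to constrain the requested fit."""


class EmptyInputError(BilayerMechError):
    """All inputs were filtered out (e.g. every trajectory too short)."""


class SchemaError(BilayerMechError, ValueError):
    """A tabular input file is missing a required column or is malformed."""
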