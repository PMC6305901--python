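"""Exception hierarchy for the perturbstance package."""


class PerturbstanceError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PerturbstanceError, ValueError):
    """A generator or analysis parameter violates its contract."""


class NoPerturbationError(PerturbstanceError):
    """Onset detection was asked to run on a flat platform trace."""


class ReconciliationError(PerturbstanceError):
    """Trial metadata could not be matched one-to-one with detected onsets."""

    def __init__(self, message, unmatched=None):
        super().__init__(message)
        self.unmatched = list(unmatched) if unmatched is not None else []


class WindowBoundsError(PerturbstanceError, ValueError):
    """An analysis window falls outside the epoch it is applied to."""


class DegenerateBmrWindowError(PerturbstanceError, ValueError):
    """COP peak latency at or before 120 ms leaves no belated-response window."""


class ZeroMvcError(PerturbstanceError, ValueError):
    """An MVC reference amplitude of zero makes %MVC undefined."""

    def __init__(self, muscle):
        super().__init__(f"MVC reference for muscle {muscle!r} is zero")
        self.muscle = muscle


class UnreachableTargetError(PerturbstanceError):
    """The H-reflex never reaches the requested fraction of M-max."""

    def __init__(self, target_fraction, max_fraction):
        super().__init__(
            f"H-reflex reaches at most {max_fraction:.3f} of M-max on the "
            f"ascending limb; target {target_fraction:.3f} is unreachable"
        )
        self.target_fraction = target_fraction
        self.max_fraction = max_fraction


class NonPositiveDefiniteError(PerturbstanceError, ValueError):
    """Requested rank-correlation targets admit no valid latent covariance."""

    def __init__(self, offending_pairs):
        pairs = ", ".join(f"({a}, {b})" for a, b in offending_pairs)
        super().__init__(
            "latent correlation matrix is not positive definite; "
            f"offending pair(s): {pairs or 'unidentified'}"
        )
        self.offending_pairs = list(offending_pairs)


class UnbalancedDesignError(PerturbstanceError, ValueError):
    """A repeated-measures analysis received incomplete subject data."""

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class ConfigValidationError(PerturbstanceError, ValueError):
    """A run configuration failed schema validation."""

    def __init__(self, field_path, message):
        super().__init__(f"{field_path}: {message}")
        self.field_path = field_path
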