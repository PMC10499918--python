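"""Exception hierarchy for pykrm."""


class PyKRMError(Exception):
    """Base class for all pykrm errors."""


class InvalidShapeError(PyKRMError):
    """A station table violates the geometry contract (ordering, counts, signs)."""


class DeflatedSpecimenError(PyKRMError):
    """The specimen has no inflated swimbladder and is excluded from analysis."""


class ValidityRangeError(PyKRMError):
    """Requested incidence angle lies outside the model's validity range."""


class DomainError(PyKRMError, ValueError):
    """An argument lies outside its physical domain."""


class InsufficientDataError(PyKRMError):
    """Too few observations for the requested fit."""


class ConvergenceError(PyKRMError):
    """A series or iteration failed to converge at the configured truncation."""
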