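"""Exception hierarchy for vesselseg.

Every error class maps onto one contract family: structural network
validation, feature-map merging, data ingestion/augmentation, synthesis,
training, and metric definedness.
"""


class VesselSegError(Exception):
    """Base class for all vesselseg errors."""


class StructuralValidationError(VesselSegError):
    """A NetworkSpec violates a structural invariant (named in the message)."""


class MergeError(VesselSegError):
    """Two feature maps cannot be merged (shape mismatch)."""


class InputError(VesselSegError):
    """An input array/file does not satisfy an operation's precondition."""


class SplitError(VesselSegError):
    """A dataset cannot be split under the requested scheme."""


class AugmentationError(VesselSegError):
    """An augmentation op is out of bounds or ill-configured."""


class GenerationError(VesselSegError):
    """The synthetic generator could not reach its target within retries."""


class DivergenceError(VesselSegError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class UndefinedMetricError(VesselSegError):
    """A metric is undefined for the given counts (e.g. no positives)."""


class DegenerateTestError(VesselSegError):
    """A statistical test is undefined (e.g. zero-variance differences)."""
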