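"""Exception hierarchy.

All errors derive from :class:`MonoNetError`; shape/parameter problems also
derive from :class:`ValueError` so generic callers can catch them the usual way.
"""


class MonoNetError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(MonoNetError, ValueError):
    """Array shapes inconsistent with the model or with each other."""


class InvalidParameterError(MonoNetError, ValueError):
    """A parameter value is outside its valid domain (non-finite, wrong range)."""


class DegenerateRescalingError(MonoNetError, ValueError):
    """An alpha_i * beta_j product is too close to zero for 1/(alpha_i beta_j)."""


class StratificationError(MonoNetError, ValueError):
    """A class has too few members for the requested stratified split."""


class EmptySampleError(MonoNetError, ValueError):
    """An empirical-distribution operation received an empty sample."""


class DegenerateSamplingError(MonoNetError, RuntimeError):
    """The KernelSHAP regression system was singular; more samples needed."""


class TrainingDivergedError(MonoNetError, RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training loss became non-finite at epoch {epoch}")


class MissingLabelsError(MonoNetError, ValueError):
    """An operation requiring class labels received an unlabeled table."""


class CheckpointError(MonoNetError, RuntimeError):
    """A model checkpoint is corrupted or version-incompatible."""
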