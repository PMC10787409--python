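"""Exception types shared across the package."""


class CuffsegError(Exception):
    """Base class for package errors."""


class ConfigurationError(CuffsegError, ValueError):
    """Invalid configuration value or combination."""


class ShapeError(CuffsegError, ValueError):
    """Array shape violates a structural contract."""


class FormatError(CuffsegError, ValueError):
    """File is not in the expected on-disk format."""


class PairingError(CuffsegError, ValueError):
    """Image and mask collections are not correctly paired."""


class SplitError(CuffsegError, ValueError):
    """Subject-level split cannot be satisfied."""


class DataError(CuffsegError, ValueError):
    """Dataset is empty or otherwise unusable."""


class CheckpointError(CuffsegError, ValueError):
    """Checkpoint file is missing or corrupted."""


class TrainingDivergedError(CuffsegError, RuntimeError):
    """Loss became non-finite during optimisation."""

    def __init__(self, epoch: int, batch: int, loss: float):
        self.epoch, self.batch, self.loss = epoch, batch, loss
        super().__init__(
            f"non-finite loss ({loss}) at epoch {epoch}, batch {batch}")
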