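"""Exception hierarchy.

User-facing errors derive from :class:`PhenonetError` so the CLI can map
them to exit code 1; anything else is treated as an internal error.
"""


class PhenonetError(Exception):
    """Base class for user-facing errors."""


class ConfigurationError(PhenonetError):
    """Invalid parameter value or unknown enum member."""


class CapacityError(PhenonetError):
    """The requested rosette cannot be rendered at the given image size."""


class ShapeError(PhenonetError):
    """Layer shape algebra failed (incompatible input/output volumes)."""


class DataError(PhenonetError):
    """Dataset files are missing, malformed or inconsistent."""


class TrainingDivergenceError(PhenonetError):
    """Loss became non-finite during optimization."""

    def __init__(self, step: int, loss: float):
        self.step = step
        self.loss = loss
        super().__init__(
            f"training diverged at step {step}: loss is {loss!r} (non-finite); "
            "reduce the learning rate or check the input scaling"
        )
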