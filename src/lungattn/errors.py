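"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input values violate a precondition (non-finite, empty, out of range)."""


class DimensionError(ValueError):
    """Array shapes or channel counts are incompatible."""


class ShapeError(ValueError):
    """Spatial size does not meet a divisibility or size requirement."""


class PlacementParseError(ValueError):
    """A placement label contains an unknown or out-of-range token."""


class GenerationError(RuntimeError):
    """Phantom geometry could not be realized within the retry budget."""


class ConfigError(ValueError):
    """Configuration is inconsistent with the data or checkpoint."""


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration
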