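"""Package exception hierarchy (CLI maps these to exit codes)."""


class DscaError(Exception):
    """Base class for runtime failures (CLI exit code 1)."""


class ConfigError(DscaError):
    """Invalid configuration or schema violation (CLI exit code 2)."""


class TilingError(DscaError):
    """Scene dimensions not compatible with the tile grid."""


class DataError(DscaError):
    """Missing or inconsistent dataset inputs."""


class DivergenceError(DscaError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, step: int):
        super().__init__(f"non-finite loss at epoch {epoch}, step {step}")
        self.epoch = epoch
        self.step = step


class GenerationError(DscaError):
    """Synthetic scene generation could not satisfy its constraints."""
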