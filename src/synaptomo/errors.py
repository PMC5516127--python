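"""Exception hierarchy shared across the pipeline stages."""


class SynaptomoError(Exception):
    """Base class for all package errors."""


class ConfigError(SynaptomoError):
    """Invalid configuration value or inconsistent run description."""


class SceneTooCrowdedError(SynaptomoError):
    """Synthetic placement could not fit the requested puncta count."""

    def __init__(self, channel: str, placed: int, requested: int):
        self.channel = channel
        super().__init__(
            f"scene too crowded: placed {placed}/{requested} puncta in channel "
            f"{channel!r} before exhausting the retry cap"
        )


class RegistrationError(SynaptomoError):
    """Shift estimation failed (e.g. constant image: no registration signal)."""


class GridMismatchError(SynaptomoError):
    """Two voxel grids that must be congruent are not."""
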