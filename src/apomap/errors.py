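"""Exception types shared across the pipeline."""


class ApomapError(Exception):
    """Base class for pipeline errors."""


class NoLandmarksError(ApomapError):
    """No boundary landmarks found; event mapping is undefined."""


class MappingError(ApomapError):
    """Segment-relative mapping cannot be performed."""


class RegistrationError(ApomapError):
    """A profile cannot be registered to landmark peaks."""


class ConfigError(ApomapError):
    """Invalid run configuration."""
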