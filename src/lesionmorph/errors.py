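"""Exception hierarchy shared across the pipeline."""


class LesionMorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LesionMorphError):
    """Invalid cohort/run configuration (bad mixture, empty profile list, unknown key)."""


class SizingError(ConfigError):
    """A requested lesion does not fit the configured voxel grid."""


class DegenerateLesionError(LesionMorphError):
    """A mask became empty or otherwise unusable (e.g. after resampling or erosion)."""


class ParameterError(LesionMorphError):
    """Invalid analysis parameter combination (ward + non-Euclidean, perplexity >= n, ...)."""


class LesionIOError(LesionMorphError):
    """Malformed or unreadable on-disk artifact (NRRD, metadata CSV, config file)."""
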