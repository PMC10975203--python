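"""Exception hierarchy for crowngrowth."""


class CrownGrowthError(Exception):
    """Base class for all crowngrowth errors."""


class FormatError(CrownGrowthError, ValueError):
    """A file could not be parsed in the requested/inferred format."""


class ValidationError(CrownGrowthError, ValueError):
    """Input data violate a documented invariant (non-finite coordinates,
    duplicate tree ids, incompatible grids, ...)."""


class EmptyCloudError(ValidationError):
    """A point cloud contains no points (or none survive filtering)."""
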