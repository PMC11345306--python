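"""Exception hierarchy shared across the package."""


class GaitVarError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GaitVarError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(GaitVarError):
    """A dataset violates a structural invariant (duplicates, bad labels)."""


class CatalogueError(GaitVarError):
    """A feature id is unknown or inconsistent with the feature catalogue."""


class DegenerateSeriesError(GaitVarError):
    """A visit series is too short (or otherwise unfit) for a trend fit."""


class SingularDesignError(DegenerateSeriesError):
    """All ages in a series are identical; the regression design is singular."""


class DegenerateSampleError(GaitVarError):
    """A sample is constant where variability is required (e.g. Shapiro-Wilk)."""


class SampleSizeError(GaitVarError):
    """A statistical routine received fewer observations than it requires."""
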