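"""Exception hierarchy for the linkage pipeline.

Every error raised on a user-facing path derives from :class:`PeslinkError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class PeslinkError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PeslinkError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(PeslinkError):
    """A data row failed validation; the message lists row and field."""


class DataIntegrityError(PeslinkError):
    """Cross-table consistency violated (e.g. a linked patient with no episodes)."""


class DegenerateTableError(PeslinkError):
    """A contingency table with a zero cell or margin where the statistic is undefined."""


class SeparationError(PeslinkError):
    """Perfect or quasi-perfect separation detected while fitting a logistic model."""


class RankDeficiencyError(PeslinkError):
    """Rank-deficient design matrix; the message names the collinear columns."""


class OracleLookupError(PeslinkError):
    """A survey row was not generated from the population handed to the oracle."""
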