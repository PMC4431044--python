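"""Exception hierarchy for qgenie.

All package-raised errors derive from :class:`QGenieError` so callers can
catch at the package boundary; the subclasses distinguish input validation
failures from statistics that are mathematically undefined on the data.
"""


class QGenieError(Exception):
    """Base class for all qgenie errors."""


class ValidationError(QGenieError, ValueError):
    """Malformed or out-of-range input (bad rating value, missing item, ...)."""


class UndefinedStatisticError(QGenieError, ValueError):
    """A statistic is undefined on the given data (zero variance, zero denominator)."""


class DesignError(QGenieError, ValueError):
    """Rating design unsupported: missing cells, unbalanced groups, dims too small."""
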