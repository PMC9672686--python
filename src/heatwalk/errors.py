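"""Exception hierarchy for heatwalk."""


class HeatwalkError(Exception):
    """Base class for all heatwalk errors."""


class InvalidInputError(HeatwalkError, ValueError):
    """An argument violates a precondition (non-finite UTCI, negative length...)."""


class SchemaError(HeatwalkError, ValueError):
    """A file is structurally wrong (missing property, wrong feature type...)."""


class CoverageError(HeatwalkError, ValueError):
    """A survey panel is missing required (level, minute) cells."""


class UndefinedStatisticError(HeatwalkError, ValueError):
    """A statistic is undefined on the given data (e.g. zero total variance)."""
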