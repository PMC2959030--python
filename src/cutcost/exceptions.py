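"""Exception hierarchy for cutcost.

Every degenerate input raises a *named* error instead of silently
propagating NaN, so threshold-ranking code can never rank an undefined
index value.
"""


class CutcostError(ValueError):
    """Base class for all cutcost errors."""


class InvalidTableError(CutcostError):
    """A confusion table violates a structural invariant (e.g. empty)."""


class UndefinedRateError(CutcostError):
    """A rate is undefined because a table margin is empty.

    The message names the offending margin (diseased or healthy).
    """


class IndifferentCostsError(CutcostError):
    """All four benefits/costs are zero; the cost ratio is undefined."""


class UndefinedKappaError(CutcostError):
    """The weighted-kappa denominator is zero (degenerate level Q with
    an extreme cost ratio)."""


class UndefinedLogOddsError(CutcostError):
    """A confusion-table cell is zero, making the log odds ratio
    infinite or undefined. No continuity correction is applied."""


class DegeneratePopulationError(CutcostError):
    """Prevalence is exactly 0 or 1; the population holds one class."""


class SelectionError(CutcostError):
    """An index was undefined at some threshold during selection.

    The message names the threshold at which the index failed.
    """


class NoSolutionError(CutcostError):
    """The binormal density-ratio equation has no crossing in the
    searched bracket."""

    def __init__(self, message: str, crossings: list | None = None):
        super().__init__(message)
        self.crossings = list(crossings or [])


class RealizabilityError(CutcostError):
    """Requested (SE, SP, prevalence, total) combination implies
    non-integer cell counts; the message names the offending row."""
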