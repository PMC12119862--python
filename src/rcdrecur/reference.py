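"""Published validation counts, as machine-readable inputs.

These are the agreement counts reported by the internal-validation
exercise of the recurrence algorithm against ten-year randomised-trial
follow-up (1930 women), and the first-event cross-tabulation from the
initial registry training population (48,192 women).  They are inputs to
the metrics layer — feeding them through :mod:`rcdrecur.metrics` must
reproduce the published sensitivity/specificity/PPV/NPV percentages,
confidence intervals and date-agreement distributions.

Matched-pair date differences are published only in bins (<6 months,
6–12 months, >1 year), so the per-pair differences reconstructed here
are synthetic representatives placed at 0, 300 and 400 days: every
binned statistic computed from them is exact, per-day statistics are
not.
"""

from __future__ import annotations

import pandas as pd

from .metrics import AgreementTable
from .model import OutcomeType

__all__ = [
    "VALIDATION_N",
    "distant_agreement",
    "any_recurrence_agreement",
    "initial_training_crosstab",
]

#: Women in the internal validation group.
VALIDATION_N = 1930

# (event_both, trial_only, rcd_only, neither,
#  censored_trial, censored_rcd, censored_both, bin counts <6m/6-12m/>1y)
_DISTANT = {
    "all_time": (518, 24, 112, 1276, 0, 0, 0, (382, 56, 80)),
    "gt5y": (144, 17, 23, 1129, 53, 94, 470, (126, 10, 8)),
}

_ANY = {
    "all_time": (572, 20, 299, 1039, 0, 0, 0, (406, 42, 124)),
    "gt1y": (447, 17, 182, 1013, 33, 166, 72, (354, 31, 62)),
    "gt5y": (137, 7, 41, 923, 35, 265, 522, (128, 5, 4)),
    "adjusted": (570, 22, 237, 1101, 0, 0, 0, (435, 40, 95)),
}


def _binned_diffs(bins: tuple[int, int, int]) -> list[int]:
    lt6, mid, gt1y = bins
    return [0] * lt6 + [300] * mid + [400] * gt1y


def _table(row) -> AgreementTable:
    both, trial, rcd, neither, c_t, c_r, c_b, bins = row
    return AgreementTable.from_counts(
        both, trial, rcd, neither, c_t, c_r, c_b, diffs=_binned_diffs(bins)
    )


def distant_agreement(period: str = "all_time") -> AgreementTable:
    """Distant-recurrence agreement counts; ``period`` is ``all_time``
    or ``gt5y`` (analysis starting five years after randomisation)."""
    return _table(_DISTANT[period])


def any_recurrence_agreement(period: str = "all_time") -> AgreementTable:
    """Any-recurrence agreement counts; ``period`` is ``all_time``,
    ``gt1y``, ``gt5y`` or ``adjusted`` (all time, with the first-year
    post-validation adjustment applied)."""
    return _table(_ANY[period])


# First-event cross-tabulation from the initial registry training
# population: rows = registry gold standard, columns = algorithm output.
_CROSSTAB_ROWS = {
    OutcomeType.LOCOREGIONAL_RECURRENCE: (4993, 84, 426, 5, 75, 17, 39, 160),
    OutcomeType.DISTANT_RECURRENCE: (3, 4927, 31, 1, 67, 2, 8, 24),
    OutcomeType.RECURRENCE_TYPE_UNKNOWN: (55, 50, 2436, 8, 40, 5, 15, 152),
    OutcomeType.CONTRALATERAL_BREAST_CANCER: (3, 0, 0, 552, 0, 0, 0, 1),
    OutcomeType.BREAST_CANCER_DEATH: (0, 0, 0, 0, 1921, 0, 0, 0),
    OutcomeType.NON_BREAST_MALIGNANCY: (2, 0, 0, 0, 0, 2274, 0, 0),
    OutcomeType.NON_BREAST_CANCER_DEATH: (0, 0, 0, 0, 0, 0, 3788, 0),
}
_NO_EVENT_ROW = (0, 0, 0, 0, 0, 0, 0, 26028)


def initial_training_crosstab() -> pd.DataFrame:
    """8×8 first-event table (7 outcome types + no event) for the
    48,192-woman training population."""
    labels = [o.value for o in OutcomeType] + ["NO_EVENT"]
    rows = [list(_CROSSTAB_ROWS[o]) for o in OutcomeType] + [list(_NO_EVENT_ROW)]
    tab = pd.DataFrame(rows, index=labels, columns=labels, dtype=int)
    assert int(tab.to_numpy().sum()) == 48192
    return tab
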