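"""Between-ancestry comparison of study-level MAF and OR distributions.

Studies are treated as units (no weighting by sample size): the East Asian
studies' MAF values are compared with the Caucasian studies' by Welch's
unequal-variance two-sample t-test, and likewise for the reported OR
values.  The OR comparison deliberately uses the odds ratios *as
published* in the roster, since the question is whether the tabulated
values differ between the two literatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientStudiesError
from .study_io import StudyTable


@dataclass(frozen=True)
class ComparisonResult:
    variable: str  # maf | or
    mean_a: float
    mean_b: float
    t: float
    df: float  # Welch-Satterthwaite, fractional
    p: float


def welch_t(x: Sequence[float], y: Sequence[float], variable: str = "") -> ComparisonResult:
    """Welch's two-sample t-test (x minus y), two-sided.

    t = (mean_x - mean_y) / sqrt(s_x^2/n_x + s_y^2/n_y) with the
    Welch-Satterthwaite degrees of freedom.  Two identical constant samples
    give t = 0, p = 1 rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientStudiesError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if np.mean(x) == np.mean(y):
            return ComparisonResult(variable, float(np.mean(x)), float(np.mean(y)), 0.0, float(len(x) + len(y) - 2), 1.0)
    res = stats.ttest_ind(x, y, equal_var=False)
    return ComparisonResult(
        variable=variable,
        mean_a=float(np.mean(x)),
        mean_b=float(np.mean(y)),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def compare_groups(
    table: StudyTable, group_a: str = "east_asian", group_b: str = "caucasian"
) -> dict[str, ComparisonResult]:
    """MAF and OR comparisons between two ancestry groups (a minus b)."""
    a = [r for r in table if r.group == group_a]
    b = [r for r in table if r.group == group_b]
    return {
        "maf": welch_t([r.maf for r in a], [r.maf for r in b], variable="maf"),
        "or": welch_t([r.or_reported for r in a], [r.or_reported for r in b], variable="or"),
    }
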