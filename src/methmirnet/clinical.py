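"""Cohort-level statistics: summary t-tests, trait correlations, qRT-PCR.

Printed cohort tables report each variable as mean +/- SD per group; the
two-sample t-test is therefore recomputed directly from those summary
statistics, either with the pooled-variance form (df = n1 + n2 - 2) or
Welch's form with Satterthwaite degrees of freedom.  Trait-by-feature
correlation tables use the same Pearson/Spearman machinery as the
network module.  qRT-PCR relative expression follows the 2^-ddCT
transform of cycle thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .network import UndefinedCorrelationError, correlate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n of one variable in two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 < 0 or self.sd2 < 0:
            raise ParameterError("standard deviations must be nonnegative")
        if self.n1 < 2 or self.n2 < 2:
            raise ParameterError("each group needs n >= 2")


def ttest_from_summary(
    s: GroupSummary, mode: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from printed summary statistics.

    Returns (t, df, p).  'pooled' assumes equal variances
    (df = n1+n2-2); 'welch' uses the Satterthwaite approximation.  Two
    zero-SD groups with equal means yield t=0, p=1 by convention.
    """
    if mode not in ("pooled", "welch"):
        raise ParameterError(f"mode must be 'pooled' or 'welch', got {mode!r}")
    if s.sd1 == 0 and s.sd2 == 0:
        if s.mean1 == s.mean2:
            df = s.n1 + s.n2 - 2
            return 0.0, float(df), 1.0
        return math.inf, float(s.n1 + s.n2 - 2), 0.0
    res = stats.ttest_ind_from_stats(
        s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2,
        equal_var=(mode == "pooled"),
    )
    if mode == "pooled":
        df = float(s.n1 + s.n2 - 2)
    else:
        v1, v2 = s.sd1**2 / s.n1, s.sd2**2 / s.n2
        df = (v1 + v2) ** 2 / (v1**2 / (s.n1 - 1) + v2**2 / (s.n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, as printed tables typically do."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def trait_correlations(
    features: pd.DataFrame, traits: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature x trait correlation matrices (r and p).

    Rows of both inputs are subjects (aligned on their shared index);
    pairwise-complete observations are used per cell.  Cells with fewer
    than 3 complete pairs or a constant vector are NaN (a constant trait
    is logged and the run continues).
    """
    common = features.index.intersection(traits.index)
    if len(common) < 3:
        raise ParameterError("fewer than 3 shared subjects between tables")
    features = features.loc[common]
    traits = traits.loc[common]
    r = pd.DataFrame(index=features.columns, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=features.columns, columns=traits.columns, dtype=float)
    for f in features.columns:
        for t in traits.columns:
            x = features[f].to_numpy(dtype=float)
            y = traits[t].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                continue
            try:
                r.loc[f, t], p.loc[f, t] = correlate(x[keep], y[keep], method)
            except UndefinedCorrelationError:
                logger.warning(
                    "constant vector for %s x %s; cell left unavailable", f, t
                )
    return r, p


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-ddCT from qRT-PCR cycle thresholds.

    ddCT = (CT_target,case - CT_ref,case) - (CT_target,ctrl - CT_ref,ctrl).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ParameterError("CT values must be finite")
    ddct_val = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct_val)
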