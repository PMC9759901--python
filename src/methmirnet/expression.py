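"""Count normalization and differential-expression screening.

Small-RNA counts are depth-normalized to reads per million mapped reads
(RPM); mRNA counts are depth-and-length normalized to reads per kilobase
of exon per million mapped reads (RPKM).  Differential screening uses a
Welch t-test on log2(normalized value + pseudocount) with
Benjamini-Hochberg FDR control, and assigns each feature a status in
{'up', 'down', 'ns'} against configurable fold-change / P / Q thresholds.

Two threshold presets mirror the screening criteria used for the two
assay types: miRNAs are screened at |log2FC| >= 1, P < 0.05, Q <= 0.05;
mRNAs at P < 0.05 and Q <= 0.05 with no fold-change floor.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnnotationError, DesignError, NormalizationError, ParameterError

logger = logging.getLogger(__name__)

#: Screening presets: miRNA requires a 2-fold change; mRNA only P and Q.
DE_PRESETS: dict[str, dict[str, float]] = {
    "mirna": {"lfc_min": 1.0, "p_max": 0.05, "q_max": 0.05},
    "mrna": {"lfc_min": 0.0, "p_max": 0.05, "q_max": 0.05},
}

DE_COLUMNS = ["mean_case", "mean_control", "log2fc", "p_value", "q_value", "status"]


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization of a features x samples count matrix.

    Every column of the result sums to 1e6 (up to float tolerance).

    Raises
    ------
    NormalizationError
        If any sample has zero total counts; the message names the sample.
    """
    if (counts.values < 0).any():
        raise NormalizationError("negative counts in matrix")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalizationError(f"zero total counts in sample(s): {list(zero.index)}")
    return counts * 1e6 / totals


def rpkm_normalize(counts: pd.DataFrame, exon_length_bp: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads.

    value = raw * 1e9 / (sample_total * exon_length_bp)

    Raises
    ------
    AnnotationError
        If any feature lacks a positive exon length; lists the features.
    """
    lengths = exon_length_bp.reindex(counts.index)
    bad = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        raise AnnotationError(f"missing or non-positive exon length for: {list(bad)}")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalizationError(f"zero total counts in sample(s): {list(zero.index)}")
    return counts.mul(1e9, axis=0).div(totals, axis=1).div(lengths.astype(float), axis=0)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q values).

    Order-preserving with the input; q_i >= p_i elementwise; capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_groups(
    columns: pd.Index, groups: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    case = [c for c in columns if groups.get(c) == "case"]
    control = [c for c in columns if groups.get(c) == "control"]
    missing = [c for c in columns if c not in groups]
    if missing:
        raise DesignError(f"samples without a group label: {missing}")
    if len(case) < 2 or len(control) < 2:
        raise DesignError(
            f"each group needs >=2 samples (case={len(case)}, control={len(control)})"
        )
    return case, control


def de_screen(
    norm: pd.DataFrame,
    groups: Mapping[str, str],
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Screen a normalized matrix for differentially expressed features.

    Parameters
    ----------
    norm
        Normalized features x samples matrix (RPM or RPKM).
    groups
        Mapping sample id -> 'case' | 'control'.
    lfc_min, p_max, q_max
        Significance thresholds; see :data:`DE_PRESETS`.
    pseudocount
        Added inside every log2 to stabilize low counts.

    Returns
    -------
    DataFrame indexed by feature with columns
    mean_case, mean_control, log2fc, p_value, q_value, status.
    Features with all-zero values in both groups are excluded before
    testing; their number is logged and recorded in ``.attrs``.
    """
    case, control = _split_groups(norm.columns, groups)
    xs = norm[case].to_numpy(dtype=float)
    ys = norm[control].to_numpy(dtype=float)

    nonzero = (xs.sum(axis=1) + ys.sum(axis=1)) > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("de_screen: excluded %d all-zero features before testing", n_excluded)
    xs, ys = xs[nonzero], ys[nonzero]
    index = norm.index[nonzero]

    lx = np.log2(xs + pseudocount)
    ly = np.log2(ys + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features trip scipy's precision-loss warning; they are
        # handled explicitly below (p = 1 by convention)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(lx, ly, axis=1, equal_var=False)
    # zero variance in both groups -> test undefined; p = 1 by convention
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("de_screen: %d zero-variance features set to p=1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)

    mean_case = xs.mean(axis=1)
    mean_control = ys.mean(axis=1)
    log2fc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    q = bh_adjust(p)

    status = np.full(len(index), "ns", dtype=object)
    sig = (np.abs(log2fc) >= lfc_min) & (p < p_max) & (q <= q_max)
    status[sig & (log2fc > 0)] = "up"
    status[sig & (log2fc < 0)] = "down"

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "status": status,
        },
        index=index,
    )[DE_COLUMNS]
    table.attrs["n_all_zero_excluded"] = n_excluded
    return table
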