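"""Per-CpG methylation calling and differentially methylated regions.

Bisulfite sequencing yields, at every cytosine, a methylated read count m
and an unmethylated count u.  A cytosine is accepted as a methylation
site when its sequencing depth m+u reaches ``depth_min`` (default 5) and
the exact binomial upper-tail probability P(X >= m | n=m+u, p0) falls at
or below ``p_max`` (default 0.05), where p0 is the null methylation
proportion expected from bisulfite non-conversion / sequencing error.

Differentially methylated regions (DMRs) between two groups are found by
a sliding-window scan: fixed-width windows advanced by a fixed step are
tested with Fisher's exact test on the pooled (m, u) counts of the two
groups, Benjamini-Hochberg corrected across all testable windows,
filtered on P, Q and the absolute group difference in methylation level,
and finally merged where significant windows overlap.  A DMR is
classified 'hyper' when cases are more methylated than controls over the
region and 'hypo' otherwise.

CpG tables are BED-like TSVs with 0-based positions:
``chrom  pos  strand  m_<sample>  u_<sample> ...`` (wide, one column
pair per sample).  DMRs are written as BED6+ with score = -log10(p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ZeroCoverageError
from .expression import bh_adjust

logger = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass(frozen=True)
class SiteCall:
    """Outcome of the binomial methylation-site test at one cytosine."""

    m_count: int
    u_count: int
    methylation_level: float  # m/(m+u); NaN at zero coverage
    p_value: float
    is_called: bool


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float  # case mean level - control mean level
    p_value: float
    q_value: float
    direction: str  # 'hyper' | 'hypo'

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def binomial_upper_tail(m: int, n: int, p0: float) -> float:
    """Exact binomial upper-tail probability P(X >= m | n, p0)."""
    if not 0 < p0 < 1:
        raise ParameterError(f"null proportion p0 must lie in (0,1), got {p0}")
    return float(stats.binom.sf(m - 1, n, p0))


def methylation_level(m_count: int, u_count: int) -> float:
    """Methylation level m/(m+u); raises at zero coverage."""
    cov = m_count + u_count
    if cov <= 0:
        raise ZeroCoverageError("methylation level undefined at zero coverage")
    return m_count / cov


def call_site(
    m_count: int,
    u_count: int,
    p0: float = 0.005,
    depth_min: int = 5,
    p_max: float = 0.05,
) -> SiteCall:
    """Test one cytosine for methylation above the error null p0.

    A site is called iff its coverage reaches ``depth_min`` and the exact
    binomial upper tail is <= ``p_max``; under-covered sites are never
    called regardless of p.
    """
    if m_count < 0 or u_count < 0:
        raise ParameterError("counts must be nonnegative")
    cov = m_count + u_count
    p = binomial_upper_tail(m_count, cov, p0) if cov > 0 else 1.0
    level = m_count / cov if cov > 0 else float("nan")
    return SiteCall(m_count, u_count, level, p, cov >= depth_min and p <= p_max)


def call_sites(
    table: pd.DataFrame,
    sample: str,
    p0: float = 0.005,
    depth_min: int = 5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Vectorized site calling for one sample of a wide CpG table.

    Returns the site keys plus m, u, level, p_value and is_called.
    """
    m = table[f"m_{sample}"].to_numpy(dtype=int)
    u = table[f"u_{sample}"].to_numpy(dtype=int)
    if not 0 < p0 < 1:
        raise ParameterError(f"null proportion p0 must lie in (0,1), got {p0}")
    cov = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.binom.sf(m - 1, cov, p0)
        level = np.where(cov > 0, m / np.maximum(cov, 1), np.nan)
    p = np.where(cov > 0, p, 1.0)
    out = table[SITE_KEY].copy()
    out["m_count"], out["u_count"] = m, u
    out["methylation_level"] = level
    out["p_value"] = p
    out["is_called"] = (cov >= depth_min) & (p <= p_max)
    return out


def classify_dmr(mean_diff: float) -> str | None:
    """'hyper' iff cases exceed controls, 'hypo' iff below, None on a tie."""
    if not np.isfinite(mean_diff):
        raise ParameterError("mean_diff must be finite")
    if mean_diff > 0:
        return "hyper"
    if mean_diff < 0:
        return "hypo"
    logger.warning("DMR with zero group difference dropped as unclassifiable")
    return None


def _aligned(
    case_sites: pd.DataFrame, control_sites: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inner-join the two tables on site keys; return keys and count arrays."""
    case_m_cols = [c for c in case_sites.columns if c.startswith("m_")]
    case_u_cols = [c for c in case_sites.columns if c.startswith("u_")]
    ctrl_m_cols = [c for c in control_sites.columns if c.startswith("m_")]
    ctrl_u_cols = [c for c in control_sites.columns if c.startswith("u_")]
    clash = set(case_m_cols + case_u_cols) & set(ctrl_m_cols + ctrl_u_cols)
    if clash:
        raise ParameterError(f"sample columns present in both groups: {sorted(clash)}")
    merged = case_sites.merge(control_sites, on=SITE_KEY, how="inner")
    return (
        merged[SITE_KEY],
        merged[case_m_cols].to_numpy(dtype=np.int64),
        merged[case_u_cols].to_numpy(dtype=np.int64),
        merged[ctrl_m_cols].to_numpy(dtype=np.int64),
        merged[ctrl_u_cols].to_numpy(dtype=np.int64),
    )


def scan_windows(
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    window_bp: int = 1000,
    step_bp: int = 100,
    min_cpgs: int = 3,
    depth_min: int = 5,
    coverage_mode: Literal["pooled", "per_sample"] = "pooled",
    test: Literal["fisher", "ttest"] = "fisher",
) -> pd.DataFrame:
    """Sliding-window differential-methylation scan (no multiplicity yet).

    Both inputs are wide CpG tables sharing the coordinate universe.  A
    site enters the scan when its coverage reaches ``depth_min`` in both
    groups, pooled across samples by default or in every sample with
    ``coverage_mode='per_sample'``.  A window is testable iff it holds at
    least ``min_cpgs`` such sites.  ``test='fisher'`` applies Fisher's
    exact test to the pooled 2x2 (m, u) x (case, control) table;
    ``test='ttest'`` applies a Welch t-test to per-sample window mean
    levels (coverage-weighted).

    Returns one row per testable window: chrom, start, end, n_cpgs,
    pooled counts, mean_diff and p.
    """
    if min_cpgs < 1:
        raise ParameterError(f"min_cpgs must be >= 1, got {min_cpgs}")
    key, case_m, case_u, ctrl_m, ctrl_u = _aligned(case_sites, control_sites)
    if key.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpgs", "m_case", "u_case",
                     "m_ctrl", "u_ctrl", "mean_diff", "p_value"]
        )

    if coverage_mode == "pooled":
        ok = ((case_m + case_u).sum(axis=1) >= depth_min) & (
            (ctrl_m + ctrl_u).sum(axis=1) >= depth_min
        )
    elif coverage_mode == "per_sample":
        ok = ((case_m + case_u) >= depth_min).all(axis=1) & (
            (ctrl_m + ctrl_u) >= depth_min
        ).all(axis=1)
    else:
        raise ParameterError(f"unknown coverage_mode {coverage_mode!r}")

    ok = np.asarray(ok)
    rows: list[dict] = []
    for chrom, idx in key.groupby("chrom", sort=True).groups.items():
        sub = np.asarray(idx)
        sub = sub[ok[sub]]
        if len(sub) == 0:
            continue
        pos = key["pos"].to_numpy()[sub]
        order = np.argsort(pos, kind="stable")
        sub, pos = sub[order], pos[order]
        cm, cu = case_m[sub], case_u[sub]
        nm, nu = ctrl_m[sub], ctrl_u[sub]
        # cumulative sums for O(1) window totals
        ccm = np.concatenate([[0], cm.sum(axis=1).cumsum()])
        ccu = np.concatenate([[0], cu.sum(axis=1).cumsum()])
        cnm = np.concatenate([[0], nm.sum(axis=1).cumsum()])
        cnu = np.concatenate([[0], nu.sum(axis=1).cumsum()])

        starts = set()
        for p_ in pos:
            k_lo = int(np.ceil((p_ - window_bp + 1) / step_bp))
            k_hi = int(np.floor(p_ / step_bp))
            for k in range(k_lo, k_hi + 1):
                if k * step_bp >= 0:
                    starts.add(k * step_bp)
        for s in sorted(starts):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, s + window_bp, side="left")
            n_sites = hi - lo
            if n_sites < min_cpgs:
                continue
            mc, uc = int(ccm[hi] - ccm[lo]), int(ccu[hi] - ccu[lo])
            mn, un = int(cnm[hi] - cnm[lo]), int(cnu[hi] - cnu[lo])
            if mc + uc == 0 or mn + un == 0:
                continue
            mean_diff = mc / (mc + uc) - mn / (mn + un)
            if test == "fisher":
                p = float(stats.fisher_exact([[mc, uc], [mn, un]])[1])
            elif test == "ttest":
                p = _window_ttest(cm[lo:hi], cu[lo:hi], nm[lo:hi], nu[lo:hi])
            else:
                raise ParameterError(f"unknown test {test!r}")
            rows.append(
                dict(chrom=chrom, start=s, end=s + window_bp, n_cpgs=int(n_sites),
                     m_case=mc, u_case=uc, m_ctrl=mn, u_ctrl=un,
                     mean_diff=mean_diff, p_value=p)
            )
    return pd.DataFrame(rows)


def _window_ttest(cm, cu, nm, nu) -> float:
    """Welch t on per-sample coverage-weighted window levels."""
    with np.errstate(invalid="ignore", divide="ignore"):
        case_lv = cm.sum(axis=0) / np.maximum((cm + cu).sum(axis=0), 1)
        ctrl_lv = nm.sum(axis=0) / np.maximum((nm + nu).sum(axis=0), 1)
        _, p = stats.ttest_ind(case_lv, ctrl_lv, equal_var=False)
    return 1.0 if not np.isfinite(p) else float(p)


def detect_dmrs(
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    window_bp: int = 1000,
    step_bp: int = 100,
    min_cpgs: int = 3,
    min_mean_diff: float = 0.1,
    p_max: float = 0.05,
    q_max: float = 0.05,
    depth_min: int = 5,
    coverage_mode: Literal["pooled", "per_sample"] = "pooled",
    test: Literal["fisher", "ttest"] = "fisher",
) -> list[DMR]:
    """Detect DMRs between case and control CpG tables.

    Testable windows are BH-corrected together; windows passing
    p <= p_max, q <= q_max and |mean_diff| >= min_mean_diff are merged
    where they overlap (half-open semantics), each merged region keeping
    the minimum window p (and its q) while its mean_diff and CpG count
    are recomputed over the merged span.  Output is sorted and pairwise
    disjoint.
    """
    win = scan_windows(
        case_sites, control_sites, window_bp, step_bp, min_cpgs,
        depth_min, coverage_mode, test,
    )
    if win.empty:
        return []
    win = win.copy()
    win["q_value"] = bh_adjust(win["p_value"].to_numpy())
    sig = win[
        (win["p_value"] <= p_max)
        & (win["q_value"] <= q_max)
        & (win["mean_diff"].abs() >= min_mean_diff)
    ]
    logger.info(
        "DMR scan: %d testable windows -> %d significant before merging",
        len(win), len(sig),
    )
    if sig.empty:
        return []

    dmrs: list[DMR] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        members: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = row["start"], row["end"], [row]
            elif row["start"] < cur_end:  # strict: touching windows stay separate
                cur_end = max(cur_end, row["end"])
                members.append(row)
            else:
                d = _finalize_region(chrom, cur_start, cur_end, members,
                                     case_sites, control_sites, depth_min, coverage_mode)
                if d is not None:
                    dmrs.append(d)
                cur_start, cur_end, members = row["start"], row["end"], [row]
        if cur_start is not None:
            d = _finalize_region(chrom, cur_start, cur_end, members,
                                 case_sites, control_sites, depth_min, coverage_mode)
            if d is not None:
                dmrs.append(d)
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.end))
    return dmrs


def _finalize_region(
    chrom, start, end, members, case_sites, control_sites, depth_min, coverage_mode
) -> DMR | None:
    best = min(members, key=lambda r: r["p_value"])
    key, cm_all, cu_all, nm_all, nu_all = _aligned(case_sites, control_sites)
    in_span = (
        (key["chrom"] == chrom) & (key["pos"] >= start) & (key["pos"] < end)
    ).to_numpy()
    cm, cu = cm_all[in_span], cu_all[in_span]
    nm, nu = nm_all[in_span], nu_all[in_span]
    if coverage_mode == "pooled":
        ok = ((cm + cu).sum(axis=1) >= depth_min) & ((nm + nu).sum(axis=1) >= depth_min)
    else:
        ok = ((cm + cu) >= depth_min).all(axis=1) & ((nm + nu) >= depth_min).all(axis=1)
    cm, cu, nm, nu = cm[ok], cu[ok], nm[ok], nu[ok]
    mc, uc, mn, un = cm.sum(), cu.sum(), nm.sum(), nu.sum()
    if mc + uc == 0 or mn + un == 0:
        return None
    mean_diff = mc / (mc + uc) - mn / (mn + un)
    direction = classify_dmr(float(mean_diff))
    if direction is None:
        return None
    return DMR(
        chrom=str(chrom), start=int(start), end=int(end), n_cpgs=int(ok.sum()),
        mean_diff=float(mean_diff), p_value=float(best["p_value"]),
        q_value=float(best["q_value"]), direction=direction,
    )


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """DMR list as a DataFrame in BED6+ column order."""
    rows = [
        dict(chrom=d.chrom, start=d.start, end=d.end,
             name=f"{d.chrom}:{d.start}-{d.end}",
             score=-np.log10(max(d.p_value, 1e-300)), strand=".",
             mean_diff=d.mean_diff, q_value=d.q_value, n_cpgs=d.n_cpgs,
             direction=d.direction)
        for d in dmrs
    ]
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "mean_diff", "q_value", "n_cpgs", "direction"]
    return pd.DataFrame(rows, columns=cols)


def write_dmrs(dmrs: Sequence[DMR], path: str | Path) -> None:
    """Write DMRs as BED6+ TSV."""
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dmrs(path: str | Path) -> list[DMR]:
    """Read DMRs written by :func:`write_dmrs`."""
    df = pd.read_csv(path, sep="\t")
    return [
        DMR(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_cpgs=int(r.n_cpgs), mean_diff=float(r.mean_diff),
            p_value=float(10 ** -r.score), q_value=float(r.q_value),
            direction=str(r.direction))
        for r in df.itertuples()
    ]


def dmr_methylation_levels(
    dmrs: Sequence[DMR], cpg_table: pd.DataFrame, samples: Sequence[str]
) -> pd.DataFrame:
    """Per-sample coverage-weighted mean methylation level of each DMR.

    Rows are DMR names ('chrom:start-end'), columns samples; a sample
    with no reads over the region gets NaN.
    """
    out = {}
    for d in dmrs:
        mask = (
            (cpg_table["chrom"] == d.chrom)
            & (cpg_table["pos"] >= d.start)
            & (cpg_table["pos"] < d.end)
        )
        sub = cpg_table[mask]
        vals = []
        for s in samples:
            m = sub[f"m_{s}"].sum()
            u = sub[f"u_{s}"].sum()
            vals.append(m / (m + u) if (m + u) > 0 else np.nan)
        out[f"{d.chrom}:{d.start}-{d.end}"] = vals
    return pd.DataFrame(out, index=list(samples)).T


def read_cpg_table(path: str | Path) -> pd.DataFrame:
    """Read a wide BED-like CpG TSV (chrom, pos, strand, m_*, u_*)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df


def write_cpg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
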