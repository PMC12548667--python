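"""Test-retest reliability: ICC(3,1), bins, group contrasts, edge-wise maps.

The reliability model is the two-way mixed-effects, single-rater, consistency
intraclass correlation ICC(3,1) of Shrout & Fleiss.  For an n x k table
(subjects x sessions, here k = 2) the two-way ANOVA decomposition gives
between-subject (BMS) and error (EMS) mean squares and

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS),

with a 95% confidence interval from F-distribution bounds on F = BMS / EMS.
Consistency ICC ignores the session main effect, so adding a constant to one
session leaves it unchanged.

Estimates are binned poor (< 0.40), fair [0.40, 0.60), good [0.60, 0.80],
excellent (> 0.80).  Negative estimates are reported as computed (binned
poor), preserving the estimator's sampling distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BINS = ("poor", "fair", "good", "excellent")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int
    n_subjects: int
    k_sessions: int = 2

    @property
    def bin(self) -> str:
        return classify_icc(self.icc)


@dataclass(frozen=True)
class GroupComparison:
    t_value: float
    df: int
    p_value: float
    cohens_d: float
    metric_name: str = ""


def classify_icc(icc: float) -> str:
    """poor < 0.40 <= fair < 0.60 <= good <= 0.80 < excellent."""
    if not np.isfinite(icc):
        raise ValueError("cannot bin a non-finite ICC")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc <= 0.80:
        return "good"
    return "excellent"


def icc_3_1(
    session1: np.ndarray, session2: np.ndarray, alpha: float = 0.05
) -> ICCResult:
    """ICC(3,1) with a (1 - alpha) confidence interval for a two-session table.

    Subjects with a missing value in either session are dropped pairwise
    (count logged).  Requires at least 3 complete subjects.
    """
    x1 = np.asarray(session1, dtype=float)
    x2 = np.asarray(session2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("sessions must be equal-length vectors")
    valid = np.isfinite(x1) & np.isfinite(x2)
    dropped = int((~valid).sum())
    if dropped:
        logger.info("dropping %d subject(s) with missing values", dropped)
    x1, x2 = x1[valid], x2[valid]
    n = x1.size
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, got {n}")
    k = 2
    data = np.column_stack([x1, x2])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    sess_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_sess = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = max(ss_total - ss_subj - ss_sess, 0.0)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    bms = ss_subj / df1
    ems = ss_err / df2
    if ems <= 0.0 or (bms > 0 and ems < bms * 1e-12):
        # perfect within-subject agreement (to numerical precision)
        return ICCResult(1.0, 1.0, 1.0, float("inf"), df1, df2, n, k)
    icc = (bms - ems) / (bms + (k - 1) * ems)
    f = bms / ems
    f_low = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_up = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_up - 1) / (f_up + k - 1)
    return ICCResult(
        float(icc), float(ci_low), float(ci_high), float(f), df1, df2, n, k
    )


def compare_groups(
    iccs_a: np.ndarray, iccs_b: np.ndarray, metric_name: str = ""
) -> GroupComparison:
    """Independent two-sample pooled-variance t test on Fisher-z ICCs.

    Each group contributes one ICC per atlas; values are Fisher transformed
    before testing.  Cohen's d is the mean difference over the pooled SD, on
    the z scale.
    """
    za = np.arctanh(np.clip(np.asarray(iccs_a, dtype=float), -1 + 1e-7, 1 - 1e-7))
    zb = np.arctanh(np.clip(np.asarray(iccs_b, dtype=float), -1 + 1e-7, 1 - 1e-7))
    if za.size < 2 or zb.size < 2:
        raise ValueError("need at least 2 ICCs per group")
    na, nb = za.size, zb.size
    df = na + nb - 2
    pooled_var = (
        (na - 1) * za.var(ddof=1) + (nb - 1) * zb.var(ddof=1)
    ) / df
    if pooled_var <= 0:
        logger.warning("zero pooled variance; t undefined for %s", metric_name)
        return GroupComparison(float("nan"), df, float("nan"), 0.0, metric_name)
    t, p = stats.ttest_ind(za, zb, equal_var=True)
    d = (za.mean() - zb.mean()) / np.sqrt(pooled_var)
    return GroupComparison(float(t), df, float(p), float(d), metric_name)


# --------------------------------------------------------------------------- #
# tables
# --------------------------------------------------------------------------- #

_CELL_KEYS = ["group", "atlas", "variant", "metric", "level", "network"]


def metric_reliability_table(
    metric_values: pd.DataFrame,
    cell_keys: list[str] | None = None,
) -> pd.DataFrame:
    """One ICC(3,1) per (group, atlas, variant, metric, level, network) cell.

    ``metric_values`` is the long-format output of
    :func:`connrel.graph.compute_all` concatenated over subjects and sessions
    (columns: subject, session, group, atlas, variant, metric, level,
    network, value).  Cells with fewer than 3 complete subjects are reported
    with missing ICC fields.
    """
    keys = cell_keys or _CELL_KEYS
    df = metric_values.copy()
    df["network"] = df["network"].fillna("")
    rows = []
    for cell, sub in df.groupby(keys, sort=True, dropna=False):
        wide = sub.pivot_table(
            index="subject", columns="session", values="value", aggfunc="first"
        )
        record = dict(zip(keys, cell))
        if {1, 2}.issubset(wide.columns):
            x1 = wide[1].to_numpy()
            x2 = wide[2].to_numpy()
            complete = np.isfinite(x1) & np.isfinite(x2)
            if complete.sum() >= 3:
                res = icc_3_1(x1, x2)
                record.update(
                    icc=res.icc,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    f_value=res.f_value,
                    bin=res.bin,
                    n=res.n_subjects,
                )
            else:
                record.update(
                    icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                    f_value=np.nan, bin="NA", n=int(complete.sum()),
                )
        else:
            record.update(
                icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                f_value=np.nan, bin="NA", n=0,
            )
        rows.append(record)
    return pd.DataFrame(rows)


def summarize_across_atlases(table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, variant, metric): mean ICC and min-max range over atlases."""
    sub = table[table["level"] != "per_network"]
    out = (
        sub.groupby(["group", "variant", "metric"], sort=True)["icc"]
        .agg(["mean", "min", "max", "count"])
        .reset_index()
        .rename(columns={"mean": "icc_mean", "min": "icc_min", "max": "icc_max",
                         "count": "n_atlases"})
    )
    return out


# --------------------------------------------------------------------------- #
# edge-wise reliability
# --------------------------------------------------------------------------- #


def edgewise_icc(
    session1_z: np.ndarray,
    session2_z: np.ndarray,
    alpha: float = 0.05,
    min_subjects: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Vectorized per-edge ICC(3,1) over stacked connectome matrices.

    Parameters are (n_subjects x N x N) stacks of Fisher-z matrices, one per
    session.  Returns (icc_matrix, ci_low_matrix, ci_high_matrix,
    bin_table) where bin_table holds the proportion of supported edges in
    each reliability bin plus the excluded-edge count.
    """
    z1 = np.asarray(session1_z, dtype=float)
    z2 = np.asarray(session2_z, dtype=float)
    if z1.shape != z2.shape or z1.ndim != 3:
        raise ValueError("expected matching (n_subjects, N, N) stacks")
    n_sub, n_nodes, _ = z1.shape
    iu = np.triu_indices(n_nodes, k=1)
    x1 = z1[:, iu[0], iu[1]]  # n_sub x E
    x2 = z2[:, iu[0], iu[1]]

    icc, lo, hi = _vector_icc(x1, x2, alpha=alpha, min_subjects=min_subjects)

    def _expand(v: np.ndarray) -> np.ndarray:
        m = np.full((n_nodes, n_nodes), np.nan)
        m[iu] = v
        m[(iu[1], iu[0])] = v
        return m

    supported = np.isfinite(icc)
    n_excluded = int((~supported).sum())
    if n_excluded:
        logger.info("%d edge(s) lacked >= %d complete subjects", n_excluded,
                    min_subjects)
    props = {}
    if supported.any():
        bins = np.array([classify_icc(v) for v in icc[supported]])
        for b in BINS:
            props[b] = float(np.mean(bins == b))
    else:
        props = {b: float("nan") for b in BINS}
    bin_table = pd.DataFrame(
        [{**props, "n_edges": int(supported.sum()), "n_excluded": n_excluded}]
    )
    return _expand(icc), _expand(lo), _expand(hi), bin_table


def _vector_icc(
    x1: np.ndarray, x2: np.ndarray, alpha: float = 0.05, min_subjects: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ICC(3,1) + CI per column of two (n x E) session tables (k = 2)."""
    valid = np.isfinite(x1) & np.isfinite(x2)
    n_e = valid.sum(axis=0).astype(float)
    s1 = np.where(valid, x1, 0.0)
    s2 = np.where(valid, x2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1.sum(axis=0) / n_e
        m2 = s2.sum(axis=0) / n_e
        grand = (m1 + m2) / 2.0
        subj_mean = (s1 + s2) / 2.0
        ss_subj = 2.0 * np.where(valid, (subj_mean - grand) ** 2, 0.0).sum(axis=0)
        ss_sess = n_e * ((m1 - grand) ** 2 + (m2 - grand) ** 2)
        ss_tot = (
            np.where(valid, (s1 - grand) ** 2, 0.0).sum(axis=0)
            + np.where(valid, (s2 - grand) ** 2, 0.0).sum(axis=0)
        )
        ss_err = np.clip(ss_tot - ss_subj - ss_sess, 0.0, None)
        df = n_e - 1.0
        bms = ss_subj / df
        ems = ss_err / df
        icc = (bms - ems) / (bms + ems)
        f = bms / ems
        f_crit = stats.f.ppf(1 - alpha / 2, df, df)
        f_low = f / f_crit
        f_up = f * f_crit
        lo = (f_low - 1) / (f_low + 1)
        hi = (f_up - 1) / (f_up + 1)
    perfect = (ems <= 0) & (n_e >= min_subjects)
    icc = np.where(perfect, 1.0, icc)
    lo = np.where(perfect, 1.0, lo)
    hi = np.where(perfect, 1.0, hi)
    unsupported = n_e < min_subjects
    icc = np.where(unsupported, np.nan, icc)
    lo = np.where(unsupported, np.nan, lo)
    hi = np.where(unsupported, np.nan, hi)
    return icc, lo, hi


def size_reliability_correlation(
    network_table: pd.DataFrame,
    size_col: str = "n_nodes",
    icc_col: str = "icc",
) -> tuple[float, int, float]:
    """Pearson r between network size and Fisher-z ICC, pooled across rows.

    Rows are (network, group, atlas) cells; returns (r, df, p) with
    df = pairs - 2.
    """
    sizes = network_table[size_col].to_numpy(dtype=float)
    iccs = network_table[icc_col].to_numpy(dtype=float)
    valid = np.isfinite(sizes) & np.isfinite(iccs)
    sizes, iccs = sizes[valid], iccs[valid]
    if sizes.size < 4:
        raise ValueError("need at least 4 (network, ICC) pairs")
    if np.ptp(sizes) == 0:
        raise ValueError("network sizes are constant; correlation undefined")
    z = np.arctanh(np.clip(iccs, -1 + 1e-7, 1 - 1e-7))
    r, p = stats.pearsonr(sizes, z)
    return float(r), int(sizes.size - 2), float(p)
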