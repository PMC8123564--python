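"""Within-subject inferential statistics.

Implements the classical two-way repeated-measures ANOVA decomposition
(each effect tested against its own effect-by-subject interaction) with
partial eta-squared effect sizes, Bonferroni-corrected pairwise follow-ups,
and the repeated-observations within-subjects correlation coefficient
(subject treated as a categorical covariate).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "AnovaResult",
    "WSCorrResult",
    "rm_anova_2way",
    "bonferroni_pairwise",
    "within_subject_corr",
]


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect of a repeated-measures ANOVA."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class WSCorrResult:
    """Within-subjects correlation (subject-centred Pearson r)."""

    r: float
    df: int
    p: float
    n: int
    n_subjects: int


def _cell_cube(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[np.ndarray, list, list]:
    """Pivot a tidy table into a (subjects, A-levels, B-levels) cube."""
    a_col, b_col = within
    piv = data.pivot_table(
        index=subject, columns=[a_col, b_col], values=dv, aggfunc="mean", observed=True
    )
    a_levels = sorted(data[a_col].unique().tolist())
    b_levels = sorted(data[b_col].unique().tolist())
    full = pd.MultiIndex.from_product([a_levels, b_levels])
    if piv.isna().any().any() or not set(full).issubset(set(piv.columns)):
        raise ValueError("design must be complete and balanced (no missing cells)")
    piv = piv.reindex(columns=full)
    counts = data.groupby([subject, a_col, b_col], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("each (subject, A, B) cell must appear exactly once")
    cube = piv.to_numpy(dtype=float).reshape(len(piv), len(a_levels), len(b_levels))
    return cube, a_levels, b_levels

def _gg_epsilon(diffs: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects-by-contrasts score matrix."""
    if diffs.shape[1] < 2:
        return 1.0
    cov = np.cov(diffs, rowvar=False)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    k = diffs.shape[1]
    denom = k * float(np.sum(eig**2))
    if denom <= 0:
        return 1.0
    return float(min(np.sum(eig) ** 2 / denom, 1.0))


def _contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast matrix (k x k-1), e.g. normalised Helmert."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "observer_id",
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a balanced complete cell table.

    Each effect (A, B, A:B) is tested against its own interaction with
    subjects.  Partial eta-squared is ``SS_effect / (SS_effect + SS_error)``.
    With ``gg_correction`` the p-values use Greenhouse-Geisser-adjusted
    degrees of freedom (the raw df are still reported).

    Returns a DataFrame with one row per effect.
    """
    a_col, b_col = within
    y, a_levels, b_levels = _cell_cube(data, dv, within, subject)
    n, p, q = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = n * q * np.sum((m_a - grand) ** 2)
    ss_b = n * p * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    ss_as = q * np.sum(
        (m_as - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    ss_bs = p * np.sum(
        (m_bs - m_s[:, None] - m_b[None, :] + grand) ** 2
    )
    resid = (
        y
        - m_as[:, :, None]
        - m_bs[:, None, :]
        - m_ab[None, :, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    # conservation check: the full decomposition must recover the total SS
    ss_s = p * q * np.sum((m_s - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    parts = ss_a + ss_b + ss_ab + ss_s + ss_as + ss_bs + ss_abs
    if not np.isclose(parts, ss_total, rtol=1e-8, atol=1e-8):
        raise AssertionError("sum-of-squares decomposition failed to conserve")

    effects = [
        (a_col, ss_a, p - 1, ss_as, (p - 1) * (n - 1)),
        (b_col, ss_b, q - 1, ss_bs, (q - 1) * (n - 1)),
        (f"{a_col}:{b_col}", ss_ab, (p - 1) * (q - 1), ss_abs, (p - 1) * (q - 1) * (n - 1)),
    ]
    rows = []
    for name, ss_e, df1, ss_err, df2 in effects:
        if ss_err <= 0:
            f_val, p_val = np.inf if ss_e > 0 else 0.0, np.nan
        else:
            f_val = (ss_e / df1) / (ss_err / df2)
            p_val = float(sstats.f.sf(f_val, df1, df2))
        eps = None
        if gg_correction:
            ca, cb = _contrasts(p), _contrasts(q)
            if name == a_col:
                scores = m_as @ ca
            elif name == b_col:
                scores = m_bs @ cb
            else:
                flat = y.reshape(n, p * q)
                scores = flat @ np.kron(ca, cb)
            eps = _gg_epsilon(scores)
            p_val = float(sstats.f.sf(f_val, df1 * eps, df2 * eps))
        rows.append(
            AnovaResult(
                effect=name,
                F=float(f_val),
                df1=df1,
                df2=df2,
                p=p_val,
                partial_eta_sq=float(ss_e / (ss_e + ss_err)) if (ss_e + ss_err) > 0 else 0.0,
                gg_epsilon=eps,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if not gg_correction:
        out = out.drop(columns=["gg_epsilon"])
    return out


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    subject: str = "observer_id",
) -> pd.DataFrame:
    """Paired-t pairwise comparisons across a factor's levels.

    Other within factors are collapsed by subject mean first.  Raw p-values
    are multiplied by the number of comparisons (k*(k-1)/2) and capped at 1.
    """
    levels = sorted(data[factor].unique().tolist())
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    collapsed = (
        data.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    )
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for la, lb in pairs:
        a, b = collapsed[la].to_numpy(), collapsed[lb].to_numpy()
        diff = a - b
        if np.allclose(diff, 0):
            t_val, p_raw = 0.0, 1.0
        else:
            t_val, p_raw = sstats.ttest_rel(a, b)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_diff": float(np.mean(diff)),
                "t": float(t_val),
                "df": len(a) - 1,
                "p_raw": float(p_raw),
                "p_adj": float(min(p_raw * m, 1.0)),
                "n_comparisons": m,
            }
        )
    return pd.DataFrame(rows)


def within_subject_corr(
    x: Sequence[float],
    y: Sequence[float],
    subjects: Sequence,
) -> WSCorrResult:
    """Correlation of repeated measures with between-subject variance removed.

    x and y are centred within each subject; r is the Pearson correlation of
    the centred values, tested on ``df = N - n_subjects - 1`` via the t
    transform.  Equivalent to entering subject as a categorical factor in a
    multiple regression of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    if not (len(x) == len(y) == len(subjects)):
        raise ValueError("x, y, subjects must have equal length")
    uniq = pd.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects")
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for s in uniq:
        sel = subjects == s
        if sel.sum() < 2:
            raise ValueError("need at least 2 observations per subject")
        xc[sel] = x[sel] - x[sel].mean()
        yc[sel] = y[sel] - y[sel].mean()
    ss_x = float(np.sum(xc**2))
    ss_y = float(np.sum(yc**2))
    if ss_x <= 0:
        raise ValueError("x is constant within every subject; r undefined")
    if ss_y <= 0:
        raise ValueError("y is constant within every subject; r undefined")
    r = float(np.sum(xc * yc) / np.sqrt(ss_x * ss_y))
    n = len(x)
    df = n - len(uniq) - 1
    if df <= 0:
        raise ValueError("not enough observations for inference")
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) >= 1.0:
        p = 0.0
    else:
        t_val = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = float(2.0 * sstats.t.sf(abs(t_val), df))
    return WSCorrResult(r=r_clip, df=df, p=p, n=n, n_subjects=len(uniq))
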