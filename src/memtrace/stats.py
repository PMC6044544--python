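"""Group-level inference for repeated-measures designs.

Classical within-subject machinery: one-sample t tests of score
detectability, one-way and two-way repeated-measures ANOVAs with Mauchly's
sphericity test and Greenhouse-Geisser degree-of-freedom adjustment,
Bonferroni-corrected paired post hocs (one-tailed where a direction was
planned), Cousineau-normalised within-subject error bars, and the ICC(2,1)
interrater reliability coefficient (two-way random effects, absolute
agreement, single measure).

All ANOVAs are computed by the full within-subject sums-of-squares
decomposition — the form classical statistics packages print — rather than
via a mixed-model approximation.  Greenhouse-Geisser correction multiplies
both degrees of freedom by the estimated epsilon whenever Mauchly's test
rejects at p < .05 (threshold configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    """A repeated-measures F test with sphericity diagnostics."""

    F: float
    df1: float
    df2: float
    p: float
    epsilon: float
    sphericity_violated: bool
    mauchly_W: float
    mauchly_p: float

    def __str__(self) -> str:
        def fmt(d: float) -> str:
            return f"{d:g}" if float(d).is_integer() else f"{d:.2f}"

        return f"F({fmt(self.df1)},{fmt(self.df2)}) = {self.F:.2f}, p = {self.p:.3f}"


@dataclass
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t test; returns (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    t, p = sps.ttest_1samp(x, mu0)
    return float(t), len(x) - 1, float(p)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    h = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))[0]
    return h[:, 1:].T


def sphericity(table: np.ndarray) -> tuple[float, float, float]:
    """Mauchly's W with its chi-square p, and Greenhouse-Geisser epsilon.

    Both are computed from the covariance of orthonormal within-subject
    contrasts.  For k = 2 sphericity holds trivially (W = 1, epsilon = 1).
    When too few subjects make the contrast covariance singular, W is NaN
    and the caller should treat sphericity as violated.
    """
    y = np.asarray(table, dtype=float)
    n, k = y.shape
    if k == 2:
        return 1.0, 1.0, 1.0
    C = _orthonormal_contrasts(k)
    S = np.cov(y, rowvar=False, ddof=1)
    Sc = C @ S @ C.T
    tr = np.trace(Sc)
    eps = float(tr**2 / ((k - 1) * np.trace(Sc @ Sc)))
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    sign, logdet = np.linalg.slogdet(Sc)
    if sign <= 0 or n - 1 < k - 1:
        return np.nan, np.nan, eps
    W = float(np.exp(logdet) / (tr / (k - 1)) ** (k - 1))
    d = k - 1
    f = -(n - 1 - (2 * d**2 + d + 2) / (6 * d)) * (logdet - d * np.log(tr / d))
    df_w = d * (d + 1) / 2 - 1
    p = float(sps.chi2.sf(f, df_w)) if df_w > 0 else 1.0
    return W, p, eps


def _f_result(
    ss_effect: float,
    df1: int,
    ss_error: float,
    df2: int,
    contrast_table: np.ndarray,
    mauchly_alpha: float,
    ss_scale: float,
) -> AnovaResult:
    W, p_w, eps = sphericity(contrast_table)
    violated = bool((not np.isfinite(p_w)) or p_w < mauchly_alpha)
    e = eps if np.isfinite(eps) and violated else 1.0
    if ss_effect < 1e-12 * max(ss_scale, 1e-300):
        # effect sum of squares is zero up to rounding in the data scale
        return AnovaResult(0.0, e * df1, e * df2, 1.0, eps, violated, W, p_w)
    F = (ss_effect / df1) / (ss_error / df2)
    p = float(sps.f.sf(F, e * df1, e * df2))
    return AnovaResult(float(F), e * df1, e * df2, p, eps, violated, W, p_w)


def rm_anova(table: pd.DataFrame | np.ndarray, mauchly_alpha: float = 0.05) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subject x condition table.

    F has uncorrected df (k-1, (k-1)(n-1)); if Mauchly's test rejects at
    ``mauchly_alpha`` both df are multiplied by the Greenhouse-Geisser
    epsilon before the p value is taken.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = y.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    grand = y.mean()
    cond = y.mean(axis=0)
    subj = y.mean(axis=1)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_err = np.sum((y - cond[None, :] - subj[:, None] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    return _f_result(
        ss_cond, k - 1, ss_err, (k - 1) * (n - 1), y, mauchly_alpha, ss_total
    )


def two_way_rm_anova(
    level_tables: tuple[pd.DataFrame | np.ndarray, pd.DataFrame | np.ndarray],
    factor_names: tuple[str, str] = ("experiment", "time"),
    mauchly_alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Two-way fully within-subject ANOVA with a 2-level first factor.

    ``level_tables`` holds one subject x condition table per level of the
    first factor (same subjects, same condition order).  Returns the two
    main effects and the interaction, each with its own sphericity
    handling: the 2-level factor is spherical by construction, the second
    factor's epsilon comes from the tables averaged over levels, and the
    interaction's from their difference.
    """
    a = np.asarray(level_tables[0], dtype=float)
    b = np.asarray(level_tables[1], dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two level tables must have identical shape")
    if isinstance(level_tables[0], pd.DataFrame) and isinstance(
        level_tables[1], pd.DataFrame
    ):
        if not level_tables[0].index.equals(level_tables[1].index):
            raise ValueError("subject index mismatch across factor levels")
    y = np.stack([a, b], axis=1)  # subjects x 2 x k
    n, na, nb = y.shape
    grand = y.mean()
    mA = y.mean(axis=(0, 2))
    mB = y.mean(axis=(0, 1))
    mS = y.mean(axis=(1, 2))
    mAB = y.mean(axis=0)
    mAS = y.mean(axis=2)
    mBS = y.mean(axis=1)

    ss_A = n * nb * np.sum((mA - grand) ** 2)
    ss_AS = nb * np.sum((mAS - mA[None, :] - mS[:, None] + grand) ** 2)
    ss_B = n * na * np.sum((mB - grand) ** 2)
    ss_BS = na * np.sum((mBS - mB[None, :] - mS[:, None] + grand) ** 2)
    ss_AB = n * np.sum(
        (mAB - mA[:, None] - mB[None, :] + grand) ** 2
    )
    resid = (
        y
        - mAB[None, :, :]
        - mAS[:, :, None]
        - mBS[:, None, :]
        + mA[None, :, None]
        + mB[None, None, :]
        + mS[:, None, None]
        - grand
    )
    ss_ABS = np.sum(resid**2)

    ss_total = np.sum((y - grand) ** 2)
    results = {
        factor_names[0]: _f_result(
            ss_A, na - 1, ss_AS, (na - 1) * (n - 1), mAS, mauchly_alpha, ss_total
        ),
        factor_names[1]: _f_result(
            ss_B,
            nb - 1,
            ss_BS,
            (nb - 1) * (n - 1),
            y.mean(axis=1),
            mauchly_alpha,
            ss_total,
        ),
        "interaction": _f_result(
            ss_AB,
            (na - 1) * (nb - 1),
            ss_ABS,
            (na - 1) * (nb - 1) * (n - 1),
            a - b,
            mauchly_alpha,
            ss_total,
        ),
    }
    return results


def paired_t_bonferroni(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    m: int | None = None,
    one_tailed_directions: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Paired t tests over condition pairs with Bonferroni correction.

    ``one_tailed_directions`` maps a pair to ``"greater"``/``"less"``
    (first column vs second); unplanned pairs get two-tailed tests.
    ``m`` defaults to the number of pairs tested.  Corrected p is
    ``min(1, m * p_raw)``.
    """
    directions = one_tailed_directions or {}
    unknown = set(directions) - set(map(tuple, pairs))
    if unknown:
        raise ValueError(f"directions supplied for unplanned pairs: {sorted(unknown)}")
    m = len(pairs) if m is None else m
    rows = []
    for pair in pairs:
        c1, c2 = pair
        alt = directions.get(tuple(pair), "two-sided")
        x, yv = table[c1].to_numpy(float), table[c2].to_numpy(float)
        if np.std(x - yv, ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, yv, alternative=alt)
        rows.append(
            {
                "pair": f"{c1} vs {c2}",
                "alternative": alt,
                "t": float(t),
                "df": len(x) - 1,
                "p_raw": float(p),
                "p_corrected": min(1.0, m * float(p)),
            }
        )
    return pd.DataFrame(rows)


def cousineau_sem(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Within-subject SEM per condition (Cousineau normalisation).

    Each cell is replaced by cell - subject mean + grand mean, removing
    between-subject offsets; the SEM is then computed per condition.
    Condition means are unchanged by the normalisation.
    """
    y = np.asarray(table, dtype=float)
    norm = y - y.mean(axis=1, keepdims=True) + y.mean()
    return norm.std(axis=0, ddof=1) / np.sqrt(y.shape[0])


def icc_absolute_single(ratings: pd.DataFrame | np.ndarray) -> ICCResult:
    """ICC(2,1) from the two-way random-effects mean squares.

    ``ratings`` is targets x raters, complete.  Absolute agreement is
    penalised by systematic rater offsets via the column mean square.
    """
    y = np.asarray(ratings, dtype=float)
    n, k = y.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 targets")
    if np.ptp(y) == 0:
        raise ValueError("constant ratings: ICC undefined")
    grand = y.mean()
    rows = y.mean(axis=1)
    cols = y.mean(axis=0)
    ms_rows = k * np.sum((rows - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((cols - grand) ** 2) / (k - 1)
    ms_err = np.sum((y - rows[:, None] - cols[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    icc = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    )
    return ICCResult(float(icc), float(ms_rows), float(ms_cols), float(ms_err), n, k)
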