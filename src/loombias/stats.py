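"""Factorial ANOVA and effect-size machinery for verbal speed estimates.

Implements the full analysis chain the experiments require: unit conversion
to m/s, the "speed of sound" participant-exclusion filter, per-condition
averaging of the two side-mirrored trials, fully-within repeated-measures
ANOVA (any number of crossed within factors), split-plot mixed ANOVA
(Distance/Direction between, Speed within), Greenhouse-Geisser sphericity
correction, partial eta-squared, Tukey HSD post hocs, paired and independent
t tests, and the pooled-SD form of Cohen's d.

Sums of squares are computed from marginal means by Moebius
(inclusion-exclusion) effect estimates; every within effect is tested
against its own effect-by-subject interaction, and the Greenhouse-Geisser
epsilon for an effect is Box's epsilon of the covariance of that effect's
orthonormal contrast scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import prod

import numpy as np
import pandas as pd
from scipy import stats as sps

MPH_PER_MPS = 2.2369362920544025  # 1 / 0.44704, exact (international mile)
MPS_PER_MPH = 0.44704
SPEED_OF_SOUND_MPH_THRESHOLD = 600.0

UNIT_FACTORS_TO_MPS = {"mph": MPS_PER_MPH, "kmh": 1.0 / 3.6, "mps": 1.0}


class DesignError(ValueError):
    """Raised when a response table does not match the declared design."""


# ---------------------------------------------------------------------------
# units, exclusion, averaging
# ---------------------------------------------------------------------------

def convert_to_mps(value, unit: str):
    """Convert a speed estimate to m/s.  ``unit`` is 'mph', 'kmh' or 'mps'."""
    try:
        factor = UNIT_FACTORS_TO_MPS[unit]
    except KeyError:
        raise ValueError(
            f"unknown unit {unit!r}; expected one of {sorted(UNIT_FACTORS_TO_MPS)}"
        ) from None
    return np.asarray(value, dtype=float) * factor if np.ndim(value) else float(value) * factor


def exclude_speed_of_sound(responses: pd.DataFrame,
                           threshold_mph: float = SPEED_OF_SOUND_MPH_THRESHOLD,
                           subject: str = "participant_id",
                           dv: str = "estimate_mps"):
    """Drop participants who answered with "speed of sound"-scale values.

    A participant is excluded iff *all* of their estimates exceed the
    threshold (600 mph by default, compared in mph-equivalent) — the rule
    used in both experiments.  Returns the surviving table and the list of
    excluded participant ids.
    """
    if responses.empty:
        return responses, []
    thresh_mps = threshold_mph * MPS_PER_MPH
    all_over = responses.groupby(subject)[dv].agg(lambda v: bool((v > thresh_mps).all()))
    excluded = sorted(all_over.index[all_over].tolist())
    kept = responses[~responses[subject].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def average_cells(responses: pd.DataFrame,
                  factors=("distance", "direction", "speed_mps"),
                  subject: str = "participant_id",
                  dv: str = "estimate_mps",
                  require_full: bool = False) -> pd.DataFrame:
    """Average the two side-mirrored trials per condition cell.

    Returns one row per participant per condition.  A participant with a
    single trial in a cell keeps that value (with a warning); factors the
    table does not vary are dropped from the grouping.  With
    ``require_full=True`` (a fully-within design) a participant missing a
    whole cell raises :class:`DesignError` naming participant and cell.
    """
    factors = [f for f in factors if f in responses.columns]
    group_cols = [subject, *factors]
    if require_full and len(factors):
        have = responses.groupby(group_cols, observed=True)[dv].count()
        full = pd.MultiIndex.from_product(
            [responses[c].unique() for c in group_cols], names=group_cols
        )
        missing = full.difference(have.index)
        if len(missing):
            who = dict(zip(group_cols, missing[0]))
            raise DesignError(
                f"participant {who[subject]!r} has no trials in cell "
                f"{ {k: v for k, v in who.items() if k != subject} }"
            )
    counts = responses.groupby(group_cols, observed=True)[dv].count()
    # a lone trial in a cell is fine when the design presents one trial per
    # cell (between-subject sides); warn only when a side is missing
    if counts.min() < counts.max():
        n_short = int((counts < counts.max()).sum())
        warnings.warn(
            f"{n_short} participant-cells have fewer trials than the rest; "
            "using the mean of what is present", stacklevel=2,
        )
    cells = (
        responses.groupby(group_cols, observed=True, as_index=False)[dv].mean()
    )
    return cells


# ---------------------------------------------------------------------------
# sums of squares from marginal means
# ---------------------------------------------------------------------------

def _effect_ss(A: np.ndarray, axes: tuple) -> float:
    """SS for the effect spanned by ``axes`` of a balanced data array.

    The effect estimate at each level combination is the Moebius sum of
    marginal means over all sub-subsets of ``axes``; the SS multiplies the
    squared estimates by the number of observations collapsed over.
    """
    other = tuple(sorted(set(range(A.ndim)) - set(axes)))
    tau = np.zeros_like(A, shape=[A.shape[a] if a in axes else 1 for a in range(A.ndim)])
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            collapse = tuple(sorted(set(range(A.ndim)) - set(sub)))
            m = A.mean(axis=collapse, keepdims=True)
            tau = tau + (-1) ** (len(axes) - len(sub)) * m
    mult = prod(A.shape[a] for a in other)
    return float(mult * (tau ** 2).sum())


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the contrast (mean-free) space."""
    if k < 2:
        return np.zeros((0, k))
    centering = np.eye(k) - 1.0 / k
    _, _, vt = np.linalg.svd(centering)
    return vt[: k - 1]


def gg_epsilon(covariance) -> float:
    """Greenhouse-Geisser (Box) epsilon from a within-level covariance.

    Double-centers the k x k covariance estimate and returns
    ``tr(S)^2 / ((k-1) tr(S^2))``, clipped to ``[1/(k-1), 1]``.  Equals 1
    under compound symmetry (sphericity) and reaches the lower bound for a
    maximally non-spherical rank-1 structure.
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"covariance must be square, got shape {S.shape}")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    P = np.eye(k) - 1.0 / k
    Sc = P @ S @ P
    denom = (k - 1) * float((Sc * Sc).sum())
    if denom <= 0:
        return 1.0
    eps = float(np.trace(Sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _contrast_epsilon(Y2: np.ndarray, level_shape, effect_axes) -> float:
    """Box epsilon for one within effect of a (n, cells) data matrix.

    ``level_shape`` gives the within-cell factor structure (in flattening
    order); the contrast matrix is the Kronecker product of orthonormal
    contrasts for factors in the effect and normalized means elsewhere.
    """
    C = np.ones((1, 1))
    for axis, k in enumerate(level_shape):
        block = _orthonormal_contrasts(k) if axis in effect_axes else \
            np.full((1, k), 1.0 / np.sqrt(k))
        C = np.kron(C, block)
    df = C.shape[0]
    if df < 2:
        return 1.0
    scores = Y2 @ C.T
    S = np.cov(scores, rowvar=False, ddof=1)
    denom = df * float((S * S).sum())
    if denom <= 0:
        return 1.0
    eps = float(np.trace(S)) ** 2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def _f_and_p(ss_eff, df_eff, ss_err, df_err):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if not np.isfinite(ms_err) or ms_err <= 0:
        # degenerate (e.g. all-equal data): report a null result
        return ms_eff, ms_err, 0.0, 1.0
    F = ms_eff / ms_err
    return ms_eff, ms_err, F, float(sps.f.sf(F, df_eff, df_err))


ANOVA_COLUMNS = [
    "effect", "ss", "df1", "df2", "ms", "ms_error", "F", "p",
    "eps_gg", "df1_gg", "df2_gg", "p_gg", "partial_eta_sq",
]


def _pivot_within(cells: pd.DataFrame, subject, within, dv):
    """Balanced (n, k1, ..., km) array of cell means plus level labels."""
    levels = [np.array(sorted(cells[f].unique(), key=str)) for f in within]
    wide = cells.pivot_table(index=subject, columns=list(within), values=dv,
                             aggfunc="mean", observed=True)
    full_cols = pd.MultiIndex.from_product(levels, names=list(within)) \
        if len(within) > 1 else pd.Index(levels[0], name=within[0])
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        bad = wide.stack(list(range(wide.columns.nlevels)), future_stack=True)
        bad = bad[bad.isna()]
        raise DesignError(
            f"within design is not fully crossed; first missing "
            f"participant-cell: {bad.index[0]}"
        )
    shape = (wide.shape[0], *[len(lv) for lv in levels])
    return wide.to_numpy().reshape(shape), levels, wide.index.to_numpy()


def rm_anova(cells: pd.DataFrame,
             within=("distance", "direction", "speed_mps"),
             subject: str = "participant_id",
             dv: str = "estimate_mps") -> pd.DataFrame:
    """Fully within-subjects factorial ANOVA on a participant x cell table.

    Every effect (main or interaction) is tested against its own
    effect-by-subject interaction.  Columns include both the uncorrected test
    and the Greenhouse-Geisser corrected df/p (identical for 1-df effects),
    plus ``partial_eta_sq = SS_effect / (SS_effect + SS_error)``.
    """
    within = [within] if isinstance(within, str) else list(within)
    A, levels, subjects = _pivot_within(cells, subject, within, dv)
    n = A.shape[0]
    if n < 2:
        raise DesignError("need at least 2 participants")
    Y2 = A.reshape(n, -1)
    level_shape = A.shape[1:]

    rows = []
    factor_axes = range(1, A.ndim)  # axis 0 is subject
    for r in range(1, len(within) + 1):
        for S in combinations(factor_axes, r):
            name = " x ".join(within[a - 1] for a in S)
            df_eff = prod(A.shape[a] - 1 for a in S)
            df_err = (n - 1) * df_eff
            ss_eff = _effect_ss(A, S)
            ss_err = _effect_ss(A, (0, *S))
            ms, ms_err, F, p = _f_and_p(ss_eff, df_eff, ss_err, df_err)
            eps = _contrast_epsilon(Y2, level_shape, tuple(a - 1 for a in S))
            df1_gg, df2_gg = eps * df_eff, eps * df_err
            p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if F > 0 else 1.0
            peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            rows.append([name, ss_eff, df_eff, df_err, ms, ms_err, F, p,
                         eps, df1_gg, df2_gg, p_gg, peta])
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def mixed_anova(cells: pd.DataFrame,
                between=("distance", "direction"),
                within: str = "speed_mps",
                subject: str = "participant_id",
                dv: str = "estimate_mps") -> pd.DataFrame:
    """Split-plot ANOVA: crossed between-subject factors, one within factor.

    Between effects are tested against subjects-within-groups; the within
    main effect and all mixed interactions against the within-by-subjects-
    within-groups error.  Greenhouse-Geisser epsilon comes from the pooled
    within-group covariance of the within levels.  Unequal group sizes are
    handled by unweighted (cell-means) analysis with the harmonic mean n,
    with a warning.
    """
    between = [between] if isinstance(between, str) else list(between)
    b_levels = [np.array(sorted(cells[f].unique(), key=str)) for f in between]
    w_levels = np.array(sorted(cells[within].unique(), key=str))
    k = len(w_levels)

    # group membership must be unique per subject
    memb = cells.groupby(subject, observed=True)[between].nunique()
    if (memb > 1).any().any():
        raise DesignError("each participant must sit in exactly one between cell")

    wide = cells.pivot_table(index=[subject, *between], columns=within,
                             values=dv, aggfunc="mean", observed=True)
    wide = wide.reindex(columns=w_levels)
    if wide.isna().any().any():
        raise DesignError("every participant needs all within levels")

    group_shape = tuple(len(lv) for lv in b_levels)
    n_groups = prod(group_shape)
    group_of = wide.index.droplevel(0)
    # per-group stacks of (n_g, k) matrices
    group_data = {}
    for key, sub in wide.groupby(level=list(range(1, wide.index.nlevels)), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        group_data[key] = sub.to_numpy()
    if len(group_data) != n_groups:
        raise DesignError("empty between cell(s) in the design")
    sizes = {key: v.shape[0] for key, v in group_data.items()}
    if min(sizes.values()) < 2:
        raise DesignError("need at least 2 participants per between cell")
    N = sum(sizes.values())
    balanced = len(set(sizes.values())) == 1
    n_h = len(sizes) / sum(1.0 / s for s in sizes.values())  # harmonic mean
    if not balanced:
        warnings.warn(
            "unbalanced between cells; using unweighted cell means with "
            f"harmonic mean n = {n_h:.2f}", stacklevel=2,
        )

    # cell-means array M[g1, g2, s] and subject-mean pieces
    M = np.zeros(group_shape + (k,))
    ss_subj_within = 0.0
    ss_err_within = 0.0
    for idx, key in enumerate(np.ndindex(*group_shape)):
        lab = tuple(b_levels[d][key[d]] for d in range(len(between)))
        Yg = group_data[lab]
        M[key] = Yg.mean(axis=0)
        subj_means = Yg.mean(axis=1)
        ss_subj_within += k * ((subj_means - subj_means.mean()) ** 2).sum()
        resid = Yg - subj_means[:, None] - M[key][None, :] + Yg.mean()
        ss_err_within += (resid ** 2).sum()
    df_subj_within = N - n_groups
    df_err_within = (N - n_groups) * (k - 1)

    # pooled within-group covariance for the GG correction
    pooled = np.zeros((k, k))
    for Yg in group_data.values():
        pooled += (Yg.shape[0] - 1) * np.cov(Yg, rowvar=False, ddof=1)
    pooled /= max(N - n_groups, 1)
    eps = gg_epsilon(pooled) if k > 1 else 1.0

    rows = []
    b_axes = range(len(between))
    # between effects: computed on the subject-mean cell array, scale k * n
    Mb = M.mean(axis=-1)  # (g1, g2)
    for r in range(1, len(between) + 1):
        for S in combinations(b_axes, r):
            name = " x ".join(between[a] for a in S)
            df_eff = prod(group_shape[a] - 1 for a in S)
            # _effect_ss on the unweighted cell-mean array already multiplies
            # by the collapsed cell count; only the k * n_h scale is added.
            ss_eff = k * n_h * _effect_ss(Mb, S)
            ms, ms_err, F, p = _f_and_p(ss_eff, df_eff, ss_subj_within, df_subj_within)
            peta = ss_eff / (ss_eff + ss_subj_within) if (ss_eff + ss_subj_within) > 0 else 0.0
            rows.append([name, ss_eff, df_eff, df_subj_within, ms, ms_err, F, p,
                         1.0, df_eff, df_subj_within, p, peta])
    # within main effect and mixed interactions on M, scale n_h
    w_axis = M.ndim - 1
    for r in range(0, len(between) + 1):
        for S in combinations(b_axes, r):
            axes = (*S, w_axis)
            name = " x ".join([*(between[a] for a in S), within])
            df_eff = (k - 1) * prod(group_shape[a] - 1 for a in S)
            ss_eff = n_h * _effect_ss(M, axes)
            ms, ms_err, F, p = _f_and_p(ss_eff, df_eff, ss_err_within, df_err_within)
            df1_gg, df2_gg = eps * df_eff, eps * df_err_within
            p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if F > 0 else 1.0
            peta = ss_eff / (ss_eff + ss_err_within) if (ss_eff + ss_err_within) > 0 else 0.0
            rows.append([name, ss_eff, df_eff, df_err_within, ms, ms_err, F, p,
                         eps, df1_gg, df2_gg, p_gg, peta])
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


# ---------------------------------------------------------------------------
# post hocs, t tests, effect sizes
# ---------------------------------------------------------------------------

def tukey_hsd(level_means, ms_error: float, df_error: float, n_per_level: int,
              labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD from level means and an ANOVA error term.

    ``q = |m_i - m_j| / sqrt(MS_error / n)``; p from the studentized range
    distribution with (k, df_error).
    """
    means = np.asarray(level_means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 levels")
    if n_per_level <= 1:
        raise ValueError("n_per_level must exceed 1")
    if labels is None:
        labels = [str(i) for i in range(k)]
    se = np.sqrt(ms_error / n_per_level)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if se > 0:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        else:
            q, p = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
        rows.append([labels[i], labels[j], diff, q, p, p < alpha])
    return pd.DataFrame(rows, columns=["level_a", "level_b", "diff", "q", "p",
                                       "significant"])


@dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference (Cohen's d, pooled-SD form)."""

    d: float
    pooled_sd: float
    mean1: float
    sd1: float
    mean2: float
    sd2: float


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> EffectSize:
    """Cohen's d with the pooled SD ``sqrt((sd1^2 + sd2^2) / 2)``."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = float(np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0))
    return EffectSize(d=float((mean1 - mean2) / pooled), pooled_sd=pooled,
                      mean1=mean1, sd1=sd1, mean2=mean2, sd2=sd2)


def paired_t(x, y):
    """Two-sided paired t test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must share a length of at least 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, n - 1, 1.0
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), n - 1, float(2 * sps.t.sf(abs(t), n - 1))


def independent_t(x, y, pooled: bool = True):
    """Two-sided independent-samples t test; returns (t, df, p).

    ``pooled=True`` (default) assumes equal variances; otherwise Welch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = np.sqrt(se2)
    if se == 0:
        return 0.0, df, 1.0
    t = (x.mean() - y.mean()) / se
    return float(t), float(df), float(2 * sps.t.sf(abs(t), df))


def partial_eta_sq_from_f(F: float, df1: float, df2: float) -> float:
    """Identity ``eta_p^2 = F df1 / (F df1 + df2)`` for cross-checking tables."""
    return F * df1 / (F * df1 + df2)
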