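"""Repeated-measures inference for condition-table outcomes.

Implements the classical univariate sums-of-squares decomposition for
balanced within-subject designs (one or two within factors, optionally one
between-subjects factor with equal group sizes), with:

* partial η² = SS_effect / (SS_effect + SS_error) per effect,
* Greenhouse–Geisser nonsphericity ε (applied to both dfs, policy-driven),
* BIC-approximation Bayes factors per effect (Wagenmakers/Masson style:
  BF10 = exp((BIC_null − BIC_alt)/2) with the effect's own error stratum),
* sequentially rejective multiple-comparison procedures (Bonferroni,
  Holm step-down, and the Shaffer logically-constrained step-down used as
  the "modified sequentially rejective Bonferroni" for pairwise families),
* paired classical and BIC-Bayesian t-tests,
* noncentral-F power for one-way repeated-measures designs
  (λ = f²·n·m/(1−ρ), df = (m−1)ε, (n−1)(m−1)ε — the G*Power within-subjects
  convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .exceptions import InsufficientDataError

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "rm_anova",
    "pairwise_correct",
    "paired_t",
    "bayes_t",
    "bf_from_bic",
    "classify_bf",
    "anova_bf_bic",
    "gg_epsilon",
    "rm_power",
    "required_n",
]


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta2: float
    gg_epsilon: float = 1.0
    gg_applied: bool = False
    bf10: float | None = None
    ss: float = np.nan
    ss_err: float = np.nan

    def __str__(self) -> str:  # report line, APA-ish
        gg = f", ε={self.gg_epsilon:.3f}" if self.gg_applied else ""
        bf = f", BF10={self.bf10:.3g}" if self.bf10 is not None else ""
        return (
            f"{self.effect}: F({self.df1:.4g}, {self.df2:.4g}) = {self.F:.3f}, "
            f"p = {self.p:.4g}, partial η² = {self.partial_eta2:.3f}{gg}{bf}"
        )


@dataclass
class PairwiseResult:
    label: str
    p: float
    threshold: float
    rejected: bool
    method: str


# ---------------------------------------------------------------------------
# Greenhouse–Geisser epsilon
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1) × k orthonormal rows spanning the space orthogonal to the mean."""
    return linalg.helmert(k, full=False)


def gg_epsilon(cell_matrix: np.ndarray, contrasts: np.ndarray, groups=None) -> float:
    """Greenhouse–Geisser ε for one within effect.

    ``cell_matrix`` is subjects × cells (cells collapsed to the effect's
    granularity); ``contrasts`` the orthonormal contrast rows defining the
    effect; ``groups`` optional between-group labels for pooling the
    covariance within groups. ε = tr(CΣC')² / (d · tr((CΣC')²)), clipped to
    [1/d, 1].
    """
    Y = np.asarray(cell_matrix, dtype=float)
    d = contrasts.shape[0]
    if groups is None:
        groups = np.zeros(Y.shape[0], dtype=int)
    groups = np.asarray(groups)
    pooled = np.zeros((Y.shape[1], Y.shape[1]))
    dof = 0
    for g in np.unique(groups):
        sub = Y[groups == g]
        if sub.shape[0] > 1:
            pooled += np.cov(sub, rowvar=False) * (sub.shape[0] - 1)
            dof += sub.shape[0] - 1
    if dof == 0:
        return 1.0
    sigma = pooled / dof
    M = contrasts @ sigma @ contrasts.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


# ---------------------------------------------------------------------------
# balanced RM / mixed ANOVA
# ---------------------------------------------------------------------------

def _pivot_complete(data, dv, within, subject, between):
    """Tidy frame → (subjects × cell) array, level lists, group labels."""
    df = data.copy()
    cols = [subject] + list(within) + ([between] if between else [])
    for c in cols + [dv]:
        if c not in df.columns:
            raise KeyError(f"column {c!r} missing from the table")
    # average duplicates within a cell (e.g. repeated measures not yet meaned)
    df = df.groupby(cols, observed=True, as_index=False)[dv].mean()
    wide = df.pivot_table(index=subject, columns=list(within), values=dv, observed=True)
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} participant(s) with incomplete cells dropped: "
            f"{list(incomplete)}"
        )
        wide = wide.drop(index=incomplete)
    if wide.shape[0] < 2:
        raise InsufficientDataError("need at least 2 complete participants")
    levels = (
        [list(wide.columns)]
        if len(within) == 1
        else [list(wide.columns.levels[i]) for i in range(len(within))]
    )
    if len(within) == 2:
        # enforce full factorial ordering
        a, b = levels
        wide = wide.reindex(columns=pd.MultiIndex.from_product([a, b]))
        if wide.isna().any().any():
            raise InsufficientDataError("within-cell grid is not complete")
    group_labels = None
    group_levels = None
    if between:
        gmap = df.groupby(subject, observed=True)[between].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else np.nan
        )
        group_labels = gmap.reindex(wide.index).to_numpy()
        if pd.isna(group_labels).any():
            raise InsufficientDataError("between-group label missing or inconsistent")
        group_levels = sorted(pd.unique(group_labels))
        counts = pd.Series(group_labels).value_counts()
        if counts.nunique() != 1:
            raise InsufficientDataError(
                "mixed designs require equal group sizes; got "
                + ", ".join(f"{k}: {v}" for k, v in counts.items())
            )
    return wide, levels, group_labels, group_levels


def _ss(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x**2))


def _within_strata(Y3, group_idx, n_groups):
    """Sums of squares for a subjects × a × b cell array (b may be 1).

    Returns dict: effect name → (ss, df, collapse axes) plus error strata.
    ``group_idx`` maps each subject to its group (all zeros when no between
    factor); equal group sizes assumed (checked upstream).
    """
    N, a, b = Y3.shape
    n = N // n_groups
    m = Y3.mean()
    m_g = np.stack([Y3[group_idx == g].mean(axis=(0, 1, 2)) for g in range(n_groups)])
    m_i = Y3.mean(axis=(0, 2))  # per A level
    m_j = Y3.mean(axis=(0, 1))  # per B level
    m_ij = Y3.mean(axis=0)
    m_s = Y3.mean(axis=(1, 2))  # per subject
    m_gi = np.stack([Y3[group_idx == g].mean(axis=(0, 2)) for g in range(n_groups)])
    m_gj = np.stack([Y3[group_idx == g].mean(axis=(0, 1)) for g in range(n_groups)])
    m_gij = np.stack([Y3[group_idx == g].mean(axis=0) for g in range(n_groups)])
    m_si = Y3.mean(axis=2)  # subject × A
    m_sj = Y3.mean(axis=1)  # subject × B

    out = {}
    # between stratum
    out["group"] = (a * b * n * _ss(m_g - m), n_groups - 1)
    out["subject(group)"] = (
        a * b * _ss(m_s - m_g[group_idx]),
        n_groups * (n - 1),
    )
    # A stratum
    out["A"] = (b * N * _ss(m_i - m), a - 1)
    out["A:group"] = (
        b * n * _ss(m_gi - m_g[:, None] - m_i[None, :] + m),
        (a - 1) * (n_groups - 1),
    )
    resid_A = (
        m_si
        - m_s[:, None]
        - m_gi[group_idx]
        + m_g[group_idx, None]
    )
    out["A:error"] = (b * _ss(resid_A), (a - 1) * n_groups * (n - 1))
    if b > 1:
        out["B"] = (a * N * _ss(m_j - m), b - 1)
        out["B:group"] = (
            a * n * _ss(m_gj - m_g[:, None] - m_j[None, :] + m),
            (b - 1) * (n_groups - 1),
        )
        resid_B = m_sj - m_s[:, None] - m_gj[group_idx] + m_g[group_idx, None]
        out["B:error"] = (a * _ss(resid_B), (b - 1) * n_groups * (n - 1))
        out["A:B"] = (
            N * _ss(m_ij - m_i[:, None] - m_j[None, :] + m),
            (a - 1) * (b - 1),
        )
        out["A:B:group"] = (
            n
            * _ss(
                m_gij
                - m_gi[:, :, None]
                - m_gj[:, None, :]
                + m_g[:, None, None]
                - (m_ij - m_i[:, None] - m_j[None, :] + m)[None]
            ),
            (a - 1) * (b - 1) * (n_groups - 1),
        )
        total = _ss(Y3 - m)
        accounted = sum(
            v[0]
            for k, v in out.items()
            if k != "A:B:error"
        )
        out["A:B:error"] = (
            max(total - accounted, 0.0),
            (a - 1) * (b - 1) * n_groups * (n - 1),
        )
    return out


def anova_bf_bic(ss_effect: float, ss_error: float, df_effect: float, n_obs: int) -> float:
    """BIC-approximation Bayes factor for one ANOVA effect.

    Compares the model with the effect against the one without it on the
    effect's own error stratum: BF10 = exp((BIC0 − BIC1)/2) with
    BICi = n·ln(SSEi/n) + ki·ln(n).
    """
    if ss_error <= 0:
        return math.inf if ss_effect > 0 else 1.0
    delta = n_obs * math.log((ss_effect + ss_error) / ss_error) - df_effect * math.log(n_obs)
    return float(math.exp(delta / 2.0))


def rm_anova(
    data: pd.DataFrame,
    dv: str = "gradient",
    within=("assigned_condition", "task"),
    subject: str = "participant_id",
    between: str | None = None,
    gg: str | bool = "auto",
    bayes: bool = True,
) -> list[AnovaResult]:
    """Balanced repeated-measures / mixed ANOVA on a tidy condition table.

    Parameters
    ----------
    data : tidy frame, one row per subject × cell (duplicates are averaged;
        subjects with missing cells are dropped with a warning).
    within : one or two within-subject factor columns.
    between : optional between-subjects factor (equal group sizes required).
    gg : Greenhouse–Geisser policy — ``False`` never, ``True`` always (for
        multi-df within effects), ``"auto"`` only when ε < 0.99.
    bayes : attach BIC-approximation Bayes factors.

    Returns one :class:`AnovaResult` per effect (within main effects and
    interaction, plus the between main effect and its interactions when a
    between factor is given).
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("one or two within factors supported")
    wide, levels, group_labels, group_levels = _pivot_complete(
        data, dv, within, subject, between
    )
    Y = wide.to_numpy(dtype=float)
    N = Y.shape[0]
    if len(within) == 1:
        a, b = len(levels[0]), 1
    else:
        a, b = len(levels[0]), len(levels[1])
    Y3 = Y.reshape(N, a, b)
    if between:
        gidx = np.array([group_levels.index(g) for g in group_labels])
        n_groups = len(group_levels)
    else:
        gidx = np.zeros(N, dtype=int)
        n_groups = 1
    strata = _within_strata(Y3, gidx, n_groups)

    # effect → (ss key, error key, display name, epsilon spec)
    plan = [("A", "A:error", within[0], ("A",))]
    if between:
        plan.insert(0, ("group", "subject(group)", between, None))
        plan.append(("A:group", "A:error", f"{within[0]}:{between}", ("A",)))
    if b > 1:
        plan.append(("B", "B:error", within[1], ("B",)))
        if between:
            plan.append(("B:group", "B:error", f"{within[1]}:{between}", ("B",)))
        plan.append(("A:B", "A:B:error", f"{within[0]}:{within[1]}", ("A", "B")))
        if between:
            plan.append(
                ("A:B:group", "A:B:error", f"{within[0]}:{within[1]}:{between}", ("A", "B"))
            )

    CA = _orthonormal_contrasts(a)
    CB = _orthonormal_contrasts(b) if b > 1 else None
    results: list[AnovaResult] = []
    for key, err_key, name, eps_spec in plan:
        ss_eff, df1 = strata[key]
        ss_err, df2 = strata[err_key]
        if df1 <= 0 or df2 <= 0:
            continue
        eps = 1.0
        if eps_spec is not None and df1 > 1:
            if eps_spec == ("A",):
                mat, C = Y3.mean(axis=2), CA
            elif eps_spec == ("B",):
                mat, C = Y3.mean(axis=1), CB
            else:
                mat, C = Y3.reshape(N, a * b), np.kron(CA, CB)
            eps = gg_epsilon(mat, C, groups=gidx if between else None)
        apply_gg = (
            eps_spec is not None
            and df1 > 1
            and (gg is True or (gg == "auto" and eps < 0.99))
        )
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err <= 0 or ss_err <= 1e-12 * (ss_eff + ss_err):
            warnings.warn(f"zero error variance for {name}; F reported as inf")
            F, p = math.inf, 0.0
        else:
            F = ms_eff / ms_err
            d1, d2 = (df1 * eps, df2 * eps) if apply_gg else (df1, df2)
            p = float(sps.f.sf(F, d1, d2))
        pe2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        bf = (
            anova_bf_bic(ss_eff, ss_err, df1, Y3.size)
            if bayes
            else None
        )
        results.append(
            AnovaResult(
                effect=name,
                F=float(F),
                df1=float(df1 * eps) if apply_gg else float(df1),
                df2=float(df2 * eps) if apply_gg else float(df2),
                p=p,
                partial_eta2=float(pe2),
                gg_epsilon=float(eps),
                gg_applied=bool(apply_gg),
                bf10=bf,
                ss=float(ss_eff),
                ss_err=float(ss_err),
            )
        )
    return results


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _shaffer_true_counts(m: int) -> tuple:
    """Achievable numbers of simultaneously true pairwise null hypotheses
    among m means: sums of C(g, 2) over the integer partitions of m."""

    def sums(remaining: int, max_part: int) -> set[int]:
        if remaining == 0:
            return {0}
        out = set()
        for g in range(min(remaining, max_part), 0, -1):
            for rest in sums(remaining - g, g):
                out.add(g * (g - 1) // 2 + rest)
        return out

    return tuple(sorted(sums(m, m)))


def pairwise_correct(
    raw_ps,
    method: str = "msrb_shaffer",
    alpha: float = 0.05,
    n_means: int | None = None,
    labels=None,
) -> list[PairwiseResult]:
    """Multiple-comparison decisions over a family of raw p-values.

    * ``bonferroni`` — single-step: reject iff p ≤ α/k.
    * ``msrb_holm`` — sequentially rejective step-down: sorted ascending,
      stage i uses α/(k−i+1); stop at the first failure.
    * ``msrb_shaffer`` — same step-down, but stage thresholds α/s_i where
      s_i is the largest number of hypotheses that can still be
      simultaneously true after i−1 rejections. For pairwise contrasts this
      needs ``n_means`` (s = 3, 1, 1 for all three pairs of 3 means).
    """
    ps = np.asarray(raw_ps, dtype=float)
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    k = ps.size
    if labels is None:
        labels = [f"c{i + 1}" for i in range(k)]
    if method == "bonferroni":
        thr = alpha / k
        return [
            PairwiseResult(lab, float(p), thr, bool(p <= thr), method)
            for lab, p in zip(labels, ps)
        ]
    if method not in ("msrb_holm", "msrb_shaffer"):
        raise ValueError(f"unknown method {method!r}")
    if method == "msrb_shaffer":
        if n_means is None or n_means * (n_means - 1) // 2 != k:
            raise ValueError(
                "msrb_shaffer needs n_means with C(n_means, 2) == number of p-values"
            )
        achievable = _shaffer_true_counts(n_means)
        s = [max(t for t in achievable if t <= k - i) or 1 for i in range(k)]
        s = [max(t, 1) for t in s]
    else:
        s = [k - i for i in range(k)]
    order = np.argsort(ps, kind="stable")
    rejected = np.zeros(k, dtype=bool)
    thresholds = np.empty(k)
    failed = False
    for stage, idx in enumerate(order):
        thr = alpha / s[stage]
        thresholds[idx] = thr
        if not failed and ps[idx] <= thr:
            rejected[idx] = True
        else:
            failed = True
    return [
        PairwiseResult(labels[i], float(ps[i]), float(thresholds[i]), bool(rejected[i]), method)
        for i in range(k)
    ]


# ---------------------------------------------------------------------------
# paired tests & Bayes factors
# ---------------------------------------------------------------------------

def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test: returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, d.mean()), n - 1, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def bayes_t(x, y) -> float:
    """BIC-approximation Bayes factor (BF10) for the paired difference.

    Null: differences have mean 0; alternative: free mean. With d the
    differences, BF10 = exp((BIC0 − BIC1)/2) = (Σd² / Σ(d−d̄)²)^(n/2) / √n.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sse1 = float(np.sum((d - d.mean()) ** 2))
    sse0 = float(np.sum(d**2))
    if sse1 == 0:
        return 1.0 / math.sqrt(n) if sse0 == 0 else math.inf
    return float((sse0 / sse1) ** (n / 2.0) / math.sqrt(n))


def bf_from_bic(bic_null: float, bic_alt: float) -> float:
    """BF10 = exp((BIC_null − BIC_alt)/2)."""
    return float(math.exp((bic_null - bic_alt) / 2.0))


def classify_bf(bf10: float) -> str:
    """Qualitative evidence band: < 1/3 supports the null, > 3 the
    alternative, otherwise anecdotal."""
    if bf10 < 1.0 / 3.0:
        return "moderate evidence for null"
    if bf10 > 3.0:
        return "moderate evidence for alternative"
    return "anecdotal"


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def rm_power(
    n: int,
    m: int,
    f: float,
    alpha: float = 0.05,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> float:
    """Power of the one-way repeated-measures F-test.

    Noncentrality λ = f²·n·m/(1−ρ); numerator df (m−1)·ε, denominator df
    (n−1)(m−1)·ε. With f = 0 the test is central and power equals α.
    """
    if not (0 < alpha < 1) or n < 2 or m < 2 or f < 0:
        raise ValueError("invalid power specification")
    if not (0 <= rho < 1) or not (1.0 / (m - 1) <= epsilon <= 1.0 + 1e-12):
        raise ValueError("rho in [0,1), epsilon in (1/(m-1), 1] required")
    df1 = (m - 1) * epsilon
    df2 = (n - 1) * (m - 1) * epsilon
    crit = sps.f.isf(alpha, df1, df2)
    lam = f**2 * n * m / (1.0 - rho)
    if lam == 0:
        return float(alpha)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_n(
    m: int,
    f: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_max: int = 10000,
) -> int:
    """Smallest n with rm_power ≥ target; raises if no finite n suffices."""
    if f <= 0:
        raise ValueError("no finite sample size reaches the target with f = 0")
    for n in range(2, n_max + 1):
        if rm_power(n, m, f, alpha, rho, epsilon) >= target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")
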