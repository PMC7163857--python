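"""Statistical layer for the study outcomes.

One-factor repeated-measures ANOVA over the meniscal states, Tukey HSD
multiple comparisons on the within-subject error term, an exact
Mann-Whitney U test for small pilot comparisons, and a sample-size
helper based on noncentral power functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "PairwiseTable",
    "rm_anova",
    "tukey_hsd",
    "mann_whitney_u",
    "required_sample_size",
]


@dataclass(frozen=True)
class RmAnovaResult:
    """One-factor repeated-measures ANOVA summary.

    ``df_treatment = k - 1`` and ``df_error = (k - 1)(n - 1)`` for ``n``
    subjects and ``k`` conditions; ``ms_error`` is the within-subject
    (subject x treatment interaction) mean square against which the
    treatment effect is tested.
    """

    F_stat: float
    df_treatment: int
    df_error: int
    ms_error: float
    p_value: float
    epsilon: float = 1.0  # Greenhouse-Geisser factor applied (1 = none)


@dataclass(frozen=True)
class PairwiseTable:
    """All-pairs p-value matrix (symmetric, unit diagonal)."""

    labels: tuple[str, ...]
    p: np.ndarray

    def p_for(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.p[i, j])


def _validate_matrix(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a subjects x conditions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells; complete data required")
    return x


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    # double-centred covariance
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(values: np.ndarray, sphericity_correction: bool = False) -> RmAnovaResult:
    """One-factor repeated-measures ANOVA (subjects x conditions matrix).

    The total sum of squares is partitioned into subjects, treatment and
    the subject x treatment residual; ``F = MS_treat / MS_error`` is
    referred to the F distribution with ``(k-1, (k-1)(n-1))`` degrees of
    freedom.  No sphericity correction is applied by default;
    ``sphericity_correction=True`` applies Greenhouse-Geisser epsilon to
    both degrees of freedom for the p-value.
    """
    x = _validate_matrix(values)
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_treat = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_treat
    df_t, df_e = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df_t
    ms_err = max(ss_err, 0.0) / df_e

    if ms_treat == 0.0:
        F, p = 0.0, 1.0
    elif ms_err == 0.0:
        F, p = np.inf, 0.0
    else:
        F = ms_treat / ms_err
        eps = _gg_epsilon(x) if sphericity_correction else 1.0
        p = float(sps.f.sf(F, eps * df_t, eps * df_e))
    eps = _gg_epsilon(x) if sphericity_correction else 1.0
    return RmAnovaResult(
        F_stat=float(F), df_treatment=df_t, df_error=df_e,
        ms_error=float(ms_err), p_value=float(p), epsilon=eps,
    )


def tukey_hsd(values: np.ndarray, anova: RmAnovaResult | None = None) -> PairwiseTable:
    """Tukey HSD over condition means, within-subject error term.

    For each pair ``q = |mean_i - mean_j| / sqrt(MS_error / n)`` with the
    repeated-measures ``MS_error`` and its ``(k-1)(n-1)`` degrees of
    freedom (comparisons are within-subject); p-values come from the
    studentized range distribution with ``k`` groups.
    """
    x = _validate_matrix(values)
    n, k = x.shape
    if anova is None:
        anova = rm_anova(x)
    means = x.mean(axis=0)
    p = np.ones((k, k))
    se = np.sqrt(anova.ms_error / n)
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if se == 0.0:
            pij = 1.0 if diff == 0.0 else 0.0
        else:
            pij = float(sps.studentized_range.sf(diff / se, k, anova.df_error))
        p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    labels = tuple(f"c{i}" for i in range(k))
    return PairwiseTable(labels=labels, p=p)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(a, b, exact_threshold: int = 20) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by complete enumeration of all C(n_a + n_b, n_a) group
    assignments of the pooled (mid-ranked) values when the combined
    sample size is at most ``exact_threshold``; the two-sided p is the
    permutation-null probability of the folded statistic
    ``max(U_a, n_a n_b - U_a)`` reaching its observed value, which
    accumulates both tails in one pass.  Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    if na + nb <= exact_threshold:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)  # midranks under ties
        u_obs = max(
            _u_statistic(ranks[:na], na),
            na * nb - _u_statistic(ranks[:na], na),
        )
        count = 0
        total = 0
        for idx in combinations(range(na + nb), na):
            u_a = _u_statistic(ranks[list(idx)], na)
            u = max(u_a, na * nb - u_a)
            total += 1
            if u >= u_obs - 1e-12:
                count += 1
        return count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def required_sample_size(
    delta: float,
    sd: float,
    power: float = 0.80,
    alpha: float = 0.05,
    design: str = "paired_t",
    k: int = 4,
    correlation: float = 0.5,
    n_max: int = 100_000,
) -> int:
    """Minimal sample size for a stated detectable difference.

    ``design="paired_t"``: two-sided paired t-test of a mean difference
    ``delta`` with difference SD ``sd``; power from the noncentral t
    distribution with ncp ``(delta/sd) sqrt(n)``.

    ``design="rm_anova"``: one-factor repeated-measures ANOVA with ``k``
    conditions in which two condition means differ by ``delta`` (others
    at the grand mean), outcome SD ``sd`` and within-subject correlation
    ``correlation``; power from the noncentral F distribution with ncp
    ``n sum((mu_i - mu_bar)^2) / (sd^2 (1 - correlation))``.

    The assumption set is an explicit argument because study reports
    rarely state it.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")

    def power_at(n: int) -> float:
        if design == "paired_t":
            df = n - 1
            if df < 1:
                return 0.0
            ncp = (delta / sd) * np.sqrt(n)
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
        if design == "rm_anova":
            df1, df2 = k - 1, (k - 1) * (n - 1)
            if df2 < 1:
                return 0.0
            mus = np.zeros(k)
            mus[0], mus[1] = delta / 2.0, -delta / 2.0
            ncp = n * np.sum((mus - mus.mean()) ** 2) / (sd**2 * (1 - correlation))
            fcrit = sps.f.ppf(1 - alpha, df1, df2)
            return float(sps.ncf.sf(fcrit, df1, df2, ncp))
        raise ValueError(f"unknown design {design!r}")

    for n in range(2, n_max + 1):
        if power_at(n) >= power:
            return n
    raise ValueError(f"power {power} unreachable with n <= {n_max}")
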