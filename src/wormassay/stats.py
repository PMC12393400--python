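"""Normality-gated group comparisons for per-worm assay outcomes.

The routing scheme mirrors common practice in behavioral genetics: every
group is screened with the Shapiro-Wilk test; if all groups look Gaussian
(p >= alpha for each), parametric tests are used (Student's t for two
groups, one-way ANOVA with Dunnett's test against the control for three or
more).  If any group fails, the nonparametric family is used instead
(Mann-Whitney for two groups, Kruskal-Wallis with Dunn's multiple-comparison
test against the control for three or more).  All tests are two-sided.

The two-sample Mann-Whitney test is exact (full enumeration of label
assignments, mid-ranks for ties) whenever the pooled sample has at most
``EXACT_ENUMERATION_LIMIT`` observations, and falls back to the tie-corrected
normal approximation with continuity correction above that.  A
Brown-Forsythe (Welch-type) ANOVA with Dunnett's T3 comparisons is available
as an optional unequal-variance parametric route.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupData",
    "Routing",
    "TestResult",
    "normality_gate",
    "compare_groups",
    "exact_mann_whitney",
    "significance_stars",
]

EXACT_ENUMERATION_LIMIT = 12
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class GroupData:
    """One labeled sample of per-animal measurements."""

    label: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Routing:
    decision: str  # "parametric" | "nonparametric"
    shapiro_p: dict
    alpha: float


@dataclass(frozen=True)
class PostHoc:
    label: str
    p_value: float
    stars: str


@dataclass(frozen=True)
class TestResult:
    routing: str
    method: str
    statistic: float
    p_value: float
    stars: str
    post_hoc: tuple = ()
    post_hoc_method: str = ""


def significance_stars(p: float) -> str:
    """Figure-legend annotation: ****, ***, **, * or NS at the conventional
    0.0001 / 0.001 / 0.01 / 0.05 thresholds."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "NS"


def normality_gate(groups: list[GroupData], alpha: float = 0.05) -> Routing:
    """Shapiro-Wilk screen: parametric only if every group passes at alpha.

    Groups need n >= 3; a zero-variance group is degenerate for the test and
    rejected with an explicit error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pvals = {}
    for g in groups:
        if g.n < 3:
            raise ValueError(f"group {g.label!r} has n={g.n} < 3; too small for normality testing")
        if np.ptp(g.values) == 0:
            raise ValueError(f"group {g.label!r} is constant-valued; normality test undefined")
        pvals[g.label] = float(sps.shapiro(g.values).pvalue)
    decision = "parametric" if all(p >= alpha for p in pvals.values()) else "nonparametric"
    return Routing(decision=decision, shapiro_p=pvals, alpha=alpha)


def exact_mann_whitney(x, y, enumeration_limit: int = EXACT_ENUMERATION_LIMIT):
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    Ties get mid-ranks.  For pooled n <= ``enumeration_limit`` the null
    distribution of U is built by enumerating every assignment of the pooled
    mid-ranks to the first sample; the two-sided p-value is the probability
    of a U at least as far from its null mean n1*n2/2 as observed.  Larger
    samples use the tie-corrected normal approximation with continuity
    correction.  Returns (U1, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= enumeration_limit:
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return u_obs, hits / total

    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u_obs, min(p, 1.0)


def _dunn_vs_control(groups: list[GroupData], control: GroupData) -> list[PostHoc]:
    """Dunn's rank-sum comparisons of each group against the control after a
    Kruskal-Wallis omnibus, with tie correction and Bonferroni adjustment
    across the comparisons."""
    pooled = np.concatenate([g.values for g in groups])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    mean_ranks = {}
    idx = 0
    for g in groups:
        mean_ranks[g.label] = ranks[idx : idx + g.n].mean()
        idx += g.n
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = ((counts**3 - counts).sum()) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_corr
    others = [g for g in groups if g.label != control.label]
    m = len(others)
    out = []
    for g in others:
        se = math.sqrt(base_var * (1.0 / g.n + 1.0 / control.n))
        z = (mean_ranks[g.label] - mean_ranks[control.label]) / se if se > 0 else 0.0
        p = min(2.0 * sps.norm.sf(abs(z)) * m, 1.0)
        out.append(PostHoc(label=g.label, p_value=p, stars=significance_stars(p)))
    return out


def _dunnett_t3(groups: list[GroupData], control: GroupData) -> list[PostHoc]:
    """Dunnett's T3 pairwise-vs-control comparisons (Welch t statistics on
    the studentized-maximum-modulus scale, approximated per comparison with
    a Sidak adjustment)."""
    others = [g for g in groups if g.label != control.label]
    m = len(others)
    out = []
    for g in others:
        res = sps.ttest_ind(g.values, control.values, equal_var=False)
        p = 1.0 - (1.0 - min(res.pvalue, 1.0)) ** m if m > 1 else res.pvalue
        p = min(float(p), 1.0)
        out.append(PostHoc(label=g.label, p_value=p, stars=significance_stars(p)))
    return out


def compare_groups(
    groups: list[GroupData],
    routing: Routing | str,
    equal_var: bool = True,
    post_hoc: bool = True,
) -> TestResult:
    """Routed two-sided group comparison.

    Two groups: Student's t (parametric) or Mann-Whitney (nonparametric).
    Three or more: one-way ANOVA with Dunnett's test against the designated
    control (parametric) or Kruskal-Wallis with Dunn's test (nonparametric).
    ``equal_var=False`` switches the parametric multi-group route to
    Brown-Forsythe (Welch) ANOVA with Dunnett's T3 comparisons;
    ``post_hoc=False`` reports the omnibus test only (no control needed).
    """
    decision = routing.decision if isinstance(routing, Routing) else routing
    if decision not in ("parametric", "nonparametric"):
        raise ValueError("routing must be 'parametric' or 'nonparametric'")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [g.values for g in groups]

    if len(groups) == 2:
        if decision == "parametric":
            res = sps.ttest_ind(*samples, equal_var=equal_var)
            method = "Student's t" if equal_var else "Welch's t"
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            stat, p = exact_mann_whitney(*samples)
            method = "Mann-Whitney U"
        return TestResult(
            routing=decision,
            method=method,
            statistic=stat,
            p_value=p,
            stars=significance_stars(p),
        )

    control = None
    if post_hoc:
        controls = [g for g in groups if g.is_control]
        if len(controls) != 1:
            raise ValueError(
                "exactly one control group must be designated for post-hoc comparisons"
            )
        control = controls[0]
        others = [g for g in groups if g.label != control.label]

    post: tuple = ()
    post_method = ""
    if decision == "parametric":
        if equal_var:
            omnibus = sps.f_oneway(*samples)
            method = "one-way ANOVA"
            if post_hoc:
                dunnett = sps.dunnett(
                    *[g.values for g in others], control=control.values, alternative="two-sided"
                )
                post = tuple(
                    PostHoc(label=g.label, p_value=float(p), stars=significance_stars(float(p)))
                    for g, p in zip(others, dunnett.pvalue)
                )
                post_method = "Dunnett vs control"
        else:
            omnibus = _welch_anova(samples)
            method = "Brown-Forsythe (Welch) ANOVA"
            if post_hoc:
                post = tuple(_dunnett_t3(groups, control))
                post_method = "Dunnett's T3 vs control"
    else:
        omnibus = sps.kruskal(*samples)
        method = "Kruskal-Wallis"
        if post_hoc:
            post = tuple(_dunn_vs_control(groups, control))
            post_method = "Dunn vs control (Bonferroni)"

    stat, p = float(omnibus.statistic), float(omnibus.pvalue)
    return TestResult(
        routing=decision,
        method=method,
        statistic=stat,
        p_value=p,
        stars=significance_stars(p),
        post_hoc=post,
        post_hoc_method=post_method,
    )


class _WelchResult:
    def __init__(self, statistic: float, pvalue: float):
        self.statistic = statistic
        self.pvalue = pvalue


def _welch_anova(samples: list[np.ndarray]) -> _WelchResult:
    """Welch's heteroscedastic one-way ANOVA."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], dtype=float)
    means = np.array([s.mean() for s in samples])
    variances = np.array([s.var(ddof=1) for s in samples])
    w = ns / variances
    w_sum = w.sum()
    grand = (w * means).sum() / w_sum
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w_sum) ** 2 / (ns - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(sps.f.sf(f, k - 1, df2))
    return _WelchResult(float(f), p)
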