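"""Group-level inference on effect slopes.

One-sample t-tests (one-sided toward the typical effect direction) with
Cohen's d, one-way ANOVA with partial eta-squared, default-prior (JZS) Bayes
factors for both, and the exact r x c Fisher test on prevalence tables.

The JZS t-test Bayes factor places a Cauchy(0, rscale) prior on the
standardised effect size delta; BF10 is the ratio of the marginal likelihood
of the observed t statistic under that prior (a noncentral-t mixture,
integrated numerically) to its likelihood under delta = 0.  One-sided
variants truncate the prior to the predicted half-line.  The ANOVA Bayes
factor integrates a g-prior on standardised group effects (inverse-gamma
mixing density on g), the default-prior formulation for fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# frequentist tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    n: int
    mean: float
    sd: float


def one_sample_t(values, mu: float = 0.0, alternative: str = "two_sided") -> TTestResult:
    """One-sample t-test with Cohen's d = (mean - mu) / SD.

    `alternative` is one of 'two_sided', 'less', 'greater' (tail of the
    alternative hypothesis).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    res = stats.ttest_1samp(values, popmean=mu, alternative=alt)
    mean = float(values.mean())
    return TTestResult(
        t=float(res.statistic), df=values.size - 1, p=float(res.pvalue),
        d=(mean - mu) / float(sd), n=values.size, mean=mean, sd=float(sd),
    )


def t_from_summary(mean: float, sd: float, n: int, mu: float = 0.0,
                   alternative: str = "two_sided") -> TTestResult:
    """One-sample t-test from summary statistics (mean, SD, n).

    Closed form: t = (mean - mu) / (sd / sqrt(n)), d = (mean - mu) / sd.
    Useful for re-deriving printed test statistics from reported descriptives.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = (mean - mu) / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "two_sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TTestResult(t=float(t), df=df, p=float(p), d=(mean - mu) / sd,
                       n=n, mean=mean, sd=sd)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_p2: float


def oneway_anova(values, group_labels) -> AnovaResult:
    """One-way fixed-effects ANOVA with partial eta-squared.

    eta_p^2 = SS_between / (SS_between + SS_within), which for a one-way
    design equals F*df_b / (F*df_b + df_w).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    grand = values.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = values.size - len(groups)
    if ss_w == 0:
        F = 0.0 if ss_b == 0 else np.inf
    else:
        F = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta = 0.0 if (ss_b + ss_w) == 0 else float(ss_b / (ss_b + ss_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p, eta_p2=eta)


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------

_SQRT2_2 = np.sqrt(2.0) / 2.0


def _check_quad(value: float, abserr: float, what: str) -> None:
    if not np.isfinite(value) or (value > 0 and abserr > 1e-6 * value + 1e-12):
        raise RuntimeError(
            f"{what}: numerical integration did not converge "
            f"(value={value}, abserr={abserr})"
        )


def jzs_ttest_bf(t: float, n: int, rscale: float = _SQRT2_2,
                 direction: str = "two_sided") -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a one-sample t statistic.

    BF10 = integral over delta of f_nct(t; n-1, delta*sqrt(n)) Cauchy(delta;
    0, rscale) d delta, divided by the central-t density at t.  `direction`
    'negative'/'positive' truncates the prior to delta < 0 / delta > 0
    (order-restricted one-sided BF); 'two_sided' uses the full prior.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    # substitute delta = rscale * tan(theta): Cauchy prior becomes uniform
    # on (-pi/2, pi/2), removing the heavy tail from the integrand
    def integrand(theta):
        delta = rscale * np.tan(theta)
        return stats.nct.pdf(t, nu, delta * sqrt_n)

    if direction == "two_sided":
        lo, hi, norm = -np.pi / 2, np.pi / 2, 1.0 / np.pi
    elif direction == "negative":
        lo, hi, norm = -np.pi / 2, 0.0, 2.0 / np.pi
    elif direction == "positive":
        lo, hi, norm = 0.0, np.pi / 2, 2.0 / np.pi
    else:
        raise ValueError(f"unknown direction {direction!r}")
    m1, abserr = integrate.quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-10,
                                limit=200)
    _check_quad(m1, abserr, "JZS t-test BF")
    m1 *= norm
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)


def _sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal basis (k x k-1) of the sum-to-zero subspace of R^k."""
    C = np.eye(k) - np.ones((k, k)) / k
    vals, vecs = np.linalg.eigh(C)
    return vecs[:, vals > 0.5]


def jzs_anova_bf(values, group_labels, rscale_fixed: float = 0.5) -> float:
    """Default-prior Bayes factor for a one-way ANOVA (fixed group effects).

    Model: y = mu + Z theta + eps with theta ~ N(0, g sigma^2 I) on the
    sum-to-zero projection of the group effects, Jeffreys prior on (mu,
    sigma^2), and g ~ InverseGamma(1/2, rscale^2/2).  BF10 is computed by
    1-D quadrature over g.  Location- and scale-invariant by construction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError("every group needs n >= 2")
    n = values.size
    X = (labels[:, None] == uniq[None, :]).astype(float)
    Z = X @ _sum_to_zero_basis(k)
    y = values - values.mean()          # harmless: model is shift-invariant

    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    Zt1 = Z.T @ np.ones(n)
    yty = y @ y
    sum_y = y.sum()
    R0 = yty - sum_y**2 / n
    p = k - 1

    def log_bf_g(g):
        B = np.linalg.inv(ZtZ + np.eye(p) / g)
        one_V_one = n - Zt1 @ B @ Zt1
        one_V_y = sum_y - Zt1 @ B @ Zty
        y_V_y = yty - Zty @ B @ Zty
        R1 = y_V_y - one_V_y**2 / one_V_one
        sign, logdet = np.linalg.slogdet(np.eye(p) + g * ZtZ)
        return (-0.5 * logdet - 0.5 * np.log(one_V_one / n)
                - 0.5 * (n - 1) * np.log(R1 / R0))

    prior = stats.invgamma(0.5, scale=rscale_fixed**2 / 2.0)

    def integrand(g):
        return np.exp(log_bf_g(g)) * prior.pdf(g)

    bf, abserr = integrate.quad(integrand, 0.0, np.inf, epsabs=1e-12,
                                epsrel=1e-8, limit=400)
    _check_quad(bf, abserr, "JZS ANOVA BF")
    return float(bf)


# ---------------------------------------------------------------------------
# exact r x c Fisher test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p: float
    method: str
    se: float | None = None
    n_tables: int | None = None


def _table_logprob_const(row_sums, col_sums):
    n = int(sum(row_sums))
    return (gammaln(np.asarray(row_sums) + 1).sum()
            + gammaln(np.asarray(col_sums) + 1).sum()
            - gammaln(n + 1))


def _enumerate_tables(row_sums, col_sums, lgamma_tab):
    """Yield -sum(log n_ij!) for every table with the given margins.

    Depth-first over rows; within a row, over cells, with margin pruning.
    The final row is fully determined by the column remainders.
    """
    r = len(row_sums)
    c = len(col_sums)
    col_rem = list(col_sums)
    # suffix sums of col_rem are maintained implicitly via recomputation per
    # cell; rows are short (c <= ~5) so this stays cheap
    out = []

    def rec_row(i, neg_logfact):
        if i == r - 1:
            out.append(neg_logfact - sum(lgamma_tab[x] for x in col_rem))
            return
        rem = row_sums[i]

        def rec_cell(j, rem, acc):
            if j == c - 1:
                if rem <= col_rem[j]:
                    col_rem[j] -= rem
                    rec_row(i + 1, acc - lgamma_tab[rem])
                    col_rem[j] += rem
                return
            tail = sum(col_rem[j + 1:])
            lo = max(0, rem - tail)
            hi = min(rem, col_rem[j])
            for x in range(lo, hi + 1):
                col_rem[j] -= x
                rec_cell(j + 1, rem - x, acc - lgamma_tab[x])
                col_rem[j] += x

        rec_cell(0, rem, neg_logfact)

    rec_row(0, 0.0)
    return np.asarray(out)


def fisher_exact_rxc(table, method: str = "enumerate", n_mc: int = 10**6,
                     seed=None, max_tables: int = 5_000_000) -> FisherResult:
    """Exact (or Monte Carlo) Fisher test for an r x c contingency table.

    The p-value sums multivariate-hypergeometric probabilities (margins
    fixed) of all tables at most as probable as the observed one; tables of
    equal probability (within 1e-12 relative) are included.  `enumerate`
    walks every feasible table; `montecarlo` samples tables conditional on
    the margins and reports p-hat with its binomial SE.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if obs.sum() == 0:
        raise ValueError("table has no observations")
    max_n = int(obs.sum())
    lgamma_tab = gammaln(np.arange(max_n + 2) + 1.0)
    obs_neg_logfact = -sum(lgamma_tab[x] for x in obs.ravel())
    tol = 1e-12 * abs(obs_neg_logfact) + 1e-12

    if method == "enumerate":
        neg_logfacts = _enumerate_tables(list(row_sums), list(col_sums), lgamma_tab)
        if neg_logfacts.size > max_tables:
            warnings.warn(
                f"{neg_logfacts.size} feasible tables exceed budget "
                f"{max_tables}; falling back to Monte Carlo", RuntimeWarning,
            )
            return fisher_exact_rxc(table, method="montecarlo", n_mc=n_mc, seed=seed)
        logp = neg_logfacts  # constant term cancels in the comparison & ratio
        keep = logp <= obs_neg_logfact + tol
        const = _table_logprob_const(row_sums, col_sums)
        probs = np.exp(const + logp)
        p = float(probs[keep].sum())
        return FisherResult(p=min(p, 1.0), method="enumerate",
                            n_tables=int(neg_logfacts.size))

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(col_sums), dtype=np.int8), col_sums)
        hits = 0
        done = 0
        chunk = 100_000
        r_edges = np.cumsum(row_sums)[:-1]
        while done < n_mc:
            m = min(chunk, n_mc - done)
            perm = rng.permuted(np.tile(labels, (m, 1)), axis=1)
            neg_lf = np.zeros(m)
            for seg in np.split(perm, r_edges, axis=1):
                for j in range(len(col_sums)):
                    cnt = (seg == j).sum(axis=1)
                    neg_lf -= lgamma_tab[cnt]
            hits += int((neg_lf <= obs_neg_logfact + tol).sum())
            done += m
        p = hits / n_mc
        se = float(np.sqrt(p * (1 - p) / n_mc))
        return FisherResult(p=float(p), method="montecarlo", se=se)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

_EFFECT_TAIL = {"nde": "less", "nse": "greater"}
_EFFECT_DIRECTION = {"nde": "negative", "nse": "positive"}


def table1_report(slopes: pd.DataFrame, classifications: pd.DataFrame,
                  rscale: float = _SQRT2_2) -> pd.DataFrame:
    """Per-group and overall summary of both effects.

    For each group and effect: mean slope, SD, n, one-sided t-test toward
    the typical direction, Cohen's d, one-sided JZS BF10, and the
    bootstrap-prevalence percentages.  Mirrors the layout of a standard
    effects-summary table.
    """
    rows = []
    group_frames = [("Overall", slopes)] + [
        (g, sub) for g, sub in slopes.groupby("group")
    ]
    for effect, col in (("nde", "nde_slope"), ("nse", "nse_slope")):
        cls = classifications[classifications["effect"] == effect]
        for gname, sub in group_frames:
            vals = sub[col].to_numpy(dtype=float)
            tt = one_sample_t(vals, alternative=_EFFECT_TAIL[effect])
            bf = jzs_ttest_bf(tt.t, tt.n, rscale=rscale,
                              direction=_EFFECT_DIRECTION[effect])
            csub = cls if gname == "Overall" else cls[cls["group"] == gname]
            n_cls = len(csub)
            pct = {
                lab: (100.0 * (csub["label"] == lab).sum() / n_cls if n_cls else np.nan)
                for lab in ("reliable_typical", "reliable_reverse", "not_reliable")
            }
            rows.append({
                "effect": effect, "group": gname, "n": tt.n,
                "mean": tt.mean, "sd": tt.sd, "t": tt.t, "df": tt.df,
                "p_one_sided": tt.p, "d": tt.d, "bf10": bf,
                "reliable_pct": pct["reliable_typical"],
                "reliable_reverse_pct": pct["reliable_reverse"],
                "not_reliable_pct": pct["not_reliable"],
            })
    return pd.DataFrame(rows)
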