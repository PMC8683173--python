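"""Differential-expression screening with an empirical-Bayes moderated t-test.

Per-probe residual variances in small two-group array designs are noisy;
shrinking them toward a common prior stabilises the t-statistic. The prior
is modelled as a scaled inverse chi-square with ``d0`` degrees of freedom and
scale ``s0_sq``; both are estimated from the marginal distribution of the
observed log sample variances by the standard method of moments on the
log-F scale (digamma/trigamma moment matching, with the trigamma equation
inverted by Newton iteration). The moderated statistic for probe g is

    t_g = log2fc_g / (s_post_g * sqrt(1/n1 + 1/n2)),
    s_post_g^2 = (d0 * s0_sq + d * s_g^2) / (d0 + d),

referred to a t distribution on ``d + d0`` degrees of freedom (d = residual
df). A probe is called differentially expressed when |linear fold change|
>= 1.5 and two-sided P < 0.05; Benjamini-Hochberg FDR is reported alongside
but not used by this legacy-style filter.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError

# finite df used for the t reference distribution when d0 is infinite;
# t on 1e6 df is numerically indistinguishable from normal
_INF_DF_CAP = 1.0e6

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05


class ModerationPrior(NamedTuple):
    """Variance prior: d0 = prior df (may be ``inf``), s0_sq = prior variance."""

    d0: float
    s0_sq: float


class DesignError(ValidationError):
    """Raised when the sample design cannot support the requested test."""


def _group_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    case = matrix.values[matrix.case_ids].to_numpy(float)
    control = matrix.values[matrix.control_ids].to_numpy(float)
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise DesignError("each group needs at least 2 samples")
    return case, control


def log2_fold_change(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe log2 fold change (case mean - control mean) and signed linear FC.

    The linear fold change carries the direction in its sign and the magnitude
    as ``2**|log2fc|``, the convention used for array DE tables (an unchanged
    probe has fc = +1, a halved one fc = -2).
    """
    case, control = _group_arrays(matrix)
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    fc = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))
    return pd.DataFrame(
        {"log2fc": log2fc, "fc": fc}, index=matrix.probe_ids.copy()
    )


def pooled_variance(matrix: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Per-probe pooled (equal-variance) sample variance and its residual df."""
    case, control = _group_arrays(matrix)
    n1, n2 = case.shape[1], control.shape[1]
    df = n1 + n2 - 2
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    return ss / df, df


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 64) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < tol:
            break
    return x


def fit_moderation_prior(sample_variances, residual_df: int) -> ModerationPrior:
    """Estimate (d0, s0_sq) from per-probe sample variances.

    Moment-matches the log sample variances to a scaled F distribution:
    with z_g = log(s_g^2) and e_g = z_g - digamma(d/2) + log(d/2), the excess
    of var(e) over trigamma(d/2) estimates trigamma(d0/2); non-positive
    excess means no detectable between-probe variance heterogeneity, reported
    as d0 = inf with s0_sq the (bias-corrected) geometric mean variance.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if (s2 > 0).sum() == 0:
        raise ValidationError("all sample variances are zero; degenerate data")
    s2 = s2[s2 > 0]
    if s2.size < 30:
        raise ValidationError(
            f"need >= 30 probes with positive variance to fit the prior, got {s2.size}"
        )
    d = float(residual_df)
    e = np.log(s2) - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    matrix: ExpressionMatrix,
    prior: ModerationPrior | None = None,
    *,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Moderated two-sample t-test for every probe.

    Returns a DataFrame indexed by probe id with columns biotype, log2fc, fc,
    t, df_total, p_value, fdr (Benjamini-Hochberg over all probes) and is_de
    (|fc| >= fc_threshold and p < p_threshold, the raw-P legacy filter).
    Rows keep the matrix's probe order; BH ties are resolved deterministically
    by that order.
    """
    if prior is None:
        s2, d = pooled_variance(matrix)
        prior = fit_moderation_prior(s2, d)
    else:
        s2, d = pooled_variance(matrix)
    d0, s0_sq = prior
    if d0 < 0 or s0_sq <= 0:
        raise ValidationError("prior requires d0 >= 0 and s0_sq > 0")

    fcs = log2_fold_change(matrix)
    n1, n2 = len(matrix.case_ids), len(matrix.control_ids)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = d + _INF_DF_CAP
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    if np.any(s2_post <= 0):
        raise ValidationError("zero posterior variance; cannot form t statistic")
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = fcs["log2fc"].to_numpy() / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    is_de = (np.abs(fcs["fc"].to_numpy()) >= fc_threshold) & (p < p_threshold)
    out = pd.DataFrame(
        {
            "biotype": matrix.biotype.values,
            "log2fc": fcs["log2fc"].to_numpy(),
            "fc": fcs["fc"].to_numpy(),
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "fdr": fdr,
            "is_de": is_de,
        },
        index=matrix.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    return out


def welch_t_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe Welch (unequal-variance) t-test, two-sided."""
    case, control = _group_arrays(matrix)
    res = stats.ttest_ind(case, control, axis=1, equal_var=False)
    out = pd.DataFrame(
        {"t": res.statistic, "df": res.df, "p_value": res.pvalue},
        index=matrix.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    return out


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact by enumeration of all label arrangements when the combined sample
    size is <= 12 (ties handled by the enumeration itself); otherwise the
    normal approximation with tie correction and continuity correction.
    Returns (U of the first sample, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise DesignError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValidationError("all pooled values identical; U test undefined")
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= 12:
        # exact two-sided P: fraction of label arrangements at least as
        # extreme (in |U - mean|) as observed, enumerated over C(n1+n2, n1)
        mu = n1 * n2 / 2.0
        obs = abs(u1 - mu)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = float(ranks[mask].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u - mu) >= obs - 1e-9:
                count += 1
        p = count / total
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma_sq = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma_sq <= 0:
            raise ValidationError("degenerate tie structure; U test undefined")
        z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma_sq)
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u1, min(p, 1.0)


def paired_t(before, after) -> tuple[float, float]:
    """Paired two-sided t-test on matched observations."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise DesignError("paired arrays must have equal length")
    if before.size < 2:
        raise DesignError("need at least 2 pairs")
    diff = after - before
    if np.allclose(diff.var(ddof=1), 0.0):
        raise ValidationError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(after, before)
    return float(res.statistic), float(res.pvalue)
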