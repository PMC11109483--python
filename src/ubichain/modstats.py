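"""Empirical-Bayes moderated t and F statistics, from first principles.

The model is the standard hierarchical variance model for high-dimensional
feature-wise testing.  For protein g, the pooled within-group sample variance
follows

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi^2_{d_g} / d_g
    1 / sigma_g^2      ~  (1 / (d0 * s0^2)) * chi^2_{d0}        (scaled inverse chi-square prior)

so that marginally s_g^2 / s0^2 ~ F(d_g, d0).  The posterior mean of
sigma_g^2 is the moderated variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

a shrinkage of each protein's variance toward the common prior s0^2, and the
moderated t statistic

    t~ = (mu_A - mu_B) / (s~_g * sqrt(1/n_A + 1/n_B))

follows a t distribution on d_g + d0 degrees of freedom under the null.  The
extra d0 degrees of freedom are what make the test usable at n = 4 per group.
The moderated one-way F replaces the residual mean square of classical ANOVA
by s~_g^2 and gains the same extra denominator df.

(d0, s0^2) are estimated by moment matching on log sample variances: under
the scaled-F model, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has

    E[e_g]   = log s0^2 + digamma(d0/2) - log(d0/2)
    Var[e_g] = trigamma(d_g/2) + trigamma(d0/2)

so the empirical excess of Var(e) over the mean of trigamma(d_g/2) identifies
trigamma(d0/2), inverted by monotone Newton iteration.  A non-positive excess
means no detectable variance heterogeneity and the prior degenerates to
d0 = infinity with s~^2 = s0^2 for every protein.

``d0 = 0`` is admitted as the no-moderation limit: the statistics then
reduce exactly to the classical pooled two-sample t and one-way ANOVA F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import IntensityMatrix, SampleDesign

#: effective df used when the prior is degenerate (d0 = infinity)
_INF_DF_CAP = 1e6


@dataclass
class GroupFit:
    """Per-protein one-way layout fit: group means and pooled residual variance."""

    protein_ids: list[str]
    group_names: list[str]
    means: np.ndarray  # proteins x groups, log2
    s2: np.ndarray  # pooled within-group variance per protein
    df: int  # residual df, N - K (shared: complete matrix)
    n: dict[str, int]  # samples per group

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.protein_ids, columns=self.group_names)


@dataclass
class VariancePrior:
    """Scaled inverse chi-square prior (d0, s0^2) for residual variances."""

    d0: float  # prior df; 0 disables moderation, inf collapses to s0^2
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df d0 must be nonnegative")
        if not self.s0_sq > 0 and self.d0 > 0:
            raise ValueError("prior variance s0_sq must be positive")

    def moderate(self, s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
        """Posterior (moderated) variances and total degrees of freedom."""
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0_sq), _INF_DF_CAP
        if self.d0 == 0:
            return np.asarray(s2, dtype=float), float(df)
        s2_mod = (self.d0 * self.s0_sq + df * np.asarray(s2, dtype=float)) / (self.d0 + df)
        return s2_mod, float(df + self.d0)


@dataclass
class ContrastResult:
    """Per-protein statistics for one comparison.

    ``table`` is indexed by protein_id with columns logFC, stat, df, p, adj_p
    (df holds "df1/df2" for F contrasts).
    """

    label: str
    table: pd.DataFrame


def fit_groups(
    matrix: IntensityMatrix, design: SampleDesign, groups: list[str] | None = None
) -> GroupFit:
    """Group means and pooled within-group variance on a complete log2 matrix."""
    if matrix.missing.any():
        raise ValueError("fit_groups expects a complete (imputed) matrix")
    if matrix.scale != "log2":
        raise ValueError("fit_groups expects a log2 matrix")
    if groups is None:
        groups = design.baits()
    means = np.empty((matrix.n_proteins, len(groups)))
    ss = np.zeros(matrix.n_proteins)
    n_total = 0
    n = {}
    for k, g in enumerate(groups):
        samples = [s for s in design.samples_for(g) if s in set(matrix.sample_ids)]
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has {len(samples)} sample(s); need >= 2")
        idx = matrix.sample_index(samples)
        vals = matrix.values[:, idx]
        mu = vals.mean(axis=1)
        means[:, k] = mu
        ss += ((vals - mu[:, None]) ** 2).sum(axis=1)
        n[g] = len(samples)
        n_total += len(samples)
    df = n_total - len(groups)
    return GroupFit(list(matrix.protein_ids), list(groups), means, ss / df, df, n)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) / y < 1e-10:
            break
    return y


def estimate_variance_prior(s2, df) -> VariancePrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    ``df`` may be a scalar (shared residual df) or per-protein vector.
    Variances that are zero (constant rows) or have df < 1 are excluded from
    estimation; with fewer than 10 usable variances the prior falls back to
    d0 = infinity with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    use = (s2 > 0) & (df_arr >= 1) & np.isfinite(s2)
    if use.sum() < 10:
        warnings.warn(
            f"only {int(use.sum())} usable variances; falling back to d0 = inf"
        )
        s0 = float(np.exp(np.mean(np.log(s2[use])))) if use.any() else 1.0
        return VariancePrior(d0=math.inf, s0_sq=s0)
    z = np.log(s2[use])
    half_d = df_arr[use] / 2.0
    e = z - special.digamma(half_d) + np.log(half_d)
    e_mean = float(np.mean(e))
    excess = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, half_d)))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    fit: GroupFit, prior: VariancePrior, group_a: str, group_b: str
) -> ContrastResult:
    """Two-sample moderated t of group_a versus group_b (logFC = mu_a - mu_b)."""
    if group_a == group_b:
        raise ValueError("the two groups of a contrast must differ")
    for g in (group_a, group_b):
        if g not in fit.group_names:
            raise KeyError(f"group {g!r} not in fit")
    ia, ib = fit.group_names.index(group_a), fit.group_names.index(group_b)
    logfc = fit.means[:, ia] - fit.means[:, ib]
    s2_mod, df_total = prior.moderate(fit.s2, fit.df)
    se = np.sqrt(s2_mod * (1.0 / fit.n[group_a] + 1.0 / fit.n[group_b]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(logfc == 0, 1.0, p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "stat": t,
            "df": df_total,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=pd.Index(fit.protein_ids, name="protein_id"),
    )
    return ContrastResult(label=f"{group_a}_vs_{group_b}", table=table)


def moderated_F(
    fit: GroupFit, prior: VariancePrior, groups: list[str] | None = None
) -> ContrastResult:
    """Moderated one-way F across ``groups`` (default: all groups in the fit)."""
    if groups is None:
        groups = list(fit.group_names)
    if len(groups) < 2:
        raise ValueError("the F test needs at least 2 groups")
    idx = [fit.group_names.index(g) for g in groups]
    means = fit.means[:, idx]
    ns = np.array([fit.n[g] for g in groups], dtype=float)
    grand = (means * ns[None, :]).sum(axis=1) / ns.sum()
    ms_between = ((ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)) / (
        len(groups) - 1
    )
    s2_mod, df2 = prior.moderate(fit.s2, fit.df)
    df1 = len(groups) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(s2_mod > 0, ms_between / s2_mod, 0.0)
    p = stats.f.sf(f, df1, df2)
    p = np.where(ms_between == 0, 1.0, p)
    table = pd.DataFrame(
        {
            "logFC": np.sqrt(ms_between),  # effect-size summary for the F layout
            "stat": f,
            "df": f"{df1}/{df2:g}",
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=pd.Index(fit.protein_ids, name="protein_id"),
    )
    return ContrastResult(label="F_" + "_".join(groups), table=table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with running-minimum enforcement."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
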