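"""Blocked ANOVA with sequential sums of squares, Tukey HSD, Welch's t.

The comparison layer behind every claim in the analysis: resistance (RBG),
relative fitness and mutation counts are each analysed with an ANOVA whose
blocking factors (ancestral genotype, phage pair, RBG endpoint) are fitted
before the treatment term, followed by all-pairs Tukey HSD on the treatment
factor.  Single- vs multi-mutation fitness uses Welch's unequal-variance
t-test with Satterthwaite degrees of freedom.

Sums of squares are sequential (type I) in the declared term order, computed
by orthogonal projection with a rank-revealing QR per term, so aliased
terms are detected and reported rather than silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats as sps


class AliasedTermError(ValueError):
    """A model term adds no rank beyond the terms fitted before it."""

    def __init__(self, terms: list[str]):
        self.terms = terms
        super().__init__(f"aliased term(s), fully confounded with earlier terms: {terms}")


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    df: int
    sum_sq: float
    mean_sq: float
    F: float
    p: float


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    residual_df: int
    residual_ss: float
    nobs: int
    total_ss: float
    term_order: list[str] = field(default_factory=list)

    @property
    def residual_mean_sq(self) -> float:
        return self.residual_ss / self.residual_df if self.residual_df > 0 else np.nan

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in ANOVA ({[t.name for t in self.terms]})")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t.name,
                "df": t.df,
                "sum_sq": t.sum_sq,
                "mean_sq": t.mean_sq,
                "F": t.F,
                "p": t.p,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual",
                "df": self.residual_df,
                "sum_sq": self.residual_ss,
                "mean_sq": self.residual_mean_sq,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _term_matrix(data: pd.DataFrame, term: str) -> np.ndarray:
    """Full-dummy indicator matrix for a factor or `a:b` interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in data.columns:
            raise KeyError(f"factor {p!r} not found in data")
    labels = data[parts[0]].astype(str)
    for p in parts[1:]:
        labels = labels + "\x1f" + data[p].astype(str)
    return pd.get_dummies(labels).to_numpy(float)


def blocked_anova(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
) -> AnovaResult:
    """Sequential (type I) fixed-effects ANOVA in the declared term order.

    Every term is treated as categorical; an interaction is written
    ``"a:b"``.  Blocks should be listed before the treatment term so the
    treatment is assessed after block adjustment.  F for each term uses the
    residual mean square of the full model.
    """
    if response not in data.columns:
        raise KeyError(f"response {response!r} not found in data")
    if not terms:
        raise ValueError("at least one model term is required")
    y = data[response].to_numpy(float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")

    # orthonormal basis of the fitted column space, starting with intercept
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    total_ss = float(((y - y.mean()) ** 2).sum())

    raw: list[tuple[str, int, float]] = []
    for term in terms:
        C = _term_matrix(data, term)
        # residualize against everything fitted so far (twice, for stability)
        R = C - Q @ (Q.T @ C)
        R = R - Q @ (Q.T @ R)
        q, r, _ = scipy.linalg.qr(R, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = max(R.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        rank = int((diag > max(tol, 1e-12)).sum())
        if rank == 0:
            raise AliasedTermError([term])
        Qt = q[:, :rank]
        proj = Qt.T @ y
        raw.append((term, rank, float(proj @ proj)))
        Q = np.hstack([Q, Qt])

    model_df = Q.shape[1]
    residual_df = n - model_df
    if residual_df < 1:
        raise ValueError(
            f"fewer observations ({n}) than model parameters ({model_df}) + 1"
        )
    fit = Q @ (Q.T @ y)
    residual_ss = float(((y - fit) ** 2).sum())
    mse = residual_ss / residual_df

    out_terms = []
    for name, df, ss in raw:
        ms = ss / df
        if total_ss <= 1e-300:  # constant response: define F = 0
            F, p = 0.0, 1.0
        elif mse <= 0:
            F, p = np.inf, 0.0
        else:
            F = ms / mse
            p = float(sps.f.sf(F, df, residual_df))
        out_terms.append(AnovaTerm(name, df, ss, ms, float(F), float(p)))
    return AnovaResult(
        terms=out_terms,
        residual_df=residual_df,
        residual_ss=residual_ss,
        nobs=n,
        total_ss=total_ss,
        term_order=list(terms),
    )


@dataclass(frozen=True)
class TukeyComparison:
    level_a: str
    level_b: str
    diff: float  # mean(level_b) - mean(level_a)
    se: float  # SE of the difference, from the residual mean square
    q: float  # studentized-range statistic
    p_adj: float


def tukey_hsd(
    anova: AnovaResult,
    factor: str,
    data: pd.DataFrame,
    response: str,
) -> list[TukeyComparison]:
    """All-pairs Tukey HSD on one fitted factor.

    Mean differences are raw level means; the SE uses the ANOVA residual
    mean square with the Tukey-Kramer (harmonic-mean cell size) correction
    for unbalanced levels; adjusted p-values come from the studentized-range
    distribution with (k levels, residual df).
    """
    if factor not in anova.term_order:
        raise KeyError(f"factor {factor!r} was not fitted in the ANOVA")
    if anova.residual_df < 1:
        raise ValueError("Tukey HSD needs at least 1 residual df")
    groups = data.groupby(data[factor].astype(str))[response]
    means = groups.mean()
    ns = groups.size()
    if (ns == 0).any():
        raise ValueError("every factor level needs at least one observation")
    levels = sorted(means.index)
    k = len(levels)
    mse = anova.residual_mean_sq
    out = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            diff = float(means[b] - means[a])
            se = float(np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b])))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = np.sqrt(2.0) * abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, anova.residual_df)) if np.isfinite(q) else 0.0
            p = float(min(max(p, 0.0), 1.0))
            out.append(TukeyComparison(a, b, diff, se, float(q), p))
    return out


def tukey_frame(comparisons: Sequence[TukeyComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level_a": c.level_a,
                "level_b": c.level_b,
                "diff": c.diff,
                "se": c.se,
                "q": c.q,
                "p_adj": c.p_adj,
            }
            for c in comparisons
        ]
    )


@dataclass(frozen=True)
class WelchTResult:
    t: float
    df: float  # Welch-Satterthwaite, real-valued
    p: float
    undefined: bool = False


def welch_t(a, b) -> WelchTResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (mean_a − mean_b) / sqrt(s²_a/n_a + s²_b/n_b), with Satterthwaite
    degrees of freedom.  Two samples with zero variance give an undefined
    marker rather than an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        return WelchTResult(np.nan, np.nan, np.nan, undefined=True)
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchTResult(float(t), float(df), p)
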