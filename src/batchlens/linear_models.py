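"""Gene-wise linear models with empirical-Bayes variance moderation.

Every probe is fitted by ordinary least squares against a shared design
matrix (batch indicators, an optional case/control class indicator and
optional blocking terms, all treatment-coded).  The per-probe residual
variances s2_g are then shrunk toward a common prior by the standard
scaled-inverse-chi-square hierarchy: the prior (d0, s0^2) is estimated by
method-of-moments on log s2_g using digamma/trigamma matching, and the
posterior variance

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

replaces s2_g in the t (or F) statistic, which gains d0 extra degrees of
freedom.  With d0 = 0 the ordinary t is recovered exactly; with d0 = inf
all probes share s0^2.

Differentially expressed genes (DEGs) are counted at a configurable
adjusted-p threshold; the default is Benjamini-Hochberg at 0.05 with no
fold-change filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "DesignMatrix",
    "GenewiseFit",
    "EBayesParams",
    "ModeratedTestResult",
    "build_design",
    "fit_genewise",
    "estimate_ebayes",
    "moderated_t",
    "moderated_f",
    "adjust_pvalues",
    "count_degs",
]


class ConfoundingError(ValueError):
    """Class indicator is aliased with the blocked batch structure."""


@dataclass
class DesignMatrix:
    """Samples x terms model matrix with treatment (reference-level) coding."""

    matrix: np.ndarray
    term_names: list
    sample_ids: list
    dropped_terms: list = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]

    def term_index(self, name: str) -> int:
        return self.term_names.index(name)


def _indicator_columns(labels, prefix, reference=None):
    levels = sorted(set(labels))
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    cols, names = [], []
    for lv in levels:
        if lv == reference:
            continue
        cols.append(np.asarray([1.0 if x == lv else 0.0 for x in labels]))
        names.append(f"{prefix}[{lv}]")
    return cols, names


def build_design(sample_ids, batch_design=None, class_labels=None,
                 blocking_terms=None, reference_batch=None) -> DesignMatrix:
    """Assemble an intercept + batch + class (+ blocking) design matrix.

    ``class_labels`` maps sample -> "case"/"control" (control is the
    reference).  Collinear batch/blocking columns are dropped with a
    warning; a class indicator that is aliased with the blocked structure
    raises :class:`ConfoundingError` (a silent drop would turn the test
    of interest into a test of nothing).
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    cols = [np.ones(n)]
    names = ["Intercept"]
    if batch_design is not None:
        labels = [batch_design.assignment[s] for s in sample_ids]
        c, nm = _indicator_columns(labels, batch_design.factor_name, reference_batch)
        cols += c
        names += nm
    if blocking_terms:
        for term, mapping in blocking_terms.items():
            labels = [mapping[s] for s in sample_ids]
            c, nm = _indicator_columns(labels, term)
            cols += c
            names += nm
    class_col = None
    if class_labels is not None:
        labels = [class_labels[s] for s in sample_ids]
        bad = set(labels) - {"case", "control"}
        if bad:
            raise ValueError(f"class labels must be 'case'/'control', got {sorted(bad)}")
        class_col = np.asarray([1.0 if x == "case" else 0.0 for x in labels])

    x = np.column_stack(cols)
    # drop collinear nuisance columns (never the intercept) greedily
    keep = [0]
    dropped = []
    for j in range(1, x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropped collinear design column(s): {', '.join(dropped)}")
    x = x[:, keep]
    names = [names[j] for j in keep]

    if class_col is not None:
        trial = np.column_stack([x, class_col])
        if np.linalg.matrix_rank(trial) == x.shape[1]:
            factor = batch_design.factor_name if batch_design is not None else "blocking structure"
            raise ConfoundingError(
                f"class indicator is confounded with {factor}: the case/control "
                "contrast is not estimable within batches"
            )
        x = trial
        names = names + ["class[case]"]
    return DesignMatrix(x, names, sample_ids, dropped)


@dataclass
class GenewiseFit:
    """Per-probe ordinary least squares against one design."""

    design: DesignMatrix
    probe_ids: list
    coefficients: np.ndarray  # probes x terms
    sigma2: np.ndarray        # residual variance s2_g = RSS / (n - rank)
    df_residual: int
    xtx_inv: np.ndarray       # (X'X)^-1, shared across probes on complete data

    def se_scale(self, contrast: np.ndarray) -> float:
        """Unit-variance standard-error factor sqrt(c' (X'X)^-1 c)."""
        c = np.asarray(contrast, dtype=float)
        return float(np.sqrt(c @ self.xtx_inv @ c))


def fit_genewise(matrix: ExpressionMatrix, design: DesignMatrix) -> GenewiseFit:
    if design.sample_ids != matrix.sample_ids:
        matrix = matrix.subset_samples(design.sample_ids)
    x = design.matrix
    n, p = x.shape
    if n <= p:
        raise ValueError(f"cannot fit: {n} samples with a rank-{p} design leaves no residual df")
    y = matrix.values  # probes x samples
    pinv = np.linalg.pinv(x)
    coef = y @ pinv.T
    resid = y - coef @ x.T
    rss = np.einsum("ij,ij->i", resid, resid)
    df = n - p
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(x.T @ x)
    return GenewiseFit(design, matrix.probe_ids, coef, sigma2, df, xtx_inv)


@dataclass
class EBayesParams:
    """Prior degrees of freedom and prior variance of the hierarchy."""

    d0: float       # may be +inf (all probes share s0^2); 0 forces the ordinary t
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("prior df must be non-negative")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")


_D0_BRACKET = (1e-2, 1e6)
_VAR_FLOOR = 1e-12


def estimate_ebayes(fit: GenewiseFit) -> EBayesParams:
    """Method-of-moments fit of (d0, s0^2) on z_g = log s2_g.

    Under the hierarchy, z_g - log s0^2 has mean digamma(d/2) - log(d/2)
    - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2) beyond
    the sampling variance trigamma(d/2); matching those two moments gives
    the estimator.  When the observed variance of z_g does not exceed the
    sampling variance, d0 = +inf is returned (complete shrinkage).
    """
    s2 = np.asarray(fit.sigma2, dtype=float)
    d = fit.df_residual
    if s2.size < 2 or d <= 0:
        raise ValueError("need at least 2 probes with positive residual df")
    if np.all(s2 <= 0):
        raise ValueError("all residual variances are zero; no variance hierarchy to fit")
    z = np.log(np.maximum(s2, _VAR_FLOOR))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        # no excess dispersion: every gene shares one variance, best
        # estimated by the plain average of the observed variances
        return EBayesParams(np.inf, float(np.mean(s2)))

    def moment_gap(d0):
        return special.polygamma(1, d0 / 2.0) - evar

    lo, hi = _D0_BRACKET
    if moment_gap(lo) < 0:       # more dispersion than even d0=lo explains
        d0 = lo
    elif moment_gap(hi) > 0:     # less dispersion than d0=hi: effectively infinite
        return EBayesParams(np.inf, float(np.mean(s2)))
    else:
        d0 = optimize.brentq(moment_gap, lo, hi, xtol=1e-8, rtol=1e-12)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesParams(float(d0), s0_sq)


@dataclass
class ModeratedTestResult:
    """Per-probe moderated t (or F) with raw and adjusted p-values."""

    probe_ids: list
    estimate: np.ndarray      # contrast estimate, log2 fold change (NaN for F)
    statistic: np.ndarray
    s2_post: np.ndarray
    df_total: float
    p_value: np.ndarray
    adj_p: np.ndarray
    kind: str = "t"
    adjust_method: str = "BH"

    def deg_set(self, alpha: float = 0.05) -> set:
        _check_alpha(alpha)
        return {p for p, q in zip(self.probe_ids, self.adj_p) if q <= alpha}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_ids,
            "logFC": self.estimate,
            self.kind: self.statistic,
            "df_total": self.df_total,
            "p": self.p_value,
            "adj_p": self.adj_p,
        }).set_index("probe_id")


def _posterior_variance(fit: GenewiseFit, ebayes: EBayesParams) -> tuple:
    d0, s0 = ebayes.d0, ebayes.s0_sq
    d = fit.df_residual
    if np.isinf(d0):
        return np.full_like(fit.sigma2, s0), np.inf
    return (d0 * s0 + d * fit.sigma2) / (d0 + d), d0 + d


def _resolve_contrast(fit: GenewiseFit, contrast) -> np.ndarray:
    if isinstance(contrast, str):
        c = np.zeros(fit.design.rank)
        c[fit.design.term_index(contrast)] = 1.0
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.design.rank,):
        raise ValueError(f"contrast length {c.shape} does not match design rank {fit.design.rank}")
    return c


def moderated_t(fit: GenewiseFit, ebayes: EBayesParams, contrast,
                adjust_method: str = "BH") -> ModeratedTestResult:
    """Moderated t for one contrast (term name or coefficient vector).

    ``ebayes`` is mandatory: passing ``EBayesParams`` with d0 -> 0 is the
    explicit way to get the ordinary t, never a silent fallback.
    """
    if ebayes is None:
        raise ValueError("empirical-Bayes parameters are required (no silent ordinary-t fallback)")
    c = _resolve_contrast(fit, contrast)
    est = fit.coefficients @ c
    scale = fit.se_scale(c)
    s2_post, df_total = _posterior_variance(fit, ebayes)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = est / (scale * np.sqrt(s2_post))
    tstat = np.where(np.isnan(tstat), 0.0, tstat)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.minimum(p, 1.0)
    adj = adjust_pvalues(p, adjust_method)
    return ModeratedTestResult(fit.probe_ids, est, tstat, s2_post, df_total, p, adj,
                               "t", adjust_method)


def moderated_f(fit: GenewiseFit, ebayes: EBayesParams, contrasts,
                adjust_method: str = "BH") -> ModeratedTestResult:
    """Moderated F over several contrasts (rows of a contrast matrix)."""
    if ebayes is None:
        raise ValueError("empirical-Bayes parameters are required")
    cmat = np.vstack([_resolve_contrast(fit, c) for c in contrasts])
    q = np.linalg.matrix_rank(cmat)
    cb = fit.coefficients @ cmat.T                       # probes x q
    mid = np.linalg.inv(cmat @ fit.xtx_inv @ cmat.T)
    quad = np.einsum("ij,jk,ik->i", cb, mid, cb)
    s2_post, df_total = _posterior_variance(fit, ebayes)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = quad / (q * s2_post)
    fstat = np.where(np.isnan(fstat), 0.0, fstat)
    if np.isinf(df_total):
        p = stats.chi2.sf(q * fstat, q)
    else:
        p = stats.f.sf(fstat, q, df_total)
    adj = adjust_pvalues(p, adjust_method)
    return ModeratedTestResult(fit.probe_ids, np.full(len(fit.probe_ids), np.nan),
                               fstat, s2_post, df_total, p, adj, "F", adjust_method)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValueError(f"unknown adjustment method {method!r}")


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")


def count_degs(result: ModeratedTestResult, alpha: float = 0.05) -> int:
    _check_alpha(alpha)
    return int(np.sum(result.adj_p <= alpha))
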