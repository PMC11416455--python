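"""Negative-binomial quasi-likelihood modelling of miRNA counts.

The model for miRNA g in sample j is

    y_gj ~ NB(mu_gj, phi_g),   log mu_gj = x_j' beta_g + o_j,

with a log link, an offset o_j = log(TMM-effective library size) and an NB
dispersion phi (variance mu + phi mu^2).  Inference follows the
quasi-likelihood route: the NB layer carries a *trended* dispersion (a
smooth function of average abundance, estimated by Cox-Reid adjusted profile
likelihood in abundance bins), and gene-specific variability is captured by
a quasi-dispersion s2_g = residual deviance / residual df, moderated across
genes by empirical Bayes (a scaled-F prior whose df is estimated by moment
matching on the log scale).  A contrast c'beta = 0 is tested with

    F_g = (drop in deviance / df1) / s2_g,post  ~  F(df1, d0 + df_resid),

where d0 is the estimated prior df.  This moderation borrows strength across
miRNAs and keeps type-I error close to nominal at n = 3 per group.

The user-facing surface is ``NBQLModel`` (data + design) whose ``fit()``
returns an ``NBQLFit``; ``NBQLFit.test(contrast)`` produces a DE table with
log2 fold changes, F statistics and BH-adjusted q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, condition_label
from .errors import AnalysisError

__all__ = [
    "NBQLModel",
    "NBQLFit",
    "DispersionEstimates",
    "design_matrix",
    "pairwise_contrast",
    "fit_nb_glm",
    "estimate_dispersions",
    "ql_f_test",
    "bh_adjust",
]

_PHI_MIN = 1e-8
_ETA_MIN, _ETA_MAX = -30.0, 30.0

DE_COLUMNS = ["log2fc", "avg_log2cpm", "f_stat", "df1", "df2", "p_value", "q_value"]


# ---------------------------------------------------------------------------
# design helpers

def design_matrix(samples: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """One-hot design with one coefficient per condition cell.

    ``by='condition'`` uses genotype.region.timepoint cells; ``by='timepoint'``
    collapses to region-agnostic timepoints (used within one region's
    temporal analysis); ``by='genotype'`` to genotype cells.
    """
    if by == "condition":
        labels = [
            condition_label(g, r, t)
            for g, r, t in zip(samples["genotype"], samples["region"], samples["timepoint"])
        ]
    elif by == "timepoint":
        labels = list(samples["timepoint"])
    elif by == "genotype":
        labels = list(samples["genotype"])
    elif by == "genotype_timepoint":
        labels = [f"{g}.{t}" for g, t in zip(samples["genotype"], samples["timepoint"])]
    else:
        raise ValueError(f"unknown design grouping {by!r}")
    levels = list(dict.fromkeys(labels))  # first-appearance order
    X = pd.DataFrame(0.0, index=samples.index, columns=levels)
    for sid, lab in zip(samples.index, labels):
        X.loc[sid, lab] = 1.0
    return X


def pairwise_contrast(design: pd.DataFrame, a: str, b: str) -> np.ndarray:
    """Contrast vector estimating coefficient ``a`` minus coefficient ``b``."""
    c = np.zeros(design.shape[1])
    cols = list(design.columns)
    c[cols.index(a)] = 1.0
    c[cols.index(b)] = -1.0
    return c


# ---------------------------------------------------------------------------
# NB likelihood pieces (vectorized over a gene-by-sample matrix)

def _nb_unit_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-cell NB deviance; phi broadcasts over genes. Poisson limit at phi=0."""
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    small = phi < _PHI_MIN
    if np.all(small):
        return 2.0 * (ylogy - (y - mu))
    phi_safe = np.maximum(phi, _PHI_MIN)
    r = 1.0 / phi_safe
    nb = 2.0 * (ylogy - (y + r) * np.log((1.0 + phi_safe * y) / (1.0 + phi_safe * mu)))
    pois = 2.0 * (ylogy - (y - mu))
    return np.where(np.broadcast_to(small, nb.shape), pois, nb)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Residual deviance per gene."""
    phi = np.asarray(phi, float)
    if phi.ndim == 1:
        phi = phi[:, None]
    return _nb_unit_deviance(y, mu, phi).sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB log-likelihood per gene (Poisson limit for tiny phi)."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    phi = np.asarray(phi, float)
    if phi.ndim == 1:
        phi = phi[:, None]
    phi_b = np.broadcast_to(np.maximum(phi, _PHI_MIN), mu.shape)
    r = 1.0 / phi_b
    nb = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + y * np.log(phi_b * mu / (1.0 + phi_b * mu))
        - r * np.log1p(phi_b * mu)
    )
    pois = y * np.log(mu) - mu - special.gammaln(y + 1.0)
    out = np.where(np.broadcast_to(phi, mu.shape) < _PHI_MIN, pois, nb)
    return out.sum(axis=1)


# ---------------------------------------------------------------------------
# IRLS fit, vectorized across genes

def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    dispersion,
    tol: float = 1e-8,
    max_iter: int = 100,
    return_info: bool = False,
):
    """Fit log-link NB GLMs to every row of ``y`` by Fisher-scoring IRLS.

    Parameters
    ----------
    y : (G, n) counts;  X : (n, p) full-rank design;  offset : (n,) or (G, n)
    dispersion : scalar or (G,) NB dispersions (0 = Poisson).

    Returns ``(beta, mu, deviance)`` and, with ``return_info=True``, a dict
    carrying per-gene convergence flags and the Cox-Reid ``0.5*logdet``
    adjustment of the final weighted information matrix.
    """
    y = np.atleast_2d(np.asarray(y, float))
    X = np.asarray(X, float)
    G, n = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise AnalysisError("design matrix is not of full column rank")
    offset = np.asarray(offset, float)
    if offset.ndim == 1:
        offset = np.broadcast_to(offset, (G, n))
    phi = np.asarray(dispersion, float)
    if phi.ndim == 0:
        phi = np.full(G, float(phi))
    phi_col = phi[:, None]

    # start from moderated observed counts on the log scale
    mu = np.maximum(y, 0.0) + np.maximum(y.mean(axis=1, keepdims=True), 1.0) / 6.0
    eta = np.log(mu)
    ridge = 1e-10 * np.eye(p)
    dev = np.full(G, np.inf)
    converged = np.zeros(G, bool)
    A = None
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, _ETA_MIN + offset.min(), _ETA_MAX + offset.max()))
        mu = np.maximum(mu, 1e-10)
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("np,gn,nq->gpq", X, W, X) + ridge
        b = np.einsum("np,gn,gn->gp", X, W, z)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        eta = offset + beta @ X.T
        eta = np.clip(eta, _ETA_MIN, _ETA_MAX)
        mu_new = np.maximum(np.exp(eta), 1e-10)
        dev_new = nb_deviance(y, mu_new, phi)
        converged = np.abs(dev_new - dev) <= tol * (np.abs(dev_new) + 1.0)
        dev = dev_new
        if converged.all():
            break
    mu = np.maximum(np.exp(eta), 1e-10)
    if return_info:
        sign, logdet = np.linalg.slogdet(A)
        info = {"converged": converged, "cox_reid": 0.5 * logdet}
        return beta, mu, dev, info
    return beta, mu, dev


# ---------------------------------------------------------------------------
# dispersion estimation

def _avg_log2_cpm(y: np.ndarray, lib: np.ndarray, prior: float = 2.0) -> np.ndarray:
    pr = prior * lib / lib.mean()
    return np.log2((y + pr) / (lib + 2 * pr) * 1e6).mean(axis=1)


def _bin_apl(y, X, offset, log10_phi) -> float:
    """Summed Cox-Reid adjusted profile likelihood of one abundance bin."""
    phi = 10.0 ** log10_phi
    beta, mu, _, info = fit_nb_glm(y, X, offset, phi, return_info=True)
    ll = nb_loglik(y, mu, phi)
    return float(np.sum(ll - info["cox_reid"]))


@dataclass
class DispersionEstimates:
    """Trended NB dispersions and moderated quasi-dispersions."""

    trended: np.ndarray            # per-gene NB dispersion from the abundance trend
    avg_log2cpm: np.ndarray        # per-gene average abundance
    bin_abundance: np.ndarray      # abundance at bin centers
    bin_dispersion: np.ndarray     # binned Cox-Reid estimates (pre-smoothing)
    quasi_dispersion: np.ndarray   # raw s2 = deviance / residual df
    squeezed_quasi: np.ndarray     # EB-moderated s2
    prior_df: float                # d0 (may be inf)
    prior_var: float               # s0^2, the prior quasi-dispersion
    df_residual: int

    def summary(self) -> str:
        d0 = "inf" if np.isinf(self.prior_df) else f"{self.prior_df:.2f}"
        return (
            f"trended NB dispersion: median {np.median(self.trended):.4g} "
            f"(range {self.trended.min():.4g}-{self.trended.max():.4g}); "
            f"quasi-dispersion prior df {d0}, prior value {self.prior_var:.3f}"
        )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (as in EB variance moderation)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_quasi(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Moment-match a scaled-F prior on log quasi-dispersions; squeeze toward it.

    Models s2_g ~ s0^2 * F(df, d0).  On the log scale, E and Var of log s2
    involve digamma/trigamma terms; d0 solves trigamma(d0/2) = var(e) and the
    posterior is the df-weighted combination (d0*s0^2 + df*s2) / (d0 + df).
    """
    ok = s2 > 1e-12
    if ok.sum() < 2:
        return s2.copy(), np.inf, float(np.median(s2))
    z = np.log(s2[ok])
    if np.var(z, ddof=1) < 1e-12:
        # degenerate: no spread at all, so no chi2 sampling noise to correct
        return s2.copy(), np.inf, float(np.exp(np.mean(z)))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_2)
    return post, d0, s0_2


def estimate_dispersions(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    n_bins: int = 10,
    lowess_frac: float = 0.6,
) -> DispersionEstimates:
    """Estimate the dispersion trend and EB-moderated quasi-dispersions.

    NB dispersions are profiled per abundance bin (Cox-Reid adjusted profile
    likelihood, maximized over log10 phi in [-8, 1]), smoothed against
    average log2 CPM, and interpolated to every gene.  Quasi-dispersions are
    residual deviance / residual df at the trended NB dispersion, then
    squeezed by empirical Bayes.
    """
    y = np.atleast_2d(np.asarray(y, float))
    X = np.asarray(X, float)
    G, n = y.shape
    p = X.shape[1]
    df_resid = n - p
    if df_resid < 1:
        raise AnalysisError(
            "residual df is 0; use a common quasi-dispersion (drop coefficients "
            "or add replicates)"
        )
    offset = np.asarray(offset, float)
    lib = np.exp(offset if offset.ndim == 1 else offset[0])
    abundance = _avg_log2_cpm(y, lib)

    n_bins = max(min(n_bins, G), 1)
    order = np.argsort(abundance)
    bins = np.array_split(order, n_bins)
    bin_ab = np.empty(len(bins))
    bin_phi = np.empty(len(bins))
    for i, idx in enumerate(bins):
        bin_ab[i] = abundance[idx].mean()
        res = optimize.minimize_scalar(
            lambda lp, ii=idx: -_bin_apl(y[ii], X, offset, lp),
            bounds=(-8.0, 1.0),
            method="bounded",
            options={"xatol": 5e-3},
        )
        bin_phi[i] = 10.0 ** res.x

    if len(bins) >= 4:
        sm = lowess(np.log10(bin_phi), bin_ab, frac=lowess_frac, return_sorted=True)
        trended = 10.0 ** np.interp(abundance, sm[:, 0], sm[:, 1])
    else:
        trended = 10.0 ** np.interp(abundance, bin_ab, np.log10(bin_phi))

    _, _, dev = fit_nb_glm(y, X, offset, trended)
    s2 = dev / df_resid
    post, d0, s0_2 = _squeeze_quasi(s2, df_resid)
    return DispersionEstimates(
        trended=trended,
        avg_log2cpm=abundance,
        bin_abundance=bin_ab,
        bin_dispersion=bin_phi,
        quasi_dispersion=s2,
        squeezed_quasi=post,
        prior_df=d0,
        prior_var=s0_2,
        df_residual=df_resid,
    )


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p propagate as NaN q."""
    p = np.asarray(pvalues, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# the model / results pair

class NBQLModel:
    """NB quasi-likelihood GLM over a filtered count matrix.

    Parameters
    ----------
    counts
        A :class:`~evmirna.containers.CountMatrix` or a plain gene-by-sample
        DataFrame of counts.
    design
        Sample-by-coefficient design matrix (full column rank); typically
        built with :func:`design_matrix`.
    offset
        Per-sample log effective library sizes.  Defaults to log column
        totals; pass ``log(library size * TMM factor)`` for normalized fits.

    Examples
    --------
    >>> X = design_matrix(cm.samples, by="timepoint")       # doctest: +SKIP
    >>> fit = NBQLModel(cm, X).fit()                        # doctest: +SKIP
    >>> table = fit.test(pairwise_contrast(X, "D75", "D0")) # doctest: +SKIP
    """

    def __init__(self, counts, design: pd.DataFrame, offset=None):
        if isinstance(counts, CountMatrix):
            self.counts = counts.counts
        else:
            self.counts = counts
        if not self.counts.columns.equals(design.index):
            design = design.loc[self.counts.columns]
        self.design = design
        self.gene_ids = self.counts.index
        if offset is None:
            offset = np.log(self.counts.sum(axis=0).to_numpy(float))
        self.offset = np.asarray(offset, float)
        self._y = self.counts.to_numpy(float)
        self._X = design.to_numpy(float)
        if np.linalg.matrix_rank(self._X) < self._X.shape[1]:
            raise AnalysisError("design matrix is not of full column rank")

    @property
    def df_residual(self) -> int:
        return self._y.shape[1] - self._X.shape[1]

    def fit(self, dispersion=None, n_bins: int = 10) -> "NBQLFit":
        """Estimate dispersions (unless given) and fit the full model.

        ``dispersion`` may be a scalar or per-gene array to bypass the
        trend estimation (useful for simulations with known dispersion);
        the quasi-dispersion/EB layer is still applied.
        """
        if dispersion is None:
            disp = estimate_dispersions(self._y, self._X, self.offset, n_bins=n_bins)
        else:
            trended = np.broadcast_to(
                np.asarray(dispersion, float), (self._y.shape[0],)
            ).copy()
            _, _, dev = fit_nb_glm(self._y, self._X, self.offset, trended)
            df = self.df_residual
            if df < 1:
                raise AnalysisError("residual df is 0; cannot form quasi-dispersions")
            s2 = dev / df
            post, d0, s0_2 = _squeeze_quasi(s2, df)
            lib = np.exp(self.offset)
            disp = DispersionEstimates(
                trended=trended,
                avg_log2cpm=_avg_log2_cpm(self._y, lib),
                bin_abundance=np.array([]),
                bin_dispersion=np.array([]),
                quasi_dispersion=s2,
                squeezed_quasi=post,
                prior_df=d0,
                prior_var=s0_2,
                df_residual=df,
            )
        beta, mu, dev, info = fit_nb_glm(
            self._y, self._X, self.offset, disp.trended, return_info=True
        )
        return NBQLFit(self, disp, beta, mu, dev, info["converged"])


@dataclass
class NBQLFit:
    """Fitted NB QL model; exposes contrast tests and a text summary."""

    model: NBQLModel
    dispersion: DispersionEstimates
    coefficients: np.ndarray       # (G, p), natural-log scale
    fitted: np.ndarray             # (G, n) fitted means
    deviance: np.ndarray           # (G,) residual deviances
    converged: np.ndarray = field(repr=False, default=None)

    @property
    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients, index=self.model.gene_ids, columns=self.model.design.columns
        )

    def _null_design(self, contrast: np.ndarray) -> np.ndarray:
        C = np.atleast_2d(np.asarray(contrast, float))
        if not C.any():
            raise AnalysisError("contrast vector must be nonzero")
        N = linalg.null_space(C)  # (p, p - df1)
        return self.model._X @ N

    def test(self, contrast, name: str | None = None) -> pd.DataFrame:
        """Quasi-likelihood F-test of ``contrast' beta = 0`` for every gene.

        Returns a DataFrame indexed by miRNA id with columns ``log2fc``
        (contrast estimate / log 2), ``avg_log2cpm``, ``f_stat``, ``df1``,
        ``df2``, ``p_value`` and BH-adjusted ``q_value``.
        """
        c = np.asarray(contrast, float)
        C = np.atleast_2d(c)
        df1 = np.linalg.matrix_rank(C) if C.any() else 0
        if df1 < 1:
            raise AnalysisError("contrast has rank 0")
        m = self.model
        X_null = self._null_design(c)
        _, _, dev_null = fit_nb_glm(m._y, X_null, m.offset, self.dispersion.trended)
        drop = np.maximum(dev_null - self.deviance, 0.0)
        s2 = self.dispersion.squeezed_quasi
        f = drop / df1 / np.maximum(s2, 1e-12)
        d0 = self.dispersion.prior_df
        df2 = d0 + self.dispersion.df_residual
        if np.isinf(df2):
            p = stats.chi2.sf(f * df1, df1)
        else:
            p = stats.f.sf(f, df1, df2)
        if self.converged is not None and not self.converged.all():
            p = np.where(self.converged, p, 1.0)
            warnings.warn(
                f"{int((~self.converged).sum())} gene(s) did not converge; p set to 1",
                stacklevel=2,
            )
        logfc = self._log2fc(c) if c.ndim == 1 else np.full(len(p), np.nan)
        out = pd.DataFrame(
            {
                "log2fc": logfc,
                "avg_log2cpm": self.dispersion.avg_log2cpm,
                "f_stat": f,
                "df1": df1,
                "df2": df2,
                "p_value": p,
                "q_value": bh_adjust(p),
            },
            index=m.gene_ids,
        )
        out.index.name = "mirna_id"
        if name is not None:
            out.attrs["contrast"] = name
        return out

    def _log2fc(self, c: np.ndarray) -> np.ndarray:
        """Contrast estimate on the log2 scale; degenerate rows use prior counts.

        A row whose counts are all zero on one side of the contrast has an
        unbounded MLE; such rows get their fold change from a refit on
        prior-augmented counts (prior 0.5, scaled to library size).
        """
        m = self.model
        logfc = (self.coefficients @ c) / np.log(2.0)
        involved = np.abs(m._X[:, c != 0]).sum(axis=1) > 0
        pos_samples = (m._X[:, c > 0]).sum(axis=1) > 0
        neg_samples = (m._X[:, c < 0]).sum(axis=1) > 0
        y = m._y
        degen = (y[:, pos_samples].sum(axis=1) == 0) | (y[:, neg_samples].sum(axis=1) == 0)
        del involved
        if degen.any():
            lib = np.exp(m.offset)
            prior = 0.5 * lib / lib.mean()
            beta_aug, _, _ = fit_nb_glm(
                y[degen] + prior, m._X, m.offset, self.dispersion.trended[degen]
            )
            logfc = logfc.copy()
            logfc[degen] = (beta_aug @ c) / np.log(2.0)
        return logfc

    def summary(self) -> str:
        m = self.model
        G, n = m._y.shape
        lines = [
            "NB quasi-likelihood GLM fit",
            "=" * 27,
            f"genes: {G}   samples: {n}   coefficients: {m._X.shape[1]}"
            f"   residual df: {self.dispersion.df_residual}",
            self.dispersion.summary(),
            f"non-converged genes: {int((~self.converged).sum()) if self.converged is not None else 0}",
        ]
        return "\n".join(lines)


def ql_f_test(fit: NBQLFit, contrast, name: str | None = None) -> pd.DataFrame:
    """Functional alias for :meth:`NBQLFit.test`."""
    return fit.test(contrast, name=name)
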