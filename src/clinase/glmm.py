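"""Binomial logit mixed model with genotype and observation-level random effects.

This is the modelling core of the package: allele-informative read counts of
one gene are treated as binomial draws whose logit-scale mean combines fixed
effects (intercept; optionally allele Group, Population, or
Latitude/Continent terms) with a genotype-level random intercept (the
cis-regulatory signal) and an observation-level random intercept (biological
replicate overdispersion).  The API follows the statsmodels convention: a
:class:`BinomialGLMM` model object is built from data and ``fit()`` returns a
:class:`BinomialGLMMResults` carrying estimates, uncertainties and
diagnostics.

The marginal likelihood is evaluated by nested adaptive Gauss-Hermite
quadrature (see :mod:`clinase._likelihood`), which keeps the variance
boundary ``sigma = 0`` exact — essential for the likelihood-ratio test of the
genotype variance component used to call allele-specific expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import gammaln

from ._likelihood import gauss_hermite, loglik_kernel

__all__ = ["BinomialGLMM", "BinomialGLMMResults"]

_SIGMA_UPPER = 15.0


class BinomialGLMM:
    """Binomial logit mixed model for allele-specific read counts.

    Parameters
    ----------
    endog : array-like, shape (nobs, 2)
        Columns (successes, failures): wild-allele and reference-allele read
        counts per observation (one observation = one library/replicate).
    exog : array-like, shape (nobs, k)
        Fixed-effect design matrix (include the intercept column).
    groups : array-like, shape (nobs,)
        Genotype (line) label per observation; defines the genotype-level
        random intercept.  The observation-level random intercept has one
        level per row and needs no labels.
    exog_names : sequence of str, optional
    n_quad : int
        Gauss-Hermite nodes per integral (adaptive, so 9 is ample).
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_quad=9):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim != 2 or endog.shape[1] != 2:
            raise ValueError("endog must have two columns (successes, failures)")
        if np.any(endog < 0):
            raise ValueError("counts must be non-negative")
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != endog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        groups = np.asarray(groups)
        if groups.shape[0] != endog.shape[0]:
            raise ValueError("groups length mismatch")

        totals = endog.sum(axis=1)
        if np.all(totals == 0):
            raise ValueError("all rows have zero total counts")
        keep = totals > 0
        endog, exog, groups = endog[keep], exog[keep], groups[keep]

        order = np.argsort(groups, kind="stable")
        self.endog = endog[order]
        self.exog = exog[order]
        self.groups = groups[order]
        self.nobs = self.endog.shape[0]
        self.k_exog = self.exog.shape[1]
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.k_exog)])
        self.n_quad = int(n_quad)

        uniq, idx = np.unique(self.groups, return_index=True)
        starts = np.sort(idx)
        self.group_labels = self.groups[starts]
        self.n_groups = len(uniq)
        self._gstart = starts.astype(np.int64)
        self._gend = np.append(starts[1:], self.nobs).astype(np.int64)

        self._y = self.endog[:, 0].astype(np.float64)
        self._n = totals[keep][order].astype(np.float64)
        self._lgc = (gammaln(self._n + 1) - gammaln(self._y + 1)
                     - gammaln(self._n - self._y + 1))
        self._z, self._w = gauss_hermite(self.n_quad)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_gene_data(cls, data: pd.DataFrame, fixed: str = "1", n_quad: int = 9):
        """Build the model from a long-format per-gene count table.

        ``data`` needs columns ``wild_count``, ``ref_count``, ``genotype``
        and, depending on ``fixed``, ``group`` / ``population`` /
        ``latitude`` + ``continent``.

        fixed : one of
          - ``"1"``: intercept only (the ASE model),
          - ``"group"``: intercept + high/low allele-group indicator,
          - ``"population"``: one mean per population (cell-means coding),
          - ``"latitude"``: intercept + latitude + continent + interaction.
        """
        y = data[["wild_count", "ref_count"]].to_numpy(dtype=float)
        g = data["genotype"].to_numpy()
        if fixed == "1":
            X = np.ones((len(data), 1))
            names = ["Intercept"]
        elif fixed == "group":
            grp = np.asarray(data["group"])
            levels = sorted(pd.unique(grp).tolist())
            if len(levels) != 2:
                raise ValueError("group must have exactly two levels")
            X = np.column_stack([np.ones(len(data)),
                                 (grp == levels[1]).astype(float)])
            names = ["Intercept", f"Group[{levels[1]}]"]
        elif fixed == "population":
            pops = pd.unique(data["population"])
            X = np.column_stack([(data["population"] == p).to_numpy(dtype=float)
                                 for p in pops])
            names = [f"Population[{p}]" for p in pops]
        elif fixed == "latitude":
            lat = (data["latitude"].astype(str) == "tropical").astype(float).to_numpy()
            conts = pd.unique(data["continent"])
            if len(conts) != 2:
                raise ValueError("latitude model needs exactly two continents")
            cont = (data["continent"] == conts[1]).to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(data)), lat, cont, lat * cont])
            names = ["Intercept", "Latitude[tropical]",
                     f"Continent[{conts[1]}]", "Latitude:Continent"]
        else:
            raise ValueError(f"unknown fixed-effect specification {fixed!r}")
        return cls(y, X, g, exog_names=names, n_quad=n_quad)

    # ------------------------------------------------------------------ #
    def loglike(self, beta, sigma_g, sigma_r, n_quad=None):
        """Marginal log-likelihood at the given parameter values."""
        if sigma_g < 0 or sigma_r < 0:
            return -np.inf
        if n_quad is None:
            z, w = self._z, self._w
        else:
            z, w = gauss_hermite(n_quad)
        eta = self.exog @ np.asarray(beta, dtype=float)
        return loglik_kernel(eta, self._y, self._n, self._lgc,
                             self._gstart, self._gend,
                             float(sigma_g), float(sigma_r), z, w)

    def _start_params(self):
        p = (self._y.sum() + 0.5) / (self._n.sum() + 1.0)
        beta = np.zeros(self.k_exog)
        # cell-means designs have no plain intercept column marked; seed every
        # column that looks like an indicator mean with the pooled logit
        if self.k_exog == 1 or "Intercept" in self.exog_names:
            beta[self.exog_names.index("Intercept")
                 if "Intercept" in self.exog_names else 0] = special.logit(p)
        else:
            beta[:] = special.logit(p)
        # crude genotype-scale start from per-genotype empirical logits
        logits = np.empty(self.n_groups)
        for i, (s, e) in enumerate(zip(self._gstart, self._gend)):
            yy, nn = self._y[s:e].sum(), self._n[s:e].sum()
            logits[i] = special.logit((yy + 0.5) / (nn + 1.0))
        sg0 = float(np.clip(np.std(logits), 0.05, 2.0))
        return beta, sg0, 0.3

    def fit(self, start_params=None, fix_sigma_g=None, fix_sigma_r=None,
            maxiter=500):
        """Maximise the marginal likelihood.

        ``fix_sigma_g`` / ``fix_sigma_r`` pin a variance component (e.g. 0.0
        to drop it), which is how nested models for likelihood-ratio tests
        are fitted.
        """
        beta0, sg0, sr0 = self._start_params()
        if start_params is not None:
            start_params = np.asarray(start_params, dtype=float)
            beta0 = start_params[:self.k_exog]
            if len(start_params) >= self.k_exog + 2:
                sg0 = float(np.clip(start_params[self.k_exog], 1e-3, 5.0))
                sr0 = float(np.clip(start_params[self.k_exog + 1], 1e-3, 5.0))

        free_g = fix_sigma_g is None
        free_r = fix_sigma_r is None
        x0 = list(beta0)
        bounds = [(None, None)] * self.k_exog
        if free_g:
            x0.append(sg0)
            bounds.append((0.0, _SIGMA_UPPER))
        if free_r:
            x0.append(sr0)
            bounds.append((0.0, _SIGMA_UPPER))

        def unpack(x):
            beta = np.asarray(x[:self.k_exog])
            i = self.k_exog
            if free_g:
                sg = x[i]; i += 1
            else:
                sg = fix_sigma_g
            sr = x[i] if free_r else fix_sigma_r
            return beta, float(sg), float(sr)

        def nll(x):
            beta, sg, sr = unpack(x)
            ll = self.loglike(beta, sg, sr)
            if not np.isfinite(ll):
                return 1e12
            return -ll

        res = optimize.minimize(nll, np.asarray(x0, dtype=float),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        if not res.success:
            res2 = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": 4 * maxiter, "fatol": 1e-10,
                         "xatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
        beta, sg, sr = unpack(res.x)
        return BinomialGLMMResults(
            model=self, params=beta, sigma_g=sg, sigma_r=sr,
            llf=-res.fun, converged=bool(res.success), nfev=int(res.nfev),
            fixed_sigma_g=fix_sigma_g, fixed_sigma_r=fix_sigma_r)


@dataclass
class BinomialGLMMResults:
    """Fit results: estimates, variance components and diagnostics."""

    model: BinomialGLMM
    params: np.ndarray
    sigma_g: float
    sigma_r: float
    llf: float
    converged: bool
    nfev: int
    fixed_sigma_g: float | None = None
    fixed_sigma_r: float | None = None
    _bse: np.ndarray | None = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Marginal-mean success proportion per observation (at u = v = 0)."""
        return special.expit(self.model.exog @ self.params)

    @property
    def mean_ref_proportion(self) -> float:
        """Reference-allele proportion implied by the intercept."""
        names = self.model.exog_names
        j = names.index("Intercept") if "Intercept" in names else 0
        return float(special.expit(-self.params[j]))

    @property
    def bse(self) -> np.ndarray:
        """Fixed-effect standard errors from the numerical Hessian."""
        if self._bse is None:
            k = self.model.k_exog
            h = np.zeros((k, k))
            eps = 1e-4

            def f(b):
                return self.model.loglike(b, self.sigma_g, self.sigma_r)

            for i in range(k):
                for j in range(i, k):
                    bi = self.params.copy(); bi[i] += eps; bi[j] += eps
                    bj = self.params.copy(); bj[i] += eps; bj[j] -= eps
                    bk = self.params.copy(); bk[i] -= eps; bk[j] += eps
                    bl = self.params.copy(); bl[i] -= eps; bl[j] -= eps
                    h[i, j] = h[j, i] = (f(bi) - f(bj) - f(bk) + f(bl)) / (4 * eps * eps)
            try:
                cov = np.linalg.inv(-h)
                d = np.diag(cov)
                self._bse = np.sqrt(np.where(d > 0, d, np.nan))
            except np.linalg.LinAlgError:
                self._bse = np.full(k, np.nan)
        return self._bse

    def check_quadrature(self) -> float:
        """|Δ log-likelihood| when the node count is doubled (accuracy check)."""
        ll2 = self.model.loglike(self.params, self.sigma_g, self.sigma_r,
                                 n_quad=2 * self.model.n_quad)
        return float(abs(ll2 - self.llf))

    def lrt_against(self, reduced: "BinomialGLMMResults",
                    df: int = 1, boundary_mixture: bool = False):
        """Likelihood-ratio test of this (full) fit against a nested fit.

        With ``boundary_mixture`` the reference is the 0.5*chi2_0 +
        0.5*chi2_1 mixture appropriate for a variance component on the
        boundary; the default is the plain chi-square.
        """
        stat = 2.0 * (self.llf - reduced.llf)
        if stat < 0:
            if stat < -1e-4:
                raise ValueError(f"negative LRT statistic {stat:.3g}: "
                                 "fits are not properly nested")
            stat = 0.0
        if boundary_mixture:
            p = 0.5 * stats.chi2.sf(stat, df) if stat > 0 else 1.0
        else:
            p = stats.chi2.sf(stat, df) if stat > 0 else 1.0
        return stat, float(p)

    def summary(self) -> str:
        lines = ["Binomial logit mixed model (adaptive Gauss-Hermite)",
                 "=" * 56,
                 f"No. observations: {self.model.nobs:>6d}   "
                 f"No. genotypes: {self.model.n_groups}",
                 f"Log-likelihood:  {self.llf:>12.4f}   "
                 f"Converged: {self.converged}",
                 "-" * 56,
                 f"{'term':<24}{'coef':>10}{'std err':>10}"]
        bse = self.bse
        for name, b, se in zip(self.model.exog_names, self.params, bse):
            lines.append(f"{name:<24}{b:>10.4f}{se:>10.4f}")
        lines.append("-" * 56)
        lines.append(f"sigma_g (genotype)    {self.sigma_g:>10.4f}"
                     + ("   [fixed]" if self.fixed_sigma_g is not None else ""))
        lines.append(f"sigma_r (replicate)   {self.sigma_r:>10.4f}"
                     + ("   [fixed]" if self.fixed_sigma_r is not None else ""))
        lines.append(f"mean ref proportion   {self.mean_ref_proportion:>10.4f}")
        return "\n".join(lines)
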