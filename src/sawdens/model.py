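"""Tweedie penalized-spline density model with a log-effort offset.

The mean model is

    log mu_i = log(effort_i) + beta0 + sum_j s_j(x_ij) + parametric terms

with catches Tweedie-distributed (variance phi * mu^p, 1 < p < 2).
Smooths are penalized B-spline bases (basis dimension ``k`` per smooth,
default 10); parametric terms are factor dummies (Season, River,
DevelopedSL).  Smoothing weights are chosen by coordinate-wise grid
search of a conditional AIC built on the Tweedie series log-likelihood,
and the power parameter is chosen by profiling the same criterion over a
grid in (1, 2).  The estimation backend is penalized IRLS
(``statsmodels`` GLMGam).

Usage follows the statsmodels convention::

    model = DensityGAM.from_dataframe(survey_df, spec)
    result = model.fit()
    print(result.summary())
    mu, se = result.predict(new_df, soak_area)
    draws = result.sample_posterior(1000, seed=1)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.genmod.families import Tweedie

from .tweedie import rng_from_seed

log = logging.getLogger(__name__)

#: covariates modelled as penalized smooths when included
SMOOTH_CANDIDATES = (
    "depth_min_m", "avg_do", "avg_temp", "avg_salin", "avg_ph",
    "min_mdts", "sum_mnn", "year", "dist_to_rm_m",
)
#: covariates modelled as parametric factors when included
FACTOR_CANDIDATES = ("season", "river", "developed_sl")

DEFAULT_POWER_GRID = np.round(np.arange(1.05, 2.0, 0.1), 3)
DEFAULT_ALPHA_GRID = 10.0 ** np.arange(-2.0, 7.0)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: which covariates enter, and in what role."""

    smooths: tuple = ()
    factors: tuple = ()

    def __post_init__(self):
        unknown = set(self.smooths) - set(SMOOTH_CANDIDATES)
        if unknown:
            raise ValueError(f"unknown smooth covariates: {sorted(unknown)}")
        unknown = set(self.factors) - set(FACTOR_CANDIDATES)
        if unknown:
            raise ValueError(f"unknown factor covariates: {sorted(unknown)}")

    @property
    def covariates(self) -> tuple:
        return tuple(self.smooths) + tuple(self.factors)

    @classmethod
    def from_covariates(cls, names) -> "ModelSpec":
        smooths = tuple(n for n in names if n in SMOOTH_CANDIDATES)
        factors = tuple(n for n in names if n in FACTOR_CANDIDATES)
        leftover = set(names) - set(smooths) - set(factors)
        if leftover:
            raise ValueError(f"unknown covariates: {sorted(leftover)}")
        return cls(smooths, factors)

    def label(self) -> str:
        terms = [f"s({n})" for n in self.smooths] + list(self.factors)
        return " + ".join(terms) if terms else "1"


def _inner_knots(x: np.ndarray, df: int, degree: int = 3) -> np.ndarray:
    """Interior B-spline knots at data quantiles, made strictly distinct.

    Tied covariate values (zero-inflated habitat metrics) would place
    coincident quantile knots and degenerate basis columns; quantiles
    are then taken over the unique values, with equal spacing as the
    last resort.
    """
    n_inner = df - (degree + 1)
    q = np.linspace(0, 1, n_inner + 2)[1:-1]
    knots = np.quantile(x, q)
    if len(np.unique(knots)) < len(knots):
        knots = np.quantile(np.unique(x), q)
    if len(np.unique(knots)) < len(knots):
        knots = x.min() + q * (x.max() - x.min())
    return knots


class DensityGAM:
    """Tweedie GAM for juvenile density from survey-set tables."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 response: str = "n_caught", offset: str = "effort_yard_min",
                 k: int = 10):
        used = [response, offset, *spec.covariates]
        missing = [c for c in used if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = data[used].dropna().reset_index(drop=True)  # complete cases
        self.n_dropped = len(data) - len(df)
        if self.n_dropped:
            log.info("complete-case analysis: %d rows dropped", self.n_dropped)
        self.data = df
        self.spec = spec
        self.response = response
        self.offset_col = offset
        self.k = int(k)
        if (df[offset] <= 0).any():
            raise ValueError("offsets (effort) must be positive")

        self.endog = df[response].to_numpy(float)
        self.offset = np.log(df[offset].to_numpy(float))
        n_min = 10 * max(len(spec.smooths), 1)
        if len(df) < n_min:
            raise ValueError(f"need >= {n_min} observations for {len(spec.smooths)} smooths")

        # parametric design: intercept + factor dummies
        self.factor_levels = {}
        cols = [np.ones(len(df))]
        names = ["Intercept"]
        for f in spec.factors:
            levels = sorted(pd.unique(df[f].astype(str)))
            self.factor_levels[f] = levels
            for lev in levels[1:]:
                cols.append((df[f].astype(str) == lev).to_numpy(float))
                names.append(f"{f}[{lev}]")
        self.exog = np.column_stack(cols)
        self.exog_names = names

        # smooth design
        if spec.smooths:
            x = df[list(spec.smooths)].to_numpy(float)
            self.smooth_ranges = [(x[:, j].min(), x[:, j].max())
                                  for j in range(x.shape[1])]
            # sum-to-zero (centering) constraint per smooth keeps the
            # basis orthogonal to the intercept; quantile-spaced knots
            # (deduplicated, so heavily tied covariates such as mangrove
            # sums cannot produce coincident knots) keep the basis well
            # conditioned
            self.smoother = BSplines(
                x, df=[self.k] * len(spec.smooths),
                degree=[3] * len(spec.smooths),
                variable_names=list(spec.smooths),
                constraints="center",
                knot_kwds=[{"knots": _inner_knots(x[:, j], self.k)}
                           for j in range(x.shape[1])],
            )
        else:
            self.smoother = None
            self.smooth_ranges = []

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec | None = None,
                       **kwargs) -> "DensityGAM":
        if spec is None:
            spec = ModelSpec(
                smooths=tuple(s for s in SMOOTH_CANDIDATES if s in data.columns),
                factors=tuple(f for f in FACTOR_CANDIDATES if f in data.columns),
            )
        return cls(data, spec, **kwargs)

    # ------------------------------------------------------------------
    def _fit_once(self, power: float, alpha):
        fam = Tweedie(var_power=float(power))
        if self.smoother is None:
            import statsmodels.api as sm

            res = sm.GLM(self.endog, self.exog, family=fam,
                         offset=self.offset).fit()
            return res
        m = GLMGam(self.endog, exog=self.exog, smoother=self.smoother,
                   alpha=list(alpha), family=fam, offset=self.offset)
        return m.fit(maxiter=100)

    def _edf(self, res) -> float:
        edf = getattr(res, "edf", None)
        if edf is None:
            return float(len(res.params))
        return float(np.sum(edf))

    def _criterion(self, res, power: float) -> float:
        """Conditional AIC: -2 x Tweedie series loglik + 2 (edf + 2).

        The +2 counts the dispersion and power parameters.  The Pearson
        scale of the fit is used as the dispersion.
        """
        edf = self._edf(res)
        # reject numerically degenerate fits (ill-conditioned basis)
        if not np.isfinite(edf) or edf < 0 or edf > len(res.params) + 1:
            return np.inf
        per_param = getattr(res, "edf", None)
        if per_param is not None and (np.min(per_param) < -0.5
                                      or np.max(per_param) > 1.5):
            return np.inf
        fam = Tweedie(var_power=float(power))
        with np.errstate(all="ignore"):
            ll = fam.loglike(self.endog, res.fittedvalues, scale=res.scale)
        if not np.isfinite(ll):
            return np.inf
        return float(-2.0 * ll + 2.0 * (edf + 2.0))

    def fit(self, power: float | None = None, alpha=None,
            power_grid=DEFAULT_POWER_GRID, alpha_grid=DEFAULT_ALPHA_GRID,
            select_passes: int = 2) -> "DensityGAMResults":
        """Fit the model, selecting smoothing weights and (optionally) power.

        ``power=None`` profiles the Tweedie power over ``power_grid``;
        ``alpha=None`` runs coordinate-wise grid search per smooth.
        Passing explicit values skips the corresponding search.
        """
        n_smooth = len(self.spec.smooths)
        select_alpha = alpha is None and n_smooth > 0
        alpha = list(alpha) if alpha is not None else [1.0] * n_smooth
        select_power = power is None

        p = 1.5 if select_power else float(power)
        best = self._fit_once(p, alpha)

        if select_power:
            scores = []
            for pg in power_grid:
                try:
                    r = self._fit_once(pg, alpha)
                    scores.append((self._criterion(r, pg), pg, r))
                except Exception:  # non-convergence at extreme powers
                    continue
            if not scores:
                raise RuntimeError("Tweedie power profiling failed to converge")
            _, p, best = min(scores, key=lambda t: t[0])

        if select_alpha:
            crit = self._criterion(best, p)
            for _ in range(select_passes):
                for j in range(n_smooth):
                    for a in alpha_grid:
                        trial = list(alpha)
                        trial[j] = a
                        try:
                            r = self._fit_once(p, trial)
                        except Exception:
                            continue
                        c = self._criterion(r, p)
                        if c < crit - 1e-9:
                            crit, alpha, best = c, trial, r
        if select_power and select_alpha:
            # re-profile power once at the selected smoothing
            scores = []
            for pg in power_grid:
                try:
                    r = self._fit_once(pg, alpha)
                    scores.append((self._criterion(r, pg), pg, r))
                except Exception:
                    continue
            _, p, best = min(scores, key=lambda t: t[0])

        converged = bool(getattr(best, "converged", True))
        if not converged:
            warnings.warn(f"model {self.spec.label()}: IRLS did not converge")
        return DensityGAMResults(self, best, float(p), list(alpha), converged)


class DensityGAMResults:
    """Fitted Tweedie density GAM: estimates, uncertainty, prediction."""

    def __init__(self, model: DensityGAM, res, power: float, alpha: list,
                 converged: bool):
        self.model = model
        self._res = res
        self.power = power
        self.alpha = alpha
        self.converged = converged
        self.params = np.asarray(res.params)
        self.scale = float(res.scale)
        self.edf_total = model._edf(res)
        self.aic = model._criterion(res, power)
        self.aic_definition = (
            "conditional AIC: -2*loglik(Tweedie series density at fitted "
            "values, Pearson scale) + 2*(total edf + 2)"
        )
        self.fittedvalues = np.asarray(res.fittedvalues)
        self.nobs = len(model.endog)

    # -- deviance ------------------------------------------------------
    @property
    def deviance(self) -> float:
        fam = Tweedie(var_power=self.power)
        return float(fam.deviance(self.model.endog, self.fittedvalues))

    @property
    def null_deviance(self) -> float:
        fam = Tweedie(var_power=self.power)
        import statsmodels.api as sm

        null = sm.GLM(self.model.endog, np.ones((self.nobs, 1)), family=fam,
                      offset=self.model.offset).fit()
        return float(fam.deviance(self.model.endog, null.fittedvalues))

    @property
    def deviance_explained(self) -> float:
        """Percent deviance explained, 100 (1 - D_model / D_null)."""
        d0 = self.null_deviance
        return 100.0 * (1.0 - self.deviance / d0) if d0 > 0 else 0.0

    def cov_params(self) -> np.ndarray:
        return np.asarray(self._res.cov_params())

    @property
    def smooth_edf(self) -> dict:
        """Effective degrees of freedom per smooth term."""
        edf = getattr(self._res, "edf", None)
        out = {}
        if edf is None or self.model.smoother is None:
            return out
        k0 = self.model.exog.shape[1]
        for j, name in enumerate(self.model.spec.smooths):
            dim = self.model.smoother.smoothers[j].dim_basis
            out[name] = float(np.sum(edf[k0:k0 + dim]))
            k0 += dim
        return out

    # -- design construction for new data ------------------------------
    def _design(self, newdata: pd.DataFrame):
        m = self.model
        cols = [np.ones(len(newdata))]
        for f in m.spec.factors:
            for lev in m.factor_levels[f][1:]:
                cols.append((newdata[f].astype(str) == lev).to_numpy(float))
        exog = np.column_stack(cols)
        extrapolated = np.zeros(len(newdata), dtype=bool)
        if m.smoother is not None:
            x = newdata[list(m.spec.smooths)].to_numpy(float).copy()
            for j, (lo, hi) in enumerate(m.smooth_ranges):
                guard_lo, guard_hi = lo, hi
                out = (x[:, j] < guard_lo) | (x[:, j] > guard_hi)
                extrapolated |= out
                x[:, j] = np.clip(x[:, j], lo, hi)
            basis = m.smoother.transform(x)
            if basis.ndim == 1:
                basis = basis[:, None]
            design = np.column_stack([exog, basis])
        else:
            design = exog
        return design, extrapolated

    def linear_predictor(self, newdata: pd.DataFrame,
                         params: np.ndarray | None = None) -> np.ndarray:
        """eta without offset at new covariates (clipped to fitted range)."""
        design, _ = self._design(newdata)
        beta = self.params if params is None else np.asarray(params)
        return design @ beta.T if beta.ndim == 2 else design @ beta

    def predict(self, newdata: pd.DataFrame, soak_area) -> pd.DataFrame:
        """Expected counts ``soak_area * exp(eta)`` with delta-method SE.

        Covariates outside the fitted range are clipped to it and the
        row flagged ``extrapolated``.
        """
        design, extrap = self._design(newdata)
        soak = np.broadcast_to(np.asarray(soak_area, float), (len(newdata),))
        eta = design @ self.params
        mu = soak * np.exp(eta)
        v = self.cov_params()
        se_eta = np.sqrt(np.einsum("ij,jk,ik->i", design, v, design))
        return pd.DataFrame({
            "mu": mu, "se": mu * se_eta, "eta": eta,
            "extrapolated": extrap,
        })

    # -- posterior simulation ------------------------------------------
    def _penalty_matrix(self) -> np.ndarray:
        m = self.model
        npar = len(self.params)
        S = np.zeros((npar, npar))
        if m.smoother is None:
            return S
        k0 = m.exog.shape[1]
        for j, a in enumerate(self.alpha):
            sm_j = m.smoother.smoothers[j]
            pen = sm_j.cov_der2 if hasattr(sm_j, "cov_der2") else None
            if pen is None:
                continue
            dim = sm_j.dim_basis
            S[k0:k0 + dim, k0:k0 + dim] = a * np.asarray(pen)
            k0 += dim
        return S

    def _penalized_loglike(self, beta: np.ndarray, S: np.ndarray) -> float:
        m = self.model
        eta = m.exog @ beta[: m.exog.shape[1]]
        if m.smoother is not None:
            eta = eta + m.smoother.basis @ beta[m.exog.shape[1]:]
        mu = np.exp(eta + m.offset)
        fam = Tweedie(var_power=self.power)
        with np.errstate(all="ignore"):
            ll = fam.loglike(m.endog, mu, scale=self.scale)
        if not np.isfinite(ll):
            return -np.inf
        return float(ll - 0.5 * beta @ S @ beta / self.scale)

    def sample_posterior(self, n: int = 1000, seed=0,
                         sampler: str = "mh", burn: int = 200,
                         thin: int = 2, rw_scale: float = 0.25,
                         t_df: float = 40.0) -> np.ndarray:
        """Draw coefficient vectors from the fitted model's posterior.

        ``sampler='gaussian'`` draws from N(beta_hat, V_hat).  The
        default Metropolis-Hastings chain targets the penalized
        likelihood, alternating independence proposals from a
        multivariate t centred at beta_hat with random-walk steps, in
        the spirit of posterior simulation for penalized GAMs.
        """
        rng = rng_from_seed(seed)
        V = self.cov_params()
        # symmetrize + nearest-PD repair if needed
        V = 0.5 * (V + V.T)
        w, Q = np.linalg.eigh(V)
        if np.any(w <= 0):
            log.warning("covariance not PD; clipping %d eigenvalues", int((w <= 0).sum()))
            w = np.clip(w, 1e-10 * w.max(), None)
            V = (Q * w) @ Q.T
        L = np.linalg.cholesky(V)
        beta_hat = self.params
        npar = len(beta_hat)
        if sampler == "gaussian":
            z = rng.standard_normal((n, npar))
            return beta_hat + z @ L.T
        if sampler != "mh":
            raise ValueError(f"unknown sampler {sampler!r}")

        S = self._penalty_matrix()
        Vinv = np.linalg.inv(V)
        _, logdetV = np.linalg.slogdet(V)

        def t_logpdf(b):
            d = b - beta_hat
            q = d @ Vinv @ d
            return -0.5 * (t_df + npar) * np.log1p(q / t_df) - 0.5 * logdetV

        def t_draw():
            z = L @ rng.standard_normal(npar)
            g = rng.chisquare(t_df) / t_df
            return beta_hat + z / np.sqrt(g)

        beta = beta_hat.copy()
        lp = self._penalized_loglike(beta, S)
        draws = np.empty((n, npar))
        total = burn + n * thin
        accept = 0
        kept = 0
        for it in range(total):
            if it % 2 == 0:  # independence t proposal
                prop = t_draw()
                lp_prop = self._penalized_loglike(prop, S)
                log_ratio = (lp_prop - lp) + (t_logpdf(beta) - t_logpdf(prop))
            else:  # random walk
                prop = beta + rw_scale * (L @ rng.standard_normal(npar))
                lp_prop = self._penalized_loglike(prop, S)
                log_ratio = lp_prop - lp
            if np.log(rng.random()) < log_ratio:
                beta, lp = prop, lp_prop
                accept += 1
            if it >= burn and (it - burn) % thin == 0:
                draws[kept] = beta
                kept += 1
        log.info("MH acceptance rate %.2f", accept / total)
        return draws

    # -- reporting ------------------------------------------------------
    def partial_effect(self, name: str, x: np.ndarray,
                       center: bool = True) -> np.ndarray:
        """Fitted smooth contribution s_name(x), optionally mean-centred."""
        m = self.model
        if name not in m.spec.smooths:
            raise ValueError(f"{name!r} is not a smooth term in this model")
        j = list(m.spec.smooths).index(name)
        lo, hi = m.smooth_ranges[j]
        xq = np.clip(np.asarray(x, float), lo, hi)
        k0 = m.exog.shape[1] + sum(m.smoother.smoothers[jj].dim_basis
                                   for jj in range(j))
        sm_j = m.smoother.smoothers[j]
        basis = sm_j.transform(xq)
        contrib = basis @ self.params[k0:k0 + sm_j.dim_basis]
        return contrib - contrib.mean() if center else contrib

    def summary(self) -> str:
        m = self.model
        lines = [
            "Tweedie density GAM",
            "=" * 64,
            f"formula: {m.response} ~ {m.spec.label()} + offset(log {m.offset_col})",
            f"family: Tweedie(p={self.power:.2f})  scale={self.scale:.4f}",
            f"n={self.nobs}  dropped (incomplete)={m.n_dropped}",
            "",
            "Parametric coefficients:",
            f"{'term':<22}{'estimate':>12}{'SE':>10}{'t':>9}{'p':>9}",
        ]
        se = np.sqrt(np.diag(self.cov_params()))
        npar = m.exog.shape[1]
        for i in range(npar):
            b, s = self.params[i], se[i]
            t = b / s if s > 0 else np.nan
            pval = 2 * stats.t.sf(abs(t), self.nobs - self.edf_total)
            lines.append(f"{m.exog_names[i]:<22}{b:>12.4f}{s:>10.4f}{t:>9.3f}{pval:>9.4f}")
        if self.smooth_edf:
            lines += ["", "Smooth terms (edf):"]
            for name, e in self.smooth_edf.items():
                lines.append(f"  s({name:<14}) edf = {e:6.3f}")
        lines += [
            "",
            f"AIC = {self.aic:.2f}   deviance explained = {self.deviance_explained:.1f}%",
            f"total edf = {self.edf_total:.2f}   converged = {self.converged}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Versioned serializable snapshot of the fit."""
        return {
            "version": 1,
            "spec": {"smooths": list(self.model.spec.smooths),
                     "factors": list(self.model.spec.factors)},
            "k": self.model.k,
            "params": self.params.tolist(),
            "alpha": list(map(float, self.alpha)),
            "power": self.power,
            "scale": self.scale,
            "aic": self.aic,
            "aic_definition": self.aic_definition,
            "edf_total": self.edf_total,
            "smooth_edf": self.smooth_edf,
            "deviance_explained": self.deviance_explained,
            "n": self.nobs,
            "converged": self.converged,
        }
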