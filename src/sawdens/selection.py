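"""All-subsets model enumeration with a collinearity filter, and AIC/AUC
selection among the fitted candidates.

Candidate covariates are toggled on and off in every combination (2^k
subsets for k toggleable covariates; with the default 10 toggleable
terms that is 1024 model specifications).  Specs containing a pair of
covariates with Pearson |rho| > 0.7 on the fitting data are discarded.
The best model is chosen AIC-first: every fit within two AIC points of
the minimum is competitive, and the winner among those is the one with
the highest cross-validated AUC (ties broken by parsimony, then AIC).
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .model import DensityGAM, DensityGAMResults, ModelSpec

log = logging.getLogger(__name__)

DEFAULT_ALWAYS_INCLUDE = ("year", "developed_sl")


def correlation_filter(data: pd.DataFrame, candidates,
                       threshold: float = 0.7) -> set[frozenset]:
    """Pairs of candidates with |Pearson rho| > threshold (complete cases)."""
    numeric = {}
    for c in candidates:
        col = data[c]
        if col.dtype == object or str(col.dtype).startswith("category"):
            codes, _ = pd.factorize(col)
            numeric[c] = pd.Series(codes, index=data.index, dtype=float)
        else:
            numeric[c] = col.astype(float)
    bad = set()
    for a, b in itertools.combinations(candidates, 2):
        pair = pd.concat([numeric[a], numeric[b]], axis=1).dropna()
        if len(pair) < 3:
            continue
        rho = pair.corr().iloc[0, 1]
        if np.isfinite(rho) and abs(rho) > threshold:
            bad.add(frozenset((a, b)))
    return bad


def enumerate_specs(
    candidates,
    data: pd.DataFrame,
    always_include=DEFAULT_ALWAYS_INCLUDE,
    cor_threshold: float = 0.7,
    return_counts: bool = False,
):
    """All subsets of the toggleable candidates, collinearity-filtered.

    ``always_include`` covariates appear in every spec and are not
    toggled.  Constant covariates are dropped from the candidate list
    with a warning.  Returns the surviving list of :class:`ModelSpec`
    (and, optionally, the subset count before filtering).
    """
    candidates = [c for c in candidates if c not in always_include]
    keep = []
    for c in candidates:
        if data[c].nunique(dropna=True) <= 1:
            warnings.warn(f"constant covariate {c!r} dropped from candidates")
        else:
            keep.append(c)
    candidates = keep
    n_subsets = 2 ** len(candidates)
    bad_pairs = correlation_filter(
        data, list(candidates) + list(always_include), cor_threshold)
    specs = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            names = set(combo) | set(always_include)
            if any(pair <= names for pair in bad_pairs):
                continue
            specs.append(ModelSpec.from_covariates(sorted(names)))
    log.info("%d subsets enumerated, %d survive the |rho|>%.2f filter",
             n_subsets, len(specs), cor_threshold)
    if return_counts:
        return specs, n_subsets
    return specs


def fit_all(specs, data: pd.DataFrame, k: int = 10, power: float | None = None,
            alpha=None, **fit_kwargs) -> list[DensityGAMResults]:
    """Fit every spec; non-convergent fits are excluded with a warning."""
    fits = []
    for spec in specs:
        try:
            res = DensityGAM(data, spec, k=k).fit(power=power, alpha=alpha,
                                                  **fit_kwargs)
        except Exception as exc:
            warnings.warn(f"model {spec.label()} failed: {exc}")
            continue
        if not res.converged or not np.isfinite(res.aic):
            warnings.warn(f"model {spec.label()} did not converge; excluded")
            continue
        fits.append(res)
    return fits


def select_best(fits, data: pd.DataFrame, cv_k: int = 10, seed: int = 0,
                aic_window: float = 2.0):
    """AIC short-list then highest cross-validated AUC.

    Returns ``(best, near_best)`` where ``near_best`` is the list of
    fits within ``aic_window`` AIC points of the minimum, ordered as
    supplied.  Ties in AUC go to the model with fewer covariates, then
    lower AIC.
    """
    from .validate import cross_validate

    fits = [f for f in fits if np.isfinite(f.aic)]
    if not fits:
        raise ValueError("no converged fits to select from")
    aic_min = min(f.aic for f in fits)
    near_best = [f for f in fits if f.aic <= aic_min + aic_window]
    if len(near_best) == 1:
        return near_best[0], near_best
    scored = []
    for f in near_best:
        try:
            report = cross_validate(f.model.spec, data, k=cv_k, seed=seed,
                                    power=f.power, alpha=f.alpha,
                                    model_k=f.model.k)
            auc = report.auc_mean
        except Exception as exc:
            warnings.warn(f"CV failed for {f.model.spec.label()}: {exc}")
            auc = -np.inf
        scored.append((auc, -len(f.model.spec.covariates), -f.aic, f))
    scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    return scored[0][3], near_best
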