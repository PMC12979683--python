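"""Internal cross-validation and external validation against sightings.

Internal: k-fold cross-validation (folds stratified on presence/absence
so each fold holds positives when possible) reporting per-fold RMSE on
counts and AUC of held-out predictions against the binary catch
outcome.  The ROC is built from the full ranking of held-out
predictions; the median prediction of the training fold additionally
defines an operating threshold whose sensitivity/specificity are
reported alongside.

External: model predictions at independent sighting locations are
divided by the domain-wide daily median prediction over valid water
depths (0-3 m) and centred by subtracting one.  Scores above zero mean
the model ranks sighting locations above the typical available cell; the
proportion above zero and a one-sample t-test of the mean score against
zero quantify consistency.  Because the score is a ratio, it is
invariant to rescaling all predictions by a positive constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .model import DensityGAM, DensityGAMResults, ModelSpec

log = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Per-fold cross-validation metrics with summary statistics."""

    rmse: list = field(default_factory=list)
    auc: list = field(default_factory=list)
    threshold_sensitivity: list = field(default_factory=list)
    threshold_specificity: list = field(default_factory=list)

    @property
    def rmse_mean(self):
        return float(np.mean(self.rmse))

    @property
    def rmse_sd(self):
        return float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0

    @property
    def auc_mean(self):
        return float(np.mean(self.auc)) if self.auc else float("nan")

    @property
    def auc_sd(self):
        return float(np.std(self.auc, ddof=1)) if len(self.auc) > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "rmse_mean": self.rmse_mean, "rmse_sd": self.rmse_sd,
            "auc_mean": self.auc_mean, "auc_sd": self.auc_sd,
            "rmse_range": [float(np.min(self.rmse)), float(np.max(self.rmse))],
            "auc_range": [float(np.min(self.auc)), float(np.max(self.auc))]
            if self.auc else None,
            "n_folds": len(self.rmse),
            "threshold_sensitivity": self.threshold_sensitivity,
            "threshold_specificity": self.threshold_specificity,
        }


def cross_validate(
    spec: ModelSpec,
    data: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    power: float | None = None,
    alpha=None,
    model_k: int = 10,
    response: str = "n_caught",
    offset: str = "effort_yard_min",
) -> CVReport:
    """k-fold CV of the density model; deterministic given (data, seed).

    Smoothing weights and Tweedie power are held at the supplied values
    (typically those selected on the full data) so folds evaluate the
    chosen model structure rather than re-running selection.
    """
    used = [response, offset, *spec.covariates]
    df = data[used].dropna().reset_index(drop=True)
    presence = (df[response] > 0).to_numpy()
    if presence.sum() >= k and (~presence).sum() >= k:
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
        split = folds.split(df, presence)
    else:
        folds = KFold(n_splits=k, shuffle=True, random_state=int(seed))
        split = folds.split(df)
    report = CVReport()
    for train_idx, test_idx in split:
        train, test = df.iloc[train_idx], df.iloc[test_idx]
        res = DensityGAM(train, spec, response=response, offset=offset,
                         k=model_k).fit(power=power, alpha=alpha)
        pred_test = res.predict(test, test[offset].to_numpy())["mu"].to_numpy()
        y_test = test[response].to_numpy()
        report.rmse.append(float(np.sqrt(np.mean((pred_test - y_test) ** 2))))
        pos = y_test > 0
        if pos.any() and (~pos).any():
            report.auc.append(float(roc_auc_score(pos, pred_test)))
            thr = float(np.median(res.predict(
                train, train[offset].to_numpy())["mu"]))
            above = pred_test > thr
            report.threshold_sensitivity.append(float(above[pos].mean()))
            report.threshold_specificity.append(float((~above[~pos]).mean()))
        else:
            warnings.warn("fold without positives: AUC undefined, excluded")
    return report


@dataclass
class ExternalReport:
    """Sighting-consistency statistics for one sighting set."""

    scores: np.ndarray
    proportion_above_zero: float
    t_statistic: float
    df: int
    p_value: float
    mean: float
    ci95: tuple
    n_skipped: int = 0

    def as_dict(self) -> dict:
        return {
            "n": int(len(self.scores)),
            "proportion_above_zero": self.proportion_above_zero,
            "t": self.t_statistic, "df": self.df, "p": self.p_value,
            "mean": self.mean, "ci95": list(self.ci95),
            "n_skipped": self.n_skipped,
        }


def external_validate(
    result: DensityGAMResults,
    sightings: pd.DataFrame,
    cells: pd.DataFrame,
    env,
    depth_range=(0.0, 3.0),
    zscore_mode: str = "ratio",
) -> ExternalReport:
    """Score independent sightings against domain-wide daily predictions.

    For sighting i on day d the score is
    ``pred(x_i, d) / median_over_valid_cells(pred(., d)) - 1``
    (``zscore_mode='ratio'``), or the per-day Z-score of log predictions
    (``zscore_mode='zlog'``) as a sensitivity alternative.  Sightings on
    days whose domain median is zero are skipped.
    """
    lo, hi = depth_range
    valid = cells[(cells["depth_min_m"] >= lo) & (cells["depth_min_m"] <= hi)]
    if valid.empty:
        raise ValueError("no valid-depth cells in the domain")
    cell_pos = {int(c): i for i, c in enumerate(valid.index)}
    scores = []
    n_skipped = 0
    for date, group in sightings.groupby("date"):
        f = env.fields(date)
        frame = valid.copy()
        for v in ("avg_temp", "avg_do", "avg_salin", "avg_ph"):
            frame[v] = f.loc[valid.index, v].to_numpy()
        frame["year"] = pd.Timestamp(date).year
        from .survey import assign_season

        frame["season"] = assign_season(date)
        eta = result.linear_predictor(frame.reset_index(drop=True))
        pred = np.exp(eta)
        if zscore_mode == "zlog":
            z = (eta - eta.mean()) / max(eta.std(), 1e-12)
            day_scores = {c: z[i] for c, i in cell_pos.items()}
            med = 1.0
        else:
            med = float(np.median(pred))
            if med <= 0:
                log.warning("%s: zero daily median prediction; skipped", date)
                n_skipped += len(group)
                continue
            day_scores = {c: pred[i] / med - 1.0 for c, i in cell_pos.items()}
        for cell in group["cell"]:
            if int(cell) in day_scores:
                scores.append(day_scores[int(cell)])
            else:
                n_skipped += 1  # sighting outside the valid-depth domain
    scores = np.asarray(scores, float)
    if len(scores) < 2:
        raise ValueError("fewer than two scored sightings")
    t_res = stats.ttest_1samp(scores, 0.0)
    ci = t_res.confidence_interval(0.95)
    return ExternalReport(
        scores=scores,
        proportion_above_zero=float((scores > 0).mean()),
        t_statistic=float(t_res.statistic),
        df=len(scores) - 1,
        p_value=float(t_res.pvalue),
        mean=float(scores.mean()),
        ci95=(float(ci.low), float(ci.high)),
        n_skipped=n_skipped,
    )
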