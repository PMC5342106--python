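"""Subnetwork risk scores (snRS) and survival stratification.

The final predictive model of a subnetwork keeps the features selected
more than ``stability_min_count`` times across the Monte-Carlo splits,
weights them by their coefficients from an unpenalized multivariable Cox
fit on the full cohort, and scores each patient by the linear combination
(snRS).  Patients are split at the median snRS into high/low risk groups
compared by Kaplan-Meier curves, the log-rank test, and Cox hazard
ratios, optionally adjusted for clinical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Stability-selected features with multivariable Cox weights."""

    subnetwork_id: str
    features: list[str]
    coefficients: dict[str, float]
    penalizer_used: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("coefficients must be finite")


@dataclass
class RiskStratification:
    """Median-split risk groups with KM, log-rank and HR summaries."""

    scores: pd.Series
    group: pd.Series  # "high" / "low"
    cutoff: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    km_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def stability_select(counts: dict[str, int], min_count: int) -> set[str]:
    """Features selected strictly more than ``min_count`` times across splits."""
    return {f for f, c in counts.items() if c > min_count}


def fit_final_model(
    features: list[str],
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    subnetwork_id: str = "",
) -> RiskModel:
    """Unpenalized multivariable Cox on the stability-selected features.

    On non-convergence or collinearity the fit falls back to a small ridge
    penalty (escalating 0.01 -> 0.1), logged.
    """
    if not features:
        raise ValueError("no features to fit")
    n_events = int(np.asarray(event).sum())
    if n_events < len(features) + 2:
        raise ValueError(f"too few events ({n_events}) for {len(features)} features")
    df = X[list(features)].copy()
    df["_time"], df["_event"] = np.asarray(time, float), np.asarray(event, int)
    for pen in (0.0, 0.01, 0.1):
        try:
            with np.errstate(all="ignore"):
                cph = CoxPHFitter(penalizer=pen)
                cph.fit(df, "_time", "_event")
            params = cph.params_
            if not np.isfinite(params.to_numpy()).all() or np.abs(params.to_numpy()).max() > 50:
                raise ConvergenceError("diverged coefficients")
            if pen > 0:
                logger.warning("final model %s: ridge fallback penalizer=%g", subnetwork_id, pen)
            return RiskModel(
                subnetwork_id=subnetwork_id,
                features=list(features),
                coefficients={f: float(params[f]) for f in features},
                penalizer_used=pen,
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            last = exc
            continue
    raise RuntimeError(f"final model {subnetwork_id}: Cox fit failed even with ridge fallback: {last}")


def snrs(model: RiskModel, X: pd.DataFrame, mrna_only: bool = False) -> pd.Series:
    """Per-patient subnetwork risk score: sum_f coef_f * x_f.

    In ``mrna_only`` mode (external-cohort application) only the mRNA
    features and their original training coefficients are used — no refit,
    no renormalization.  In strict mode every model feature must resolve.
    """
    feats = model.features
    if mrna_only:
        feats = [f for f in feats if "|mrna" in f]
        if not feats:
            raise ValueError("model has no mRNA features for mRNA-only application")
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise KeyError(f"features missing from matrix: {missing}")
    coefs = np.array([model.coefficients[f] for f in feats])
    scores = X[feats].to_numpy(float) @ coefs
    return pd.Series(scores, index=X.index, name="snrs")


def _km_table(time: np.ndarray, event: np.ndarray, label: str) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event, label=label)
    tbl = km.event_table.copy()
    tbl["survival"] = km.survival_function_[label].reindex(tbl.index).to_numpy()
    ci = km.confidence_interval_
    tbl["ci_low"] = ci.iloc[:, 0].reindex(tbl.index).to_numpy()
    tbl["ci_high"] = ci.iloc[:, 1].reindex(tbl.index).to_numpy()
    return tbl.reset_index().rename(columns={"event_at": "time"})


def stratify_median(scores: pd.Series, time: np.ndarray, event: np.ndarray) -> RiskStratification:
    """Median-cutoff high/low risk groups with KM, log-rank and Cox HR.

    Scores above the median are high risk; scores at or below it are low
    risk (deterministic, conservative tie rule).  Identical scores for all
    patients are refused as degenerate.
    """
    s = scores.to_numpy(float)
    if np.ptp(s) == 0:
        raise ValueError("degenerate risk score: all patients identical")
    cutoff = float(np.median(s))
    high = s > cutoff
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split leaves a group with fewer than 2 patients")
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    df = pd.DataFrame({"high": high.astype(int), "_t": time, "_e": event})
    cph = CoxPHFitter().fit(df, "_t", "_e")
    summ = cph.summary.loc["high"]
    return RiskStratification(
        scores=scores,
        group=pd.Series(np.where(high, "high", "low"), index=scores.index, name="group"),
        cutoff=cutoff,
        logrank_p=float(lr.p_value),
        hr=float(summ["exp(coef)"]),
        hr_ci=(float(summ["exp(coef) lower 95%"]), float(summ["exp(coef) upper 95%"])),
        km_tables={
            "high": _km_table(time[high], event[high], "high"),
            "low": _km_table(time[~high], event[~high], "low"),
        },
    )


def clinical_adjustment(
    scores: pd.Series,
    clinical: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
) -> pd.DataFrame:
    """Univariate and multivariable Cox table for snRS + clinical covariates.

    Stage enters dichotomized (III/IV vs I/II); snRS enters continuous.
    Constant covariates are dropped with a log entry.  Returns one row per
    variable with univariate and multivariable HR, 95% CI and p.
    """
    covs = pd.DataFrame(index=clinical.index)
    covs["snRS"] = scores.reindex(clinical.index).to_numpy(float)
    covs["age"] = clinical["age"].to_numpy(float)
    if "stage" in clinical:
        covs["stage_III_IV"] = (clinical["stage"].to_numpy(int) >= 3).astype(float)
    if "lymph_node_count" in clinical:
        covs["lymph_node_count"] = clinical["lymph_node_count"].to_numpy(float)
    if "tumor_weight" in clinical:
        covs["tumor_weight"] = clinical["tumor_weight"].to_numpy(float)

    dropped = [c for c in covs.columns if covs[c].nunique() <= 1]
    for c in dropped:
        logger.warning("clinical adjustment: dropping constant covariate %s", c)
    covs = covs.drop(columns=dropped)

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []

    def _fit(cols: list[str]) -> pd.DataFrame | None:
        df = covs[cols].copy()
        df["_t"], df["_e"] = time, event
        for pen in (0.0, 0.01, 0.1):
            try:
                with np.errstate(all="ignore"):
                    cph = CoxPHFitter(penalizer=pen).fit(df, "_t", "_e")
                if pen > 0:
                    logger.warning("clinical adjustment: ridge fallback (%g) for %s", pen, cols)
                return cph.summary
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                continue
        logger.warning("clinical adjustment: fit failed for %s", cols)
        return None

    uni = {}
    for c in covs.columns:
        summ = _fit([c])
        if summ is not None:
            uni[c] = summ.loc[c]
    multi = _fit(list(covs.columns))

    for c in covs.columns:
        row = {"variable": c}
        if c in uni:
            row.update(
                uni_hr=float(uni[c]["exp(coef)"]),
                uni_ci_low=float(uni[c]["exp(coef) lower 95%"]),
                uni_ci_high=float(uni[c]["exp(coef) upper 95%"]),
                uni_p=float(uni[c]["p"]),
            )
        if multi is not None and c in multi.index:
            row.update(
                multi_hr=float(multi.loc[c, "exp(coef)"]),
                multi_ci_low=float(multi.loc[c, "exp(coef) lower 95%"]),
                multi_ci_high=float(multi.loc[c, "exp(coef) upper 95%"]),
                multi_p=float(multi.loc[c, "p"]),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
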