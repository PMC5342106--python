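"""Prognostic ranking of subnetworks by Monte-Carlo cross-validated C-index.

Each subnetwork's multi-omic profile (the screened-in features of its
member genes) is scored by repeated random 80/20 splits: an elastic-net
penalized Cox model is fitted on the training split, its linear predictor
is applied to the test split, and Harrell's concordance index is recorded.
The median over splits is the subnetwork's predictive value; significance
comes from re-running the whole procedure on survival-permuted data.
A C-index of 1 is perfect ranking, 0.5 is a random guess.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from netprog.config import AnalysisConfig
from netprog.dataset import OmicsDataset
from netprog.discovery import Subnetwork
from netprog.screening import ScreeningResult

logger = logging.getLogger(__name__)


@dataclass
class SubnetworkProfile:
    """Patients x features matrix of one subnetwork's selected features."""

    subnetwork_id: str
    X: pd.DataFrame  # patients x feature keys, z-standardized columns

    @property
    def feature_keys(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class CVResult:
    """Outcome of the Monte-Carlo cross-validation for one profile."""

    c_distribution: np.ndarray
    median_c: float
    selection_counts: dict[str, int]
    splits: list[dict] = field(default_factory=list)
    alphas_used: list[float] = field(default_factory=list)


@dataclass
class PrognosticModel:
    """Ranked subnetwork model: median C, permutation p, pass flag."""

    subnetwork_id: str
    median_c: float
    permutation_p: float
    selection_counts: dict[str, int]
    passed: bool = False

    def __post_init__(self) -> None:
        self.passed = bool(self.median_c > 0.5 and self.permutation_p < 0.05)


def concordance_index(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of a risk score against survival.

    Permissible pairs are those where one patient is known to fail first:
    (i, j) with t_i < t_j and the earlier patient an observed event, or
    tied times where exactly one patient is an event.  A pair counts 1 if
    the earlier-failing patient has the higher predicted risk, 0.5 on tied
    risk, 0 otherwise.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    tied_time = (time[:, None] == time[None, :]) & (event[:, None] == 1) & (event[None, :] == 0)
    permissible = earlier | tied_time
    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no comparable pairs")
    higher = risk[:, None] > risk[None, :]
    tied_risk = risk[:, None] == risk[None, :]
    score = np.where(higher, 1.0, np.where(tied_risk, 0.5, 0.0))
    return float(score[permissible].sum() / n_perm)


def assemble_profile(
    sub: Subnetwork, ds: OmicsDataset, screened: ScreeningResult
) -> SubnetworkProfile:
    """Multi-omic profile of a subnetwork: selected features of its members.

    Methylation must already be collapsed to one probe per gene.  Columns
    are z-standardized; a member gene missing from a modality simply
    contributes no column there (logged).
    """
    sel = screened.selected
    rows = sel[sel["gene"].isin(sub.genes)]
    cols = {}
    for fid, row in rows.iterrows():
        try:
            vals = ds.feature_value(row["gene"], row["modality"], row["probe"] or None)
        except KeyError:
            logger.info("subnetwork %s: feature %s absent from dataset", sub.subnetwork_id, fid)
            continue
        v = vals.to_numpy(float)
        sd = v.std()
        if sd == 0:
            continue
        cols[fid] = (v - v.mean()) / sd
    if not cols:
        raise ValueError(f"subnetwork {sub.subnetwork_id or sorted(sub.genes)} has no usable features")
    X = pd.DataFrame(cols, index=ds.patients)
    return SubnetworkProfile(subnetwork_id=sub.subnetwork_id, X=X)


# ---------------------------------------------------------------------------
# penalized Cox fitting helpers


def _fit_enet_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Elastic-net Cox coefficients, regularization by inner CV or fixed.

    Returns (coefficients, alpha).  With ``cfg.fixed_alpha`` set, a single
    path point is fitted; otherwise the alpha path is scored by
    ``inner_cv_folds``-fold concordance on held-out folds.
    """
    y = Surv.from_arrays(event.astype(bool), time)
    l1 = max(cfg.enet_mix, 1e-6)  # coxnet requires l1_ratio > 0
    if cfg.fixed_alpha is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=[cfg.fixed_alpha])
        with warnings.catch_warnings():
            # an all-zero model at the fixed penalty is a valid outcome
            # (scored as C = 0.5 by the caller)
            warnings.simplefilter("ignore", UserWarning)
            model.fit(X, y)
        return model.coef_[:, 0], float(cfg.fixed_alpha)

    path = CoxnetSurvivalAnalysis(l1_ratio=l1, n_alphas=cfg.n_alphas, alpha_min_ratio=0.05)
    path.fit(X, y)
    alphas = path.alphas_
    n = len(time)
    folds = np.tile(np.arange(cfg.inner_cv_folds), n // cfg.inner_cv_folds + 1)[:n]
    folds = rng.permutation(folds)
    scores = np.zeros((cfg.inner_cv_folds, len(alphas)))
    valid = np.zeros((cfg.inner_cv_folds, len(alphas)), dtype=bool)
    for k in range(cfg.inner_cv_folds):
        tr, va = folds != k, folds == k
        if event[tr].sum() < 2 or event[va].sum() < 1:
            continue
        try:
            m = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=list(alphas))
            m.fit(X[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
        except (ArithmeticError, ValueError):
            continue
        for a_i in range(m.coef_.shape[1]):
            risk = X[va] @ m.coef_[:, a_i]
            try:
                scores[k, a_i] = concordance_index(risk, time[va], event[va])
                valid[k, a_i] = True
            except ValueError:
                continue
    with np.errstate(invalid="ignore"):
        mean_c = np.where(valid.any(axis=0), scores.sum(axis=0) / np.maximum(valid.sum(axis=0), 1), np.nan)
    if np.isnan(mean_c).all():
        best = len(alphas) // 2  # no informative fold: middle of the path
    else:
        best = int(np.nanargmax(mean_c))
    return path.coef_[:, best], float(alphas[best])


def _draw_split(
    n: int, n_events_mask: np.ndarray, train_frac: float, rng: np.random.Generator, max_redraw: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split, redrawn until both sides contain events."""
    n_train = int(round(train_frac * n))
    for _ in range(max_redraw):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if n_events_mask[tr].sum() >= 2 and n_events_mask[te].sum() >= 1:
            return np.sort(tr), np.sort(te)
    raise RuntimeError("could not draw a split with events on both sides")


def monte_carlo_cv(
    profile: SubnetworkProfile,
    time: np.ndarray,
    event: np.ndarray,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
    n_splits: int | None = None,
) -> CVResult:
    """Repeated random-split evaluation of one profile.

    Per split: standardize on train, fit elastic-net Cox, apply the linear
    predictor to the test split, record Harrell's C.  All-zero models
    (nothing selected at the chosen penalty) score C = 0.5, i.e. no
    information.  Selected-feature counts accumulate across splits.
    """
    X_all = profile.X.to_numpy(float)
    keys = profile.feature_keys
    n = len(time)
    n_splits = cfg.n_cv_splits if n_splits is None else n_splits
    ev_mask = np.asarray(event, int) == 1

    cs = np.empty(n_splits)
    counts: dict[str, int] = {k: 0 for k in keys}
    splits_meta, alphas_used = [], []
    for s in range(n_splits):
        tr, te = _draw_split(n, ev_mask, cfg.train_frac, rng)
        mu = X_all[tr].mean(axis=0)
        sd = X_all[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X_all[tr] - mu) / sd, (X_all[te] - mu) / sd
        try:
            coef, alpha = _fit_enet_cox(Xtr, time[tr], event[tr], cfg, rng)
        except (ArithmeticError, ValueError) as exc:
            logger.debug("split %d: penalized fit failed (%s); scoring 0.5", s, exc)
            coef, alpha = np.zeros(X_all.shape[1]), np.nan
        nonzero = np.flatnonzero(coef)
        if nonzero.size == 0:
            cs[s] = 0.5
        else:
            cs[s] = concordance_index(Xte @ coef, time[te], event[te])
            for j in nonzero:
                counts[keys[j]] += 1
        alphas_used.append(alpha)
        splits_meta.append({"train": tr, "test": te, "n_selected": int(nonzero.size), "c": float(cs[s])})
    return CVResult(
        c_distribution=cs,
        median_c=float(np.median(cs)),
        selection_counts=counts,
        splits=splits_meta,
        alphas_used=alphas_used,
    )


def permutation_test(
    profile: SubnetworkProfile,
    time: np.ndarray,
    event: np.ndarray,
    observed_median_c: float,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
) -> float:
    """Survival-permutation p-value for an observed median C-index.

    (time, event) pairs are jointly permuted across patients
    ``cfg.n_permutations`` times; each permutation re-runs the Monte-Carlo
    cross-validation (with ``cfg.perm_cv_splits`` splits) and the add-one
    fraction of permuted median C-indexes >= observed is returned.
    """
    if cfg.n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    exceed = 0
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(len(time))
        res = monte_carlo_cv(profile, time[perm], event[perm], cfg, rng, n_splits=cfg.perm_cv_splits)
        if res.median_c >= observed_median_c:
            exceed += 1
    return (exceed + 1) / (cfg.n_permutations + 1)


def rank_models(models: list[PrognosticModel]) -> list[PrognosticModel]:
    """Descending median C; ties by permutation p then subnetwork id."""
    return sorted(models, key=lambda m: (-m.median_c, m.permutation_p, m.subnetwork_id))


def baseline_molecular_model(
    ds: OmicsDataset,
    screened_all: ScreeningResult,
    modality_set: set[str],
    cfg: AnalysisConfig,
    rng: np.random.Generator,
    n_splits: int | None = None,
) -> CVResult:
    """Genome-wide molecular baseline for one or more modalities.

    Mirrors the subnetwork evaluation but over all features of the given
    modalities, with a univariate pre-selection (LRT p < alpha) performed
    inside each training split to avoid leakage, then an elastic-net Cox
    on the surviving features.  Splits with empty pre-selection score 0.5.
    """
    from netprog.screening import batched_cox_fit, _lrt_p, _null_loglik

    if not modality_set:
        raise ValueError("modality_set must not be empty")
    bad = modality_set - {"mrna", "cnv", "methylation"}
    if bad:
        raise ValueError(f"unknown modalities: {sorted(bad)}")

    stats = screened_all.stats
    rows = stats[(stats["modality"].isin(modality_set)) & (stats["status"] == "ok")]
    mats = []
    for fid, row in rows.iterrows():
        vals = ds.feature_value(row["gene"], row["modality"], row["probe"] or None).to_numpy(float)
        mats.append(vals)
    X_all = np.asarray(mats).T  # patients x features
    keys = list(rows.index)
    time = ds.survival_time.to_numpy(float)
    event = ds.event.to_numpy(int)
    n = len(time)
    n_splits = cfg.n_cv_splits if n_splits is None else n_splits
    ev_mask = event == 1

    cs = np.empty(n_splits)
    counts: dict[str, int] = {k: 0 for k in keys}
    for s in range(n_splits):
        tr, te = _draw_split(n, ev_mask, cfg.train_frac, rng)
        mu, sd = X_all[tr].mean(axis=0), X_all[tr].std(axis=0)
        keep_var = sd > 0
        sd_safe = np.where(keep_var, sd, 1.0)
        Ztr = (X_all[tr] - mu) / sd_safe
        # univariate pre-selection on the training split only
        stack = Ztr.T[keep_var][:, :, None]
        _, _, ll, conv = batched_cox_fit(stack, time[tr], event[tr])
        p = _lrt_p(ll, _null_loglik(None, time[tr], event[tr]))
        sel = np.flatnonzero(keep_var)[conv & (p < cfg.alpha_screen)]
        if sel.size == 0:
            cs[s] = 0.5
            continue
        Xtr = Ztr[:, sel]
        Xte = ((X_all[te] - mu) / sd_safe)[:, sel]
        try:
            coef, _ = _fit_enet_cox(Xtr, time[tr], event[tr], cfg, rng)
        except (ArithmeticError, ValueError):
            coef = np.zeros(sel.size)
        nonzero = np.flatnonzero(coef)
        if nonzero.size == 0:
            cs[s] = 0.5
        else:
            cs[s] = concordance_index(Xte @ coef, time[te], event[te])
            for j in nonzero:
                counts[keys[sel[j]]] += 1
    return CVResult(c_distribution=cs, median_c=float(np.median(cs)), selection_counts=counts)
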