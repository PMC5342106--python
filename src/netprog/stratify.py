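"""Consensus-NMF tumor stratification from pooled subnetwork features.

Stability-selected features of all subnetwork models with median C > 0.5
are pooled (deduplicated), min-max scaled to the non-negative domain, and
factorized ``n_runs`` times by NMF from random initializations.  The
patient co-clustering frequency over runs forms a consensus matrix, cut
by average-linkage hierarchical clustering into k strata whose survival
is compared by log-rank and Cox hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from netprog.dataset import OmicsDataset
from netprog.evaluation import PrognosticModel
from netprog.screening import ScreeningResult

logger = logging.getLogger(__name__)


@dataclass
class StratificationResult:
    """Cluster labels, consensus matrix and between-strata survival stats."""

    labels: pd.Series  # patient -> 1..k
    consensus: pd.DataFrame  # patient x patient co-clustering frequency
    pooled_features: list[str]
    modality_counts: dict[str, int] = field(default_factory=dict)
    logrank_p: float | None = None
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None


def pool_features(
    models: list[PrognosticModel],
    stability_sets: dict[str, set[str]],
    ds: OmicsDataset,
    screened: ScreeningResult,
) -> pd.DataFrame:
    """Union of stability-selected features over models with median C > 0.5.

    Returns a patients x features matrix from the core set; per-modality
    feature counts are logged.
    """
    keep = [m for m in models if m.median_c > 0.5]
    pooled: set[str] = set()
    for m in keep:
        pooled |= stability_sets.get(m.subnetwork_id, set())
    if not pooled:
        raise ValueError("no features to pool: no model with median C > 0.5 has stable features")
    stats = screened.stats
    cols = {}
    counts = {"mrna": 0, "cnv": 0, "methylation": 0}
    for fid in sorted(pooled):
        row = stats.loc[fid]
        cols[fid] = ds.feature_value(row["gene"], row["modality"], row["probe"] or None).to_numpy(float)
        counts[row["modality"]] += 1
    logger.info("pooled %d features for stratification (%s)", len(cols), counts)
    return pd.DataFrame(cols, index=ds.patients)


def nmf_consensus(
    matrix: pd.DataFrame,
    k: int,
    n_runs: int,
    seed: int,
) -> StratificationResult:
    """Consensus NMF clustering of patients into k strata.

    Each pooled feature is min-max scaled to [0, 1] (rank-preserving map
    to the non-negative domain); per run, patients are assigned to their
    dominant factor; the consensus co-clustering frequency is cut by
    average-linkage hierarchical clustering into k groups.
    """
    n, p = matrix.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if k >= min(n, p):
        raise ValueError(f"rank k={k} must be below min(n_patients, n_features)={min(n, p)}")

    X = matrix.to_numpy(float)
    rng_range = np.ptp(X, axis=0)
    rng_range[rng_range == 0] = 1.0
    X = (X - X.min(axis=0)) / rng_range

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6E6D66]))
    consensus = np.zeros((n, n))
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    for _ in range(n_runs):
        state = int(rng.integers(0, 2**31 - 1))
        model = NMF(n_components=k, init="random", random_state=state, max_iter=500, tol=1e-5)
        with warnings.catch_warnings():
            # random restarts are summarized by the consensus; exact per-run
            # convergence is not required
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        labels = W.argmax(axis=1)
        consensus += labels[:, None] == labels[None, :]
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)

    dist = squareform(1.0 - consensus, checks=False)
    final = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
    return StratificationResult(
        labels=pd.Series(final, index=matrix.index, name="cluster"),
        consensus=pd.DataFrame(consensus, index=matrix.index, columns=matrix.index),
        pooled_features=list(matrix.columns),
    )


def compare_strata(
    labels: pd.Series, time: np.ndarray, event: np.ndarray
) -> tuple[float, float, tuple[float, float]]:
    """Log-rank p across strata and HR (95% CI) of cluster 1 vs cluster 2.

    With more than two clusters the HR contrasts the largest cluster
    against the rest pooled.  Each cluster needs >= 2 patients and the
    cohort >= 1 event per compared group.
    """
    lab = labels.to_numpy()
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters to compare")
    if counts.min() < 2:
        raise ValueError("every cluster needs at least 2 patients")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lr = multivariate_logrank_test(time, lab, event)

    ref = uniq[np.argmax(counts)] if len(uniq) > 2 else uniq[0]
    indicator = (lab == ref).astype(int)
    df = pd.DataFrame({"c1": indicator, "_t": time, "_e": event})
    cph = CoxPHFitter().fit(df, "_t", "_e")
    summ = cph.summary.loc["c1"]
    return (
        float(lr.p_value),
        float(summ["exp(coef)"]),
        (float(summ["exp(coef) lower 95%"]), float(summ["exp(coef) upper 95%"])),
    )
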