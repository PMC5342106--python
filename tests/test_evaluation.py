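import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as lifelines_cindex

from conftest import brute_force_cindex
from netprog.config import AnalysisConfig
from netprog.evaluation import (
    assemble_profile,
    baseline_molecular_model,
    concordance_index,
    monte_carlo_cv,
    permutation_test,
    PrognosticModel,
    rank_models,
    SubnetworkProfile,
)
from netprog.discovery import Subnetwork
from netprog.screening import collapse_methylation, screen_features


def test_perfect_and_reversed_risk():
    rng = np.random.default_rng(0)
    t = rng.uniform(1, 100, 50)
    e = np.ones(50, dtype=int)
    assert concordance_index(-t, t, e) == 1.0
    assert concordance_index(t, t, e) == 0.0


def test_worked_four_patient_example():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, dtype=int)
    risk = np.array([10.0, 9.0, 1.0, 2.0])
    assert concordance_index(risk, t, e) == pytest.approx(5 / 6)


def test_no_comparable_pairs_rejected():
    with pytest.raises(ValueError, match="comparable"):
        concordance_index(np.r_[1.0, 2.0], np.r_[5.0, 5.0], np.r_[0, 0])


def test_complement_symmetry_without_risk_ties():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(4, 30))
        t = rng.uniform(1, 50, n)
        e = (rng.random(n) < 0.7).astype(int)
        r = rng.normal(size=n)
        if e.sum() == 0:
            continue
        assert concordance_index(r, t, e) + concordance_index(-r, t, e) == pytest.approx(1.0)


def test_matches_brute_force_enumeration_with_censoring_and_ties():
    rng = np.random.default_rng(2)
    for _ in range(60):
        n = int(rng.integers(3, 9))
        t = rng.integers(1, 5, n).astype(float)  # force time ties
        e = rng.integers(0, 2, n)
        r = np.round(rng.normal(size=n), 1)  # occasional risk ties
        if not ((e == 1) & (t < t.max())).any():
            continue
        try:
            expected = brute_force_cindex(r, t, e)
        except ValueError:
            continue
        assert concordance_index(r, t, e) == pytest.approx(expected)


def test_matches_lifelines_on_tie_free_data():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = 40
        t = rng.uniform(1, 100, n)
        e = (rng.random(n) < 0.6).astype(int)
        r = rng.normal(size=n)
        # lifelines orders by predicted survival (higher = longer): pass -risk
        assert concordance_index(r, t, e) == pytest.approx(lifelines_cindex(t, -r, e))


def _noise_profile(rng, n=200, p=6, label="sub1"):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     index=[f"P{i}" for i in range(n)],
                     columns=[f"G{j}|mrna" for j in range(p)])
    return SubnetworkProfile(subnetwork_id=label, X=X)


def _survival(rng, n=200, eta=None, censor=0.25):
    eta = np.zeros(n) if eta is None else eta
    t = 30 * (-np.log(rng.uniform(size=n)) * np.exp(-eta)) ** (1 / 1.2)
    e = (rng.random(n) > censor).astype(int)
    return t, e


def test_null_profile_has_chance_level_median_c(fast_cfg):
    rng = np.random.default_rng(4)
    profile = _noise_profile(rng)
    t, e = _survival(rng)
    res = monte_carlo_cv(profile, t, e, fast_cfg, np.random.default_rng(5))
    assert 0.40 <= res.median_c <= 0.60
    assert len(res.c_distribution) == fast_cfg.n_cv_splits
    assert res.median_c == np.median(res.c_distribution)


def test_planted_feature_lifts_median_c(fast_cfg):
    rng = np.random.default_rng(6)
    profile = _noise_profile(rng, n=300)
    eta = 1.0 * profile.X.iloc[:, 0].to_numpy()
    t, e = _survival(rng, n=300, eta=eta)
    res = monte_carlo_cv(profile, t, e, fast_cfg, np.random.default_rng(7))
    assert res.median_c > 0.6
    assert res.selection_counts["G0|mrna"] >= 0.9 * fast_cfg.n_cv_splits


def test_monte_carlo_cv_deterministic(fast_cfg):
    rng = np.random.default_rng(8)
    profile = _noise_profile(rng)
    t, e = _survival(rng)
    a = monte_carlo_cv(profile, t, e, fast_cfg, np.random.default_rng(9))
    b = monte_carlo_cv(profile, t, e, fast_cfg, np.random.default_rng(9))
    np.testing.assert_array_equal(a.c_distribution, b.c_distribution)
    assert a.selection_counts == b.selection_counts


def test_permutation_boundary_p_is_one(fast_cfg):
    rng = np.random.default_rng(10)
    profile = _noise_profile(rng, n=100)
    t, e = _survival(rng, n=100)
    # an observed median below every permuted value gives the maximal p of 1
    p = permutation_test(profile, t, e, observed_median_c=0.0, cfg=fast_cfg,
                         rng=np.random.default_rng(11))
    assert p == 1.0


def test_permutation_detects_planted_signal(fast_cfg):
    rng = np.random.default_rng(12)
    profile = _noise_profile(rng, n=250)
    eta = 1.2 * profile.X.iloc[:, 0].to_numpy()
    t, e = _survival(rng, n=250, eta=eta)
    obs = monte_carlo_cv(profile, t, e, fast_cfg, np.random.default_rng(13))
    p = permutation_test(profile, t, e, obs.median_c, fast_cfg, np.random.default_rng(14))
    assert p <= 0.05


def test_rank_models_ordering_and_pass_flag():
    models = [
        PrognosticModel("a", 0.6, 0.30, {}),
        PrognosticModel("b", 0.7, 0.01, {}),
        PrognosticModel("c", 0.6, 0.02, {}),
        PrognosticModel("d", 0.45, 0.01, {}),
    ]
    ranked = rank_models(models)
    assert [m.subnetwork_id for m in ranked] == ["b", "c", "a", "d"]
    assert [m.passed for m in ranked] == [True, True, False, False]


def test_assemble_profile_bounds_and_gene_restriction(planted_cohort):
    _, _, truth, ds = planted_cohort
    screened = collapse_methylation(screen_features(ds, AnalysisConfig(seed=1)), ds.probe_map)
    genes = frozenset(list(truth.module_members[0])[:4])
    sub = Subnetwork(genes=genes, induced_edges=[], subnetwork_id="s1")
    profile = assemble_profile(sub, ds, screened)
    assert profile.X.shape[1] <= 12  # at most 3 modalities x 4 genes
    assert all(screened.stats.loc[c, "gene"] in genes for c in profile.X.columns)
    assert list(profile.X.index) == ds.patients
    np.testing.assert_allclose(profile.X.std(axis=0, ddof=0), 1.0, atol=1e-9)


def test_profile_depends_only_on_gene_set(planted_cohort):
    _, _, truth, ds = planted_cohort
    screened = collapse_methylation(screen_features(ds, AnalysisConfig(seed=1)), ds.probe_map)
    genes = frozenset(list(truth.module_members[0])[:4])
    a = assemble_profile(Subnetwork(genes=genes, induced_edges=[], network_label="x"), ds, screened)
    b = assemble_profile(Subnetwork(genes=genes, induced_edges=[], network_label="y"), ds, screened)
    pd.testing.assert_frame_equal(a.X, b.X)


def test_assemble_profile_without_features_errors(null_cohort):
    _, _, _, ds = null_cohort
    screened = collapse_methylation(screen_features(ds, AnalysisConfig(seed=1)), ds.probe_map)
    # pick genes with no selected features
    sel_genes = set(screened.selected["gene"])
    cold = [g for g in ds.mrna.index if g not in sel_genes][:4]
    with pytest.raises(ValueError, match="no usable features"):
        assemble_profile(Subnetwork(genes=frozenset(cold), induced_edges=[]), ds, screened)


def test_baseline_guards_and_null_behavior(null_cohort, fast_cfg):
    _, _, _, ds = null_cohort
    screened = collapse_methylation(screen_features(ds, fast_cfg), ds.probe_map)
    with pytest.raises(ValueError, match="empty"):
        baseline_molecular_model(ds, screened, set(), fast_cfg, np.random.default_rng(1))
    with pytest.raises(ValueError, match="unknown"):
        baseline_molecular_model(ds, screened, {"proteome"}, fast_cfg, np.random.default_rng(1))
    res = baseline_molecular_model(ds, screened, {"mrna"}, fast_cfg, np.random.default_rng(2), n_splits=10)
    assert 0.35 <= res.median_c <= 0.65


def test_combined_baseline_beats_irrelevant_single_modality(planted_cohort, fast_cfg):
    """With planted effects in all modalities, the combined baseline should
    not trail a single modality by much, paired over identical split RNG."""
    _, _, _, ds = planted_cohort
    screened = collapse_methylation(screen_features(ds, fast_cfg), ds.probe_map)
    combined = baseline_molecular_model(ds, screened, {"mrna", "cnv", "methylation"},
                                        fast_cfg, np.random.default_rng(3), n_splits=10)
    single = baseline_molecular_model(ds, screened, {"cnv"},
                                      fast_cfg, np.random.default_rng(3), n_splits=10)
    assert combined.median_c >= single.median_c - 0.05
    assert combined.median_c > 0.6
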