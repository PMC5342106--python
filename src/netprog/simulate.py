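"""Synthetic cohorts with planted prognostic network modules.

The generator emulates the statistical structure the pipeline assumes: a
sparse protein-interaction-like network containing dense planted modules,
matched multi-omic feature matrices (continuous mRNA and copy-number
scores, bounded methylation beta values with 1-3 probes per gene), and
overall-survival outcomes from a Weibull proportional-hazards model whose
log-hazard loads on a subset of planted-module features, with independent
exponential censoring calibrated to a target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from netprog._rng import substream
from netprog.dataset import OmicsDataset

#: modalities that can carry planted effects
EFFECT_MODALITIES = ("mrna", "cnv", "methylation")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``effect_log_hr`` is the log hazard ratio per standard deviation of an
    active feature; ``frac_active_features`` is the fraction of planted
    (gene, modality) features that actually carry it.  The Weibull baseline
    is h0(t) = (shape/scale) * (t/scale)^(shape-1).
    """

    n_genes: int = 300
    n_modules: int = 1
    module_size: int = 8
    p_in: float = 0.8
    p_out: float = 0.01
    n_patients: int = 400
    effect_log_hr: float = 0.7
    frac_active_features: float = 0.6
    baseline_scale: float = 60.0  # months
    baseline_shape: float = 1.2
    censoring_rate: float = 0.3
    probes_per_gene_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules do not fit: n_modules * module_size > n_genes")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if not 0.0 <= self.frac_active_features <= 1.0:
            raise ValueError("frac_active_features must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort: module membership and nonzero effects."""

    module_members: list[set[str]]
    active_features: set[tuple[str, str]]  # (gene, modality)
    true_betas: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        planted = set().union(*self.module_members) if self.module_members else set()
        for gene, modality in self.active_features:
            if gene not in planted:
                raise ValueError(f"active feature ({gene}, {modality}) outside planted modules")
        if any(b == 0 for b in self.true_betas.values()):
            raise ValueError("true_betas must be nonzero")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(cfg: SimulationConfig) -> tuple[nx.Graph, PlantedTruth]:
    """Planted-partition network plus the truth record of its modules.

    Within-module gene pairs are connected with probability ``p_in``,
    all other pairs with ``p_out``; the graph is simple and undirected.
    Active (gene, modality) features are drawn from the planted modules at
    rate ``frac_active_features``, each with log-HR ``effect_log_hr``.
    """
    rng = substream(cfg.seed, "network")
    genes = _gene_names(cfg.n_genes)

    picked = rng.choice(cfg.n_genes, size=cfg.n_modules * cfg.module_size, replace=False)
    modules = [
        {genes[i] for i in picked[m * cfg.module_size : (m + 1) * cfg.module_size]}
        for m in range(cfg.n_modules)
    ]
    module_of = {}
    for m, members in enumerate(modules):
        for g in members:
            module_of[g] = m

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    mod_idx = np.array([module_of.get(g, -1) for g in genes])
    same_module = (mod_idx[iu] >= 0) & (mod_idx[iu] == mod_idx[ju])
    prob = np.where(same_module, cfg.p_in, cfg.p_out)
    keep = rng.random(prob.shape) < prob
    graph.add_edges_from((genes[a], genes[b]) for a, b in zip(iu[keep], ju[keep]))

    active: set[tuple[str, str]] = set()
    betas: dict[tuple[str, str], float] = {}
    if cfg.effect_log_hr != 0.0:
        candidates = [(g, m) for members in modules for g in sorted(members) for m in EFFECT_MODALITIES]
        n_active = int(round(cfg.frac_active_features * len(candidates)))
        for k in rng.choice(len(candidates), size=n_active, replace=False):
            g, m = candidates[k]
            active.add((g, m))
            betas[(g, m)] = cfg.effect_log_hr
    return graph, PlantedTruth(module_members=modules, active_features=active, true_betas=betas)


def _weibull_ph_times(rng: np.random.Generator, eta: np.ndarray, scale: float, shape: float) -> np.ndarray:
    # S(t|eta) = exp(-(t/scale)^shape * e^eta); invert U ~ Uniform(0,1)
    u = rng.uniform(size=eta.shape)
    return scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)


def _censoring_rate_for(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving expected censored fraction ``target``.

    For independent C ~ Exp(lam), P(censored | T=t) = 1 - exp(-lam t);
    solve mean_i[1 - exp(-lam T_i)] = target on the realized event times.
    """

    def gap(lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam * times)) - target)

    lo, hi = 1e-12, 1.0 / max(times.mean(), 1e-12)
    while gap(hi) < 0:
        hi *= 4.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid targets
            raise RuntimeError("censoring rate calibration failed")
    return brentq(gap, lo, hi, xtol=1e-14)


def generate_omics_survival(
    net: nx.Graph, truth: PlantedTruth, cfg: SimulationConfig
) -> OmicsDataset:
    """Multi-omic matrices and survival outcomes matched to the network.

    mRNA is standard normal; CNV a continuous GISTIC-like score
    (N(0, 0.5^2)); methylation beta values are a logistic transform of a
    per-gene Gaussian latent plus probe-level intercept and noise, so
    planted effects act on the latent (logit) scale.  The linear predictor
    is the sum of true_beta x standardized-latent-feature over active
    features; survival times are Weibull proportional hazards with that
    predictor; censoring is independent exponential calibrated to
    ``censoring_rate``.  An empty truth yields a valid null cohort.
    """
    genes = sorted(net.nodes)
    n, p = cfg.n_patients, len(genes)
    patients = [f"P{i:04d}" for i in range(n)]

    rng_feat = substream(cfg.seed, "features")
    mrna = rng_feat.normal(size=(p, n))
    cnv = rng_feat.normal(scale=0.5, size=(p, n))
    meth_latent = rng_feat.normal(size=(p, n))

    # probe structure: 1..probes_per_gene_max probes per gene
    n_probes_per_gene = rng_feat.integers(1, cfg.probes_per_gene_max + 1, size=p)
    probe_ids, probe_gene, probe_rows = [], [], []
    for gi, gene in enumerate(genes):
        for k in range(n_probes_per_gene[gi]):
            probe_ids.append(f"cg_{gene}_{k}")
            probe_gene.append(gene)
            probe_rows.append(gi)
    intercepts = rng_feat.normal(scale=1.0, size=len(probe_ids))
    probe_noise = rng_feat.normal(scale=0.5, size=(len(probe_ids), n))
    meth = expit(intercepts[:, None] + meth_latent[np.array(probe_rows)] + probe_noise)

    latent = {"mrna": mrna, "cnv": cnv, "methylation": meth_latent}
    gene_row = {g: i for i, g in enumerate(genes)}
    eta = np.zeros(n)
    for (gene, modality), beta in truth.true_betas.items():
        x = latent[modality][gene_row[gene]]
        z = (x - x.mean()) / x.std()
        eta += beta * z

    rng_surv = substream(cfg.seed, "survival")
    t_event = _weibull_ph_times(rng_surv, eta, cfg.baseline_scale, cfg.baseline_shape)
    if cfg.censoring_rate > 0:
        lam = _censoring_rate_for(t_event, cfg.censoring_rate)
        t_cens = rng_surv.exponential(scale=1.0 / lam, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    rng_clin = substream(cfg.seed, "clinical")
    clinical = pd.DataFrame(
        {
            "age": np.round(rng_clin.normal(58.0, 11.0, size=n), 1),
            "stage": rng_clin.choice([1, 2, 3, 4], size=n, p=[0.2, 0.45, 0.27, 0.08]),
            "lymph_node_count": rng_clin.poisson(3.0, size=n),
            "tumor_weight": np.round(rng_clin.gamma(shape=4.0, scale=12.0, size=n), 1),
        },
        index=patients,
    )

    return OmicsDataset(
        patients=patients,
        mrna=pd.DataFrame(mrna, index=genes, columns=patients),
        cnv=pd.DataFrame(cnv, index=genes, columns=patients),
        methylation=pd.DataFrame(meth, index=probe_ids, columns=patients),
        probe_map=pd.Series(probe_gene, index=probe_ids, name="gene"),
        clinical=clinical,
        survival_time=pd.Series(time, index=patients, name="time"),
        event=pd.Series(event, index=patients, name="event"),
    )
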