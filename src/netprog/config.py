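"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and budgets of the discovery/evaluation pipeline.

    The defaults encode the published procedure: screening keeps features
    with LRT p < 0.05; subnetworks need >= 4 genes; prognostic power is the
    median test C-index over 100 random 80/20 splits; the permutation null
    uses 100 survival permutations; the final model keeps features selected
    more than 5 times across splits; stratification uses consensus NMF with
    k = 2.  ``perm_cv_splits`` and ``fixed_alpha`` trade permutation-null
    fidelity for runtime (each permutation re-runs the cross-validation
    with fewer splits and, optionally, a fixed elastic-net strength).
    """

    alpha_screen: float = 0.05
    beta_restart: float = 0.4
    delta: float | str = "auto"
    min_subnetwork_size: int = 4
    n_cv_splits: int = 100
    train_frac: float = 0.8
    n_permutations: int = 100
    enet_mix: float = 0.5
    stability_min_count: int = 5
    nmf_k: int = 2
    nmf_runs: int = 50
    seed: int = 0
    # discovery internals
    auto_delta_perms: int = 10
    auto_delta_cap: int | None = None  # None -> min_subnetwork_size + 1
    discovery_n_perm: int = 30
    # penalized-CV internals
    n_alphas: int = 30
    inner_cv_folds: int = 5
    fixed_alpha: float | None = None
    perm_cv_splits: int = 20

    def __post_init__(self) -> None:
        if self.auto_delta_cap is not None and int(self.auto_delta_cap) < 2:
            raise ValueError("auto_delta_cap must be >= 2")
        for name in ("min_subnetwork_size", "n_cv_splits", "n_permutations",
                     "stability_min_count", "nmf_k", "nmf_runs", "auto_delta_perms",
                     "discovery_n_perm", "n_alphas", "inner_cv_folds",
                     "perm_cv_splits"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.alpha_screen < 1.0:
            raise ValueError("alpha_screen must lie in (0, 1)")
        if not 0.0 < self.beta_restart <= 1.0:
            raise ValueError("beta_restart must lie in (0, 1]")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0.0 <= self.enet_mix <= 1.0:
            raise ValueError("enet_mix must lie in [0, 1]")
        if self.delta != "auto" and float(self.delta) <= 0:
            raise ValueError('delta must be positive or "auto"')

    @property
    def effective_delta_cap(self) -> int:
        """Permuted-SCC size cap for auto-delta selection.

        Defaults to one above the minimum reportable subnetwork size, i.e.
        delta is pushed just high enough that permuted heat yields no
        subnetwork large enough to report.
        """
        return int(self.auto_delta_cap) if self.auto_delta_cap is not None else self.min_subnetwork_size + 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the full configuration, stamped into outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
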