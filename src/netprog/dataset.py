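"""Aligned multi-omic + clinical container for one patient cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical modality labels used throughout the pipeline
MODALITIES = ("mrna", "cnv", "methylation")


@dataclass
class OmicsDataset:
    """Per-modality feature matrices plus clinical/survival table.

    All matrices are feature x patient (genes for mRNA/CNV, probes for
    methylation) and share one patient ordering.  ``probe_map`` maps each
    methylation probe id to its gene symbol (many probes per gene allowed).
    """

    patients: list[str]
    mrna: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    probe_map: pd.Series
    clinical: pd.DataFrame  # patients x {age, stage, lymph_node_count, tumor_weight}
    survival_time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        pats = list(self.patients)
        for name in ("mrna", "cnv", "methylation"):
            mat = getattr(self, name)
            if list(mat.columns) != pats:
                raise ValueError(f"{name} matrix patient columns do not match cohort ordering")
        for name in ("clinical",):
            if list(getattr(self, name).index) != pats:
                raise ValueError(f"{name} table index does not match cohort ordering")
        for name in ("survival_time", "event"):
            if list(getattr(self, name).index) != pats:
                raise ValueError(f"{name} index does not match cohort ordering")
        meth = self.methylation.to_numpy(dtype=float)
        if meth.size and (np.nanmin(meth) < 0 or np.nanmax(meth) > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")
        t = self.survival_time.to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError("survival_time must be positive")
        ev = self.event.to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        missing = set(self.methylation.index) - set(self.probe_map.index)
        if missing:
            raise ValueError(f"{len(missing)} methylation probes missing from probe_map")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def feature_value(self, gene: str, modality: str, probe: str | None = None) -> pd.Series:
        """Per-patient values of one feature; methylation is addressed by probe."""
        if modality == "mrna":
            return self.mrna.loc[gene]
        if modality == "cnv":
            return self.cnv.loc[gene]
        if modality == "methylation":
            if probe is None:
                probes = self.probe_map.index[self.probe_map == gene]
                if len(probes) != 1:
                    raise KeyError(f"gene {gene} has {len(probes)} methylation probes; specify one")
                probe = probes[0]
            return self.methylation.loc[probe]
        raise KeyError(f"unknown modality {modality!r}")
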