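"""Readers and writers for the pipeline's on-disk formats.

Feature matrices are TSV with the feature id (gene symbol, or probe id
for methylation) in the first column and one column per patient; the
network is a two-column gene-symbol edge list; clinical data is a TSV
with patient id, survival time, event indicator and optional covariates.
Every writer stamps the analysis-config hash into a leading ``#`` comment
line, which all readers skip.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netprog.config import AnalysisConfig
from netprog.dataset import OmicsDataset
from netprog.simulate import PlantedTruth

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("age", "stage", "lymph_node_count", "tumor_weight")


def _header(cfg: AnalysisConfig | None) -> str:
    return f"# netprog config_hash={cfg.hash()}\n" if cfg is not None else ""


def write_feature_matrix(mat: pd.DataFrame, path: str | Path, modality: str, cfg: AnalysisConfig | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        mat.rename_axis("feature").to_csv(fh, sep="\t", lineterminator="\n")


def read_feature_matrix(path: str | Path, modality: str) -> pd.DataFrame:
    """Feature x patient matrix; NA cells preserved for the missing-data policy.

    Duplicate feature ids and non-numeric cells are rejected with the
    offending row (and column) named.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate feature ids: {sorted(set(dup))[:5]}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip().str.upper() != "NA")
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        out[col] = converted
    out.attrs["modality"] = modality
    return out


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column gene-symbol TSV as an undirected simple graph.

    Duplicate and reversed edges are merged; self-loops dropped (their
    count logged) with the node kept as isolated.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty edge list") from None
    if df.empty:
        raise ValueError(f"{path}: empty edge list")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    g = nx.Graph()
    self_loops = 0
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a == b:
            self_loops += 1
            g.add_node(a)
        else:
            g.add_edge(a, b)
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    return g


def write_edge_list(net: nx.Graph, path: str | Path, cfg: AnalysisConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical + survival TSV indexed by patient id.

    Requires ``time`` and ``event`` columns; rejects nonpositive times and
    events outside {0, 1}.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"{path}: nonpositive survival time for patient {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise ValueError(f"{path}: event must be 0 or 1 (patient {bad!r})")
    return df


def read_probe_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.iloc[:, 0].rename("gene")


# ---------------------------------------------------------------------------
# dataset assembly


def _apply_missing_policy(mat: pd.DataFrame, name: str, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Drop features with > 20% missing values; median-impute the rest."""
    frac = mat.isna().mean(axis=1)
    drop = frac > max_missing_frac
    if drop.any():
        logger.info("%s: dropped %d feature(s) with >%d%% missing", name, int(drop.sum()), int(100 * max_missing_frac))
        mat = mat[~drop]
    if mat.isna().any().any():
        med = mat.median(axis=1)
        mat = mat.apply(lambda col: col.fillna(med))
        logger.info("%s: median-imputed remaining missing values", name)
    return mat


def load_dataset(directory: str | Path) -> OmicsDataset:
    """Assemble an OmicsDataset from a directory of pipeline TSV files.

    The core sample set is the intersection of patient ids across all
    modalities and the clinical table, in clinical-table order; dropped
    patients are logged per file.
    """
    d = Path(directory)
    mrna = read_feature_matrix(d / "mrna.tsv", "mrna")
    cnv = read_feature_matrix(d / "cnv.tsv", "cnv")
    meth = read_feature_matrix(d / "methylation.tsv", "methylation")
    probe_map = read_probe_map(d / "probe_map.tsv")
    clin = read_clinical(d / "clinical.tsv")

    core = [p for p in clin.index if all(p in m.columns for m in (mrna, cnv, meth))]
    for name, mat in (("mrna", mrna), ("cnv", cnv), ("methylation", meth)):
        extra = len(clin.index) - len([p for p in clin.index if p in mat.columns])
        if extra:
            logger.info("core set: %d clinical patient(s) absent from %s", extra, name)
    if len(core) < len(clin.index):
        logger.info("core set: %d of %d patients retained", len(core), len(clin.index))

    mrna = _apply_missing_policy(mrna[core], "mrna")
    cnv = _apply_missing_policy(cnv[core], "cnv")
    meth = _apply_missing_policy(meth[core], "methylation")
    meth = meth.loc[[p for p in meth.index if p in probe_map.index]]
    clin = clin.loc[core]

    clinical_cols = [c for c in CLINICAL_COLUMNS if c in clin.columns]
    return OmicsDataset(
        patients=list(core),
        mrna=mrna,
        cnv=cnv,
        methylation=meth,
        probe_map=probe_map.loc[meth.index],
        clinical=clin[clinical_cols],
        survival_time=clin["time"].astype(float),
        event=clin["event"].astype(int),
    )


def write_dataset(ds: OmicsDataset, directory: str | Path, cfg: AnalysisConfig | None = None) -> None:
    """Write a dataset in the same TSV formats ``load_dataset`` reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_feature_matrix(ds.mrna, d / "mrna.tsv", "mrna", cfg)
    write_feature_matrix(ds.cnv, d / "cnv.tsv", "cnv", cfg)
    write_feature_matrix(ds.methylation, d / "methylation.tsv", "methylation", cfg)
    with open(d / "probe_map.tsv", "w") as fh:
        fh.write(_header(cfg))
        ds.probe_map.rename_axis("probe").to_csv(fh, sep="\t", lineterminator="\n")
    clin = ds.clinical.copy()
    clin["time"] = ds.survival_time
    clin["event"] = ds.event
    with open(d / "clinical.tsv", "w") as fh:
        fh.write(_header(cfg))
        clin.rename_axis("patient").to_csv(fh, sep="\t", lineterminator="\n")


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "module_members": [sorted(m) for m in truth.module_members],
        "active_features": sorted([list(t) for t in truth.active_features]),
        "true_betas": {f"{g}|{m}": b for (g, m), b in sorted(truth.true_betas.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_gmt(subnetworks, path: str | Path) -> None:
    """Subnetworks as GMT gene sets: id, description, member genes."""
    with open(path, "w") as fh:
        for sub in subnetworks:
            desc = f"size={sub.size};p={sub.size_class_p}"
            fh.write("\t".join([sub.subnetwork_id, desc] + sorted(sub.genes)) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, cfg: AnalysisConfig | None = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")
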