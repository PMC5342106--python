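"""Fisher-combined per-gene heat scores from screened survival p-values.

A gene's heat is ``score = -2 * sum_m ln(p_m)`` over its survival-related
(screened-in) modality p-values, i.e. Fisher's method for combining
independent tests; genes with no selected feature score 0, and the genes
with positive score form the survival-related gene set that seeds the
network diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netprog.screening import ScreeningResult

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class GeneHeat:
    """Heat score of one gene plus the modality p-values that built it."""

    gene: str
    score: float
    contributing: dict[str, float] = field(default_factory=dict)


def gene_heat(screened: ScreeningResult) -> dict[str, GeneHeat]:
    """Per-gene heat over selected features only (methylation pre-collapsed).

    Every gene present in the screening table gets an entry; genes with no
    selected feature have score 0.  Numerically-zero p-values are floored
    at the smallest positive double and logged.
    """
    meth = screened.stats[screened.stats["modality"] == "methylation"]
    dup = meth["gene"].duplicated()
    if dup.any():
        raise ValueError("methylation probes must be collapsed to one per gene before heat scoring")

    heats: dict[str, GeneHeat] = {
        g: GeneHeat(gene=g, score=0.0) for g in screened.stats["gene"].unique()
    }
    floored = 0
    for fid, row in screened.selected.iterrows():
        p = float(row["p_lrt"])
        if p <= 0.0:
            p = _P_FLOOR
            floored += 1
        gh = heats[row["gene"]]
        gh.contributing[row["modality"]] = p
        gh.score += -2.0 * np.log(p)
    if floored:
        logger.warning("floored %d zero p-values at %g", floored, _P_FLOOR)
    return heats


def survival_gene_set(heats: dict[str, GeneHeat]) -> set[str]:
    """Genes with a positive heat score — the survival-related gene set."""
    genes = {g for g, gh in heats.items() if gh.score > 0}
    logger.info("%d survival-related genes (score > 0) of %d scored", len(genes), len(heats))
    return genes


def heat_table(heats: dict[str, GeneHeat]) -> pd.DataFrame:
    """Tabular view: gene, score, and the per-modality contributing p-values."""
    rows = [
        {
            "gene": gh.gene,
            "score": gh.score,
            "p_mrna": gh.contributing.get("mrna", np.nan),
            "p_cnv": gh.contributing.get("cnv", np.nan),
            "p_methylation": gh.contributing.get("methylation", np.nan),
        }
        for gh in heats.values()
    ]
    return pd.DataFrame(rows).set_index("gene").sort_index()
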