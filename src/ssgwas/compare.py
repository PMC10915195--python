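"""Pairwise comparison of window schemes by shared pathways and genes.

For every pair of schemes the comparison counts NP, the significant
pathways the two have in common, and NG, the genes identified by both
schemes (intersection, configurable to union) that belong to those shared
pathways.  The diagonal holds each scheme's own counts.  This is the
lower-triangular summary used to judge overlapping against non-overlapping
windows of each size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError
from .enrichment import EnrichmentResult


@dataclass
class ComparisonMatrix:
    schemes: list[str]
    NP: np.ndarray          # shared significant pathways
    NG: np.ndarray          # genes in those shared pathways
    gene_mode: str          # "intersection" or "union"

    def frame(self, which: str = "NP", lower_triangular: bool = True) -> pd.DataFrame:
        m = {"NP": self.NP, "NG": self.NG}[which]
        df = pd.DataFrame(m, index=self.schemes, columns=self.schemes)
        if lower_triangular:
            mask = np.triu(np.ones_like(m, dtype=bool), k=1)
            df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
        df.index.name = f"{which}_{self.gene_mode}"
        return df


def _sig_pathways(results: list[EnrichmentResult]) -> dict[str, frozenset[str]]:
    return {r.pathway_id: None for r in results if r.significant}  # ordered set


def compare(results: dict[str, list[EnrichmentResult]],
            gene_sets: dict[str, set[str]], db,
            gene_mode: str = "intersection") -> ComparisonMatrix:
    """Build the NP/NG matrices.

    ``results`` maps scheme label -> enrichment results, ``gene_sets`` maps
    scheme label -> the genes that scheme identified (pooled across traits),
    ``db`` is the PathwayDB the tests ran against.  NP[i][j] counts shared
    significant pathways; NG[i][j] counts genes identified by both schemes
    (or either, with ``gene_mode='union'``) lying in those shared pathways.
    """
    if gene_mode not in ("intersection", "union"):
        raise DataError("gene_mode must be 'intersection' or 'union'")
    schemes = list(results)
    if set(schemes) != set(gene_sets):
        raise DataError("results and gene_sets must cover the same schemes")
    backgrounds = {r.N for res in results.values() for r in res}
    if len(backgrounds) > 1:
        raise DataError("schemes were tested against different backgrounds")
    sig = {s: set(_sig_pathways(results[s])) for s in schemes}
    k = len(schemes)
    NP = np.zeros((k, k), dtype=int)
    NG = np.zeros((k, k), dtype=int)
    for i, si in enumerate(schemes):
        for j, sj in enumerate(schemes):
            shared = sig[si] & sig[sj]
            NP[i, j] = len(shared)
            members: set[str] = set()
            for pid in shared:
                members |= set(db.pathways[pid][1])
            if gene_mode == "intersection":
                g = gene_sets[si] & gene_sets[sj]
            else:
                g = gene_sets[si] | gene_sets[sj]
            NG[i, j] = len(g & members)
    return ComparisonMatrix(schemes, NP, NG, gene_mode)


def summarize(cm: ComparisonMatrix) -> str:
    """Deterministic text report: per-scheme ranks by own NP and NG, and
    which overlap mode dominates the size-matched pairs."""
    if len(cm.schemes) < 2:
        raise DataError("need at least two schemes to summarize")
    diag_np = np.diag(cm.NP)
    diag_ng = np.diag(cm.NG)
    order = np.argsort(-diag_np, kind="stable")
    lines = [f"Scheme comparison (gene mode: {cm.gene_mode})",
             "scheme                 NP    NG"]
    for i in order:
        lines.append(f"{cm.schemes[i]:<22}{diag_np[i]:>4}{diag_ng[i]:>6}")
    # size-matched overlap-vs-nonoverlap verdicts
    by_size: dict[str, dict[str, int]] = {}
    for i, s in enumerate(cm.schemes):
        if "_" in s:
            size, mode = s.split("_", 1)
            by_size.setdefault(size, {})[mode] = i
    verdicts = []
    for size, modes in sorted(by_size.items()):
        if {"overlap", "nonoverlap"} <= set(modes):
            i, j = modes["overlap"], modes["nonoverlap"]
            if diag_np[i] > diag_np[j]:
                verdicts.append(f"{size}: overlapping has more significant pathways")
            elif diag_np[i] < diag_np[j]:
                verdicts.append(f"{size}: non-overlapping has more significant pathways")
            else:
                verdicts.append(f"{size}: tied")
    if verdicts:
        lines.append("")
        lines.extend(verdicts)
    return "\n".join(lines)
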