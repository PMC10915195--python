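"""Mapping selected SNPs to genes and tabulating SNP-gene distance bins.

Each selected marker is assigned to the gene containing it (smallest span on
ties) or, failing that, to the nearest gene on the same chromosome by
distance to the closer gene boundary, with lexicographic gene-id
tie-breaking.  Distances fall into the five bins used to summarise window
schemes: inside the gene, within 2,500 bp, 2,500-5,000 bp, 5,000-25,000 bp
and more than 25,000 bp away (upper edges inclusive).  A marker on a
chromosome without annotated genes is reported with gene "NA" in the
farthest bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneAnnotation

BINS = ["inside", "1-2500", "2500-5000", "5000-25000", ">25000"]
_EDGES = (0, 2_500, 5_000, 25_000)


def distance_bin(distance: float) -> str:
    """Half-open bins with inclusive upper edges; 0 means inside."""
    if distance <= 0:
        return BINS[0]
    if distance <= 2_500:
        return BINS[1]
    if distance <= 5_000:
        return BINS[2]
    if distance <= 25_000:
        return BINS[3]
    return BINS[4]


def assign_nearest_gene(snps: pd.DataFrame, ann: GeneAnnotation,
                        all_within: float | None = None) -> pd.DataFrame:
    """One row per marker: its gene, distance (bp) and bin.

    ``snps`` needs columns ``marker, chrom, pos``.  With ``all_within`` set,
    every gene within that distance is reported instead of only the nearest
    (one row per marker-gene pair).
    """
    genes_by_chrom = {str(c): sub.reset_index(drop=True)
                      for c, sub in ann.genes.groupby("chrom", sort=False)}
    rows = []
    for r in snps.itertuples():
        chrom, bp = str(r.chrom), int(r.pos)
        sub = genes_by_chrom.get(chrom)
        if sub is None or not len(sub):
            rows.append((r.marker, "NA", np.inf, BINS[4]))
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        inside = (start <= bp) & (bp <= end)
        if inside.any():
            cand = sub.loc[inside].copy()
            cand["span"] = cand["end"] - cand["start"]
            cand = cand.sort_values(["span", "gene_id"])
            rows.append((r.marker, cand["gene_id"].iloc[0], 0, BINS[0]))
            continue
        dist = np.where(bp < start, start - bp, bp - end)
        if all_within is not None:
            hit = np.nonzero(dist <= all_within)[0]
            if hit.size:
                for i in hit:
                    d = int(dist[i])
                    rows.append((r.marker, sub["gene_id"].iloc[i], d, distance_bin(d)))
                continue
        order = np.lexsort((sub["gene_id"].to_numpy(), dist))
        i = order[0]
        d = int(dist[i])
        rows.append((r.marker, sub["gene_id"].iloc[i], d, distance_bin(d)))
    return pd.DataFrame(rows, columns=["marker", "gene_id", "distance_bp", "bin"])


def tabulate_bins(assignments: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts per scheme per distance bin: number of SNPs and of distinct
    genes, with row totals — the standard summary layout for comparing
    window schemes by SNP-gene proximity."""
    rows = []
    for scheme, df in assignments.items():
        rec: dict[str, object] = {"scheme": scheme}
        genes_total: set[str] = set()
        for b in BINS:
            sub = df.loc[df["bin"] == b]
            rec[f"n_snp_{b}"] = sub["marker"].nunique()
            g = set(sub["gene_id"]) - {"NA"}
            rec[f"n_gene_{b}"] = len(g)
            genes_total |= g
        rec["n_snp_total"] = df["marker"].nunique()
        rec["n_gene_total"] = len(genes_total)
        rows.append(rec)
    return pd.DataFrame(rows)
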