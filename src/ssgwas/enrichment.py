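"""Pathway over/under-representation of a selected gene set.

For each pathway with K background members, drawing n selected genes from a
background of N and observing k in the pathway, the two-sided hypergeometric
p-value is twice the smaller tail probability, capped at one (a
minimum-likelihood-sum alternative is available behind a flag).  Multiple
testing across pathways is corrected with the Holm step-down procedure
("Bonferroni step-down"); a pathway is significant when the adjusted p is
strictly below alpha.  The background defaults to the annotation genes that
appear in the pathway database; pathways with no background member are
skipped and do not count toward the correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import DataError, PathwayDB


def hypergeom_two_sided(k: int, K: int, n: int, N: int,
                        method: str = "doubling") -> float:
    """Two-sided hypergeometric p for overlap k of a size-n draw with a
    size-K class in a universe of N.

    ``doubling``: p = min(1, 2 min(P[X<=k], P[X>=k])).  ``minlike``: sum of
    all outcome probabilities not exceeding that of k.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"invalid hypergeometric arguments K={K}, n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise DataError(f"overlap k={k} outside support [{lo}, {hi}]")
    if lo == hi:
        return 1.0
    rv = hypergeom(N, K, n)
    if method == "doubling":
        lower = rv.cdf(k)
        upper = rv.sf(k - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        support = np.arange(lo, hi + 1)
        pmf = rv.pmf(support)
        return float(min(1.0, pmf[pmf <= pmf[k - lo] * (1 + 1e-12)].sum()))
    raise DataError(f"unknown two-sided method {method!r}")


def holm_stepdown(p_raw) -> np.ndarray:
    """Holm's sequentially rejective adjusted p-values, in input order:
    p_adj(i) = max_{j<=i} min(1, (m - j + 1) p_(j)) over the ascending sort."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class EnrichmentResult:
    """One pathway's test within one scheme's selection."""

    pathway_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    direction: str
    significant: bool


def enrich(selected_genes, db: PathwayDB, background,
           alpha: float = 0.05, method: str = "doubling") -> list[EnrichmentResult]:
    """Test every pathway with background members; Holm-correct across them.

    ``background`` is the gene universe; selected genes outside it are
    ignored.  Direction is "enriched" when k exceeds its expectation nK/N,
    otherwise "depleted"; significance requires p_adj < alpha (strict).
    """
    background = set(background)
    if not background:
        raise DataError("empty background gene universe")
    selected = set(selected_genes) & background
    n, N = len(selected), len(background)
    rows = []
    for pid, (name, genes) in sorted(db.pathways.items()):
        members = genes & background
        K = len(members)
        if K == 0:
            continue
        k = len(selected & members)
        p = hypergeom_two_sided(k, K, n, N, method=method)
        direction = "enriched" if k > n * K / N else "depleted"
        rows.append([pid, name, k, K, n, N, p, direction])
    if not rows:
        return []
    p_adj = holm_stepdown([r[6] for r in rows])
    return [EnrichmentResult(pid, name, k, K, n, N, p, float(pa), d, bool(pa < alpha))
            for (pid, name, k, K, n, N, p, d), pa in zip(rows, p_adj)]


def enrichment_frame(results: list[EnrichmentResult], scheme: str | None = None
                     ) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    if scheme is not None and len(df):
        df.insert(0, "scheme", scheme)
    return df
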