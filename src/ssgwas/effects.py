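"""Back-solving SNP effects from GEBVs and per-SNP variance contributions.

Given the genotyped animals' breeding values a-hat, the 2p-centered dosage
matrix Z and the genomic relationship matrix G* with divisor
s = 2 sum p_j (1 - p_j), the marker effects are the projection

    u = Z' G*^-1 a-hat / s,

which reproduces a-hat exactly when G is unblended and invertible.  The
variance contribution of marker j is the empirical variance, across the
genotyped animals, of its genotype-score contribution z_.j * u_j (an
alternative parametric form 2 p_j (1 - p_j) u_j^2 is available behind a
flag).  Percentages are taken against the REML estimate of the trait's
total additive genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError


def backsolve_effects(gebv_genotyped: np.ndarray, Z: np.ndarray,
                      G_star: np.ndarray, divisor: float) -> np.ndarray:
    """Marker effects u = Z' G*^-1 a-hat / s, one column per trait."""
    a = np.atleast_2d(np.asarray(gebv_genotyped, dtype=float))
    if a.shape[0] == 1 and Z.shape[0] != 1:
        a = a.T
    if a.shape[0] != Z.shape[0] or G_star.shape != (Z.shape[0], Z.shape[0]):
        raise DataError("dimension mismatch between GEBVs, Z and G*")
    if divisor <= 0:
        raise DataError("divisor 2*sum p(1-p) must be positive")
    return Z.T @ np.linalg.solve(G_star, a) / divisor


def snp_variances(u: np.ndarray, Z: np.ndarray, method: str = "empirical",
                  allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """Per-marker additive-variance contributions, one column per trait.

    ``empirical``: sample variance (n-1 denominator) over genotyped animals
    of z_.j u_j.  ``parametric``: 2 p_j (1 - p_j) u_j^2.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] == 1 and Z.shape[1] != 1:
        u = u.T
    if u.shape[0] != Z.shape[1]:
        raise DataError("effect vector length must equal the marker count")
    if method == "empirical":
        if Z.shape[0] < 2:
            raise DataError("need at least two genotyped animals for variances")
        col_var = Z.var(axis=0, ddof=1)
        return col_var[:, None] * u ** 2
    if method == "parametric":
        if allele_freqs is None:
            raise DataError("parametric variances need allele frequencies")
        p = np.asarray(allele_freqs, dtype=float)
        return (2.0 * p * (1.0 - p))[:, None] * u ** 2
    raise DataError(f"unknown snp variance method {method!r}")


@dataclass
class SNPEffectSet:
    """Per-trait marker effects and variance contributions, aligned to the
    marker map, with the REML sigma_a^2 used as the percentage denominator."""

    marker_map: pd.DataFrame
    traits: list[str]
    effects: np.ndarray        # n_markers x T
    variances: np.ndarray      # n_markers x T
    allele_freqs: np.ndarray
    sigma_a2: np.ndarray       # per-trait total additive variance

    def __post_init__(self):
        if (self.sigma_a2 <= 0).any():
            raise DataError("sigma_a2 must be positive for every trait")
        if (self.variances < -1e-12).any():
            raise DataError("negative per-SNP variance")

    def pct_of_sigma_a2(self) -> np.ndarray:
        return self.variances / self.sigma_a2 * 100.0

    def to_frame(self) -> pd.DataFrame:
        pct = self.pct_of_sigma_a2()
        frames = []
        for k, t in enumerate(self.traits):
            df = self.marker_map.copy()
            df["trait"] = t
            df["effect"] = self.effects[:, k]
            df["variance"] = self.variances[:, k]
            df["pct_of_sigma_a2"] = pct[:, k]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def compute_snp_effects(gebv_genotyped: np.ndarray, genotypes, relationships,
                        sigma_a2: np.ndarray, traits,
                        method: str = "empirical") -> SNPEffectSet:
    """Back-solve effects and variances for a genotyped set.

    ``genotypes`` is the (QC-filtered, imputed) GenotypeMatrix of the
    genotyped animals in the same order as ``relationships.genotyped_ids``.
    """
    from .relationships import center_Z

    rel = relationships
    if rel.G22_star is None or rel.allele_freqs is None:
        raise DataError("relationship set has no genomic component")
    if list(genotypes.animal_ids) != list(rel.genotyped_ids):
        raise DataError("genotype matrix order does not match relationship set")
    Z = center_Z(genotypes, rel.allele_freqs)
    u = backsolve_effects(gebv_genotyped, Z, rel.G22_star, rel.divisor)
    v = snp_variances(u, Z, method=method, allele_freqs=rel.allele_freqs)
    return SNPEffectSet(genotypes.marker_map.copy(), list(traits), u, v,
                        rel.allele_freqs, np.asarray(sigma_a2, dtype=float))
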