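"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a small multibreed dairy bull stud: a pedigree of a
few hundred animals whose phenotyped bulls carry Holstein fractions in
[0.625, 1.0], gene-dropped 0/1/2 genotypes on several chromosomes, and
repeated records for three correlated semen traits (volume VOL, sperm number
NS, motility MOT) under a repeatability model

    y = Xb + Za a + Zp p + e,
    a ~ N(0, A (x) Va),  p ~ N(0, I (x) Vp),  e ~ N(0, I (x) Ve),

with fixed effects contemporary group (year-month), ejaculate order, age,
ambient temperature and a heterosis (expected-heterozygosity) regression.
Breeding values are pedigree-multivariate-normal plus optional explicit
marker QTL contributions, so both polygenic and marker-trackable signal
exist.  All randomness flows from a single seed.

Traits are simulated on a standardized scale (phenotypic variance about 1
per trait); the default covariance components give heritability 0.3 and
repeatability 0.5 per trait with moderate genetic correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GeneAnnotation, GenotypeMatrix, PathwayDB, PedigreeTable,
                 PhenotypeTable, UNKNOWN_PARENT, DataError, _sort_marker_map)

TRAITS = ["VOL", "NS", "MOT"]


def _corr_cov(variances, corr):
    v = np.asarray(variances, dtype=float)
    n = len(v)
    c = np.full((n, n), corr) + (1 - corr) * np.eye(n)
    sd = np.sqrt(v)
    return c * np.outer(sd, sd)


#: default components: h^2 = 0.3, repeatability = 0.5, phenotypic variance 1
DEFAULT_VA = _corr_cov([0.3, 0.3, 0.3], 0.5)
DEFAULT_VP = _corr_cov([0.2, 0.2, 0.2], 0.3)
DEFAULT_VE = _corr_cov([0.5, 0.5, 0.5], 0.2)


def _check_psd(m, name):
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.allclose(m, m.T):
        raise DataError(f"{name} must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise DataError(f"{name} is not positive semi-definite")
    return m


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults mirror the population the analysis is designed for: 131
    phenotyped bulls (offspring of 62 sires and 112 dams, pedigree ~305
    animals), about 100 records per bull, 72 genotyped animals, and a few
    thousand markers over several chromosomes.
    """

    n_sires: int = 62
    n_dams: int = 112
    n_generations: int = 1
    n_bulls_phenotyped: int = 131
    records_per_bull: int = 100
    n_genotyped_bulls: int = 61
    n_genotyped_dams: int = 11
    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    maf_low: float = 0.10
    maf_high: float = 0.50
    Va: np.ndarray = field(default_factory=lambda: DEFAULT_VA.copy())
    Vp: np.ndarray = field(default_factory=lambda: DEFAULT_VP.copy())
    Ve: np.ndarray = field(default_factory=lambda: DEFAULT_VE.copy())
    trait_means: tuple = (4.0, 1.2, 65.0)
    n_contemporary_groups: int = 24
    cg_sd: float = 0.30
    ejaculate_effect: float = 0.20
    age_slope: float = 0.01
    temp_slope: float = -0.02
    heterosis_effect: float = 0.50
    qtl_spec: list = field(default_factory=list)
    #: list of (chromosome 1-based, within-chromosome marker index 0-based,
    #: 3-vector of allele substitution effects)
    holstein_fraction_range: tuple = (0.625, 1.0)
    missing_rate: tuple = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        self.Va = _check_psd(self.Va, "Va")
        self.Vp = _check_psd(self.Vp, "Vp")
        self.Ve = _check_psd(self.Ve, "Ve")
        if self.records_per_bull < 1:
            raise DataError("records_per_bull must be >= 1")
        if self.n_sires + self.n_dams < 2:
            raise DataError("need at least two founders")
        if self.n_generations > 0 and (self.n_sires < 1 or self.n_dams < 1):
            raise DataError("generations require at least one sire and one dam")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome


def default_qtl_spec(spec: SimulationSpec, fraction: float = 0.25,
                     n_per_chromosome: int = 2, shared: bool = True,
                     rng: np.random.Generator | None = None) -> list:
    """QTLs at fixed positions whose summed variance is roughly ``fraction``
    of the polygenic additive variance, with effects shared across traits."""
    rng = rng or np.random.default_rng(spec.seed + 17)
    n_qtl = spec.n_chromosomes * n_per_chromosome
    mean_2pq = 2 * 0.3 * 0.7  # expectation under the default MAF window
    per_qtl = fraction * float(np.mean(np.diag(spec.Va))) / n_qtl
    u = np.sqrt(per_qtl / mean_2pq)
    out = []
    m = spec.markers_per_chromosome
    for chrom in range(1, spec.n_chromosomes + 1):
        for k in range(n_per_chromosome):
            idx = int((k + 1) * m / (n_per_chromosome + 1))
            if shared:
                eff = u * np.array([1.0, 1.0, 1.0])
            else:
                eff = u * rng.choice([-1.0, 1.0], size=3)
            out.append((chrom, idx, eff))
    return out


@dataclass
class TruthSet:
    """Simulation ground truth used as the oracle in recovery tests."""

    breeding_values: pd.DataFrame          # animal x trait, total (poly + QTL)
    permanent_env: pd.DataFrame            # phenotyped bull x trait
    fixed_coefficients: dict
    qtl: pd.DataFrame                      # chrom, marker, per-trait effect
    va_total: np.ndarray                   # Va + realized QTL variance, per trait

    def to_frame(self) -> pd.DataFrame:
        df = self.breeding_values.copy()
        df.insert(0, "animal", df.index)
        return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pedigree

def compute_heterozygosity(f_h_sire: float, f_h_dam: float) -> float:
    """Expected heterozygosity of the cross: f_H(sire) f_O(dam) + f_O(sire) f_H(dam)
    with f_O = 1 - f_H."""
    for v in (f_h_sire, f_h_dam):
        if not 0.0 <= v <= 1.0:
            raise DataError(f"breed fraction {v} outside [0, 1]")
    return f_h_sire * (1.0 - f_h_dam) + (1.0 - f_h_sire) * f_h_dam


def simulate_pedigree(spec: SimulationSpec, rng: np.random.Generator | None = None
                      ) -> tuple[PedigreeTable, dict]:
    """Founder sires/dams plus ``n_generations`` of offspring.

    Offspring Holstein fraction is the parental mean; founders are drawn
    inside ``holstein_fraction_range`` so every descendant stays in range.
    Returns the pedigree and a metadata dict with the phenotyped-bull and
    genotyped id lists (the last generation supplies the phenotyped bulls;
    with zero generations they are sampled from the founders).
    """
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.holstein_fraction_range
    sires = [f"S{i:04d}" for i in range(spec.n_sires)]
    dams = [f"D{i:04d}" for i in range(spec.n_dams)]
    animals = sires + dams
    sire_col = [UNKNOWN_PARENT] * len(animals)
    dam_col = [UNKNOWN_PARENT] * len(animals)
    frac = {a: rng.uniform(lo, hi) for a in animals}
    males, females = list(sires), list(dams)
    bulls: list[str] = []
    for gen in range(1, spec.n_generations + 1):
        n_off = spec.n_bulls_phenotyped
        new = []
        for k in range(n_off):
            a = f"B{gen}{k:04d}"
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            animals.append(a)
            sire_col.append(s)
            dam_col.append(d)
            frac[a] = 0.5 * (frac[s] + frac[d])
            new.append(a)
        males, females = new, females  # offspring treated as bulls
        bulls = new
    if spec.n_generations == 0:
        n = min(spec.n_bulls_phenotyped, len(animals))
        bulls = list(rng.choice(animals, size=n, replace=False))
    bf = pd.DataFrame({"holstein": [frac[a] for a in animals]}, index=pd.Index(animals, name="animal"))
    bf["other"] = 1.0 - bf["holstein"]
    ped = PedigreeTable(animals, sire_col, dam_col, bf)
    g_bulls = bulls[: spec.n_genotyped_bulls]
    g_dams = dams[: spec.n_genotyped_dams]
    meta = {"bulls": bulls, "genotyped": g_bulls + g_dams}
    return ped, meta


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(spec: SimulationSpec, ped: PedigreeTable,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Mendelian gene drop over the pedigree, one independent locus at a time.

    Founder alleles are Bernoulli with per-marker allele-2 frequency drawn
    from uniform(maf_low, maf_high); each non-founder inherits one uniformly
    chosen allele from each parent.  Positions are strictly increasing within
    chromosome.  No linkage is simulated.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n, m = len(ped), spec.n_markers
    p = rng.uniform(spec.maf_low, spec.maf_high, size=m)
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    parents = ped.parent_indices()
    for i in range(n):
        s, d = parents[i]
        if s < 0:
            h1[i] = rng.random(m) < p
        else:
            pick = rng.random(m) < 0.5
            h1[i] = np.where(pick, h1[s], h2[s])
        if d < 0:
            h2[i] = rng.random(m) < p
        else:
            pick = rng.random(m) < 0.5
            h2[i] = np.where(pick, h1[d], h2[d])
    codes = (h1 + h2).astype(float)
    chroms = np.repeat(np.arange(1, spec.n_chromosomes + 1), spec.markers_per_chromosome)
    spacing = rng.integers(2_000, 8_000, size=m)
    pos = np.concatenate([np.cumsum(spacing[chroms == c]) + 10_000
                          for c in range(1, spec.n_chromosomes + 1)])
    mm = pd.DataFrame({
        "marker": [f"M{c}_{j:05d}" for c, j in
                   zip(chroms, np.concatenate([np.arange((chroms == c).sum())
                                               for c in range(1, spec.n_chromosomes + 1)]))],
        "chrom": chroms.astype(str),
        "pos": pos.astype(int),
    })
    mm = _sort_marker_map(mm)
    return GenotypeMatrix(list(ped.animals), codes, mm)


def _qtl_flat_indices(spec: SimulationSpec) -> np.ndarray:
    idx = []
    for chrom, j, _ in spec.qtl_spec:
        if not (1 <= chrom <= spec.n_chromosomes and 0 <= j < spec.markers_per_chromosome):
            raise DataError(f"QTL ({chrom}, {j}) outside the simulated genome")
        idx.append((chrom - 1) * spec.markers_per_chromosome + j)
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(spec: SimulationSpec, ped: PedigreeTable,
                        genotypes: GenotypeMatrix, bulls: list[str],
                        rng: np.random.Generator | None = None
                        ) -> tuple[PhenotypeTable, TruthSet]:
    """Repeated 3-trait records for ``bulls`` plus the full truth set.

    Breeding values: L_A N L_Va' (covariance A (x) Va) plus centered QTL
    genotype scores times the QTL effects.  Permanent environment: i.i.d.
    MVN(0, Vp) per bull.  Residual: i.i.d. MVN(0, Ve) per record.
    """
    from .relationships import build_A

    rng = rng or np.random.default_rng(spec.seed + 2)
    n = len(ped)
    A = build_A(ped)
    La = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    Lva = np.linalg.cholesky(spec.Va + 1e-12 * np.eye(3))
    a = La @ rng.standard_normal((n, 3)) @ Lva.T

    qtl_rows = []
    va_total = np.diag(spec.Va).astype(float).copy()
    if spec.qtl_spec:
        qidx = _qtl_flat_indices(spec)
        U = np.array([np.asarray(e, dtype=float) for _, _, e in spec.qtl_spec])
        Zq = genotypes.codes[:, qidx]
        Zq = Zq - Zq.mean(axis=0)
        a = a + Zq @ U
        va_total += ((Zq ** 2).mean(axis=0)[:, None] * U ** 2).sum(axis=0)
        for (chrom, j, eff), fi in zip(spec.qtl_spec, qidx):
            qtl_rows.append({"chrom": chrom, "marker_index": j,
                             "marker": genotypes.marker_map["marker"].iloc[fi],
                             **{f"effect_{t}": e for t, e in zip(TRAITS, eff)}})

    bidx = np.array([ped.index_of(b) for b in bulls])
    pe = rng.standard_normal((len(bulls), 3)) @ np.linalg.cholesky(spec.Vp + 1e-12 * np.eye(3)).T

    cg_labels = [f"{2001 + k // 12}-{k % 12 + 1:02d}" for k in range(spec.n_contemporary_groups)]
    cg_eff = rng.normal(0.0, spec.cg_sd, size=(spec.n_contemporary_groups, 3))
    eo_eff = np.full(3, spec.ejaculate_effect)
    beta_age = np.full(3, spec.age_slope)
    beta_temp = np.full(3, spec.temp_slope)
    beta_het = np.full(3, spec.heterosis_effect)
    mu = np.asarray(spec.trait_means, dtype=float)

    het = {}
    parents = ped.parent_indices()
    for b in bulls:
        i = ped.index_of(b)
        s, d = parents[i]
        if s >= 0 and d >= 0:
            fs = ped.holstein_fraction(ped.animals[s])
            fd = ped.holstein_fraction(ped.animals[d])
        else:
            fs = fd = ped.holstein_fraction(b)
        het[b] = compute_heterozygosity(fs, fd)

    start_age = rng.uniform(24, 60, size=len(bulls))
    rows = []
    rec = 0
    Lve = np.linalg.cholesky(spec.Ve + 1e-12 * np.eye(3))
    for k, b in enumerate(bulls):
        for r in range(spec.records_per_bull):
            # stagger the cycle by bull so contemporary group is not aliased
            # with ejaculate order or age
            cg = (k + r) % spec.n_contemporary_groups
            eo = int(rng.integers(2))
            age = start_age[k] + 0.5 * r
            temp = 28.0 + 5.0 * np.sin(2 * np.pi * cg / 12.0) + rng.normal(0, 1.5)
            e = Lve @ rng.standard_normal(3)
            y = (mu + cg_eff[cg] + eo * eo_eff + beta_age * age + beta_temp * temp
                 + beta_het * het[b] + a[bidx[k]] + pe[k] + e)
            miss = np.array([rng.random() < mr for mr in spec.missing_rate])
            if miss.all():
                miss[rng.integers(3)] = False
            yv = np.where(miss, np.nan, y)
            rows.append((b, *yv, cg_labels[cg], str(eo + 1), age, temp, het[b]))
            rec += 1
    df = pd.DataFrame(rows, columns=["animal", *TRAITS, "contemporary_group",
                                     "ejaculate_order", "age_months",
                                     "ambient_temp_C", "heterozygosity"])
    phen = PhenotypeTable(df, list(TRAITS))
    truth = TruthSet(
        breeding_values=pd.DataFrame(a, index=pd.Index(ped.animals, name="animal"), columns=TRAITS),
        permanent_env=pd.DataFrame(pe, index=pd.Index(bulls, name="animal"), columns=TRAITS),
        fixed_coefficients={
            "mu": mu, "contemporary_group": cg_eff, "cg_labels": cg_labels,
            "ejaculate_order": eo_eff, "age_months": beta_age,
            "ambient_temp_C": beta_temp, "heterozygosity": beta_het,
        },
        qtl=pd.DataFrame(qtl_rows),
        va_total=va_total,
    )
    return phen, truth


# ---------------------------------------------------------------------------
# annotation and pathways over the synthetic genome

def simulate_annotation(genotypes: GenotypeMatrix, gene_length: int = 3_000,
                        gene_gap: int = 4_000,
                        rng: np.random.Generator | None = None) -> GeneAnnotation:
    """Synthetic gene map tiling each simulated chromosome.

    Genes of fixed length alternate with intergenic gaps across the span of
    the marker positions, so markers fall inside genes, near genes and far
    from genes in realistic proportions.
    """
    rows = []
    g = 0
    for chrom, sub in genotypes.marker_map.groupby("chrom", sort=False):
        start = max(1, int(sub["pos"].min()) - gene_gap)
        end = int(sub["pos"].max()) + gene_gap
        pos = start
        while pos < end:
            rows.append((f"G{g:05d}", str(chrom), pos, pos + gene_length - 1, "+"))
            g += 1
            pos += gene_length + gene_gap
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def simulate_pathways(annotation: GeneAnnotation, n_pathways: int = 30,
                      genes_per_pathway: int = 15,
                      causal_genes: list[str] | None = None,
                      rng: np.random.Generator | None = None) -> PathwayDB:
    """Random gene sets over the synthetic annotation.

    If ``causal_genes`` is given, the first few pathways are seeded with
    them so a planted signal has pathways to light up.
    """
    rng = rng or np.random.default_rng(12345)
    genes = list(annotation.genes["gene_id"])
    paths: dict[str, tuple[str, frozenset[str]]] = {}
    causal = list(causal_genes or [])
    for k in range(n_pathways):
        members = set(rng.choice(genes, size=min(genes_per_pathway, len(genes)),
                                 replace=False))
        if causal and k < 5:
            members |= set(causal)
        paths[f"path{k:03d}"] = (f"synthetic pathway {k}", frozenset(members))
    return PathwayDB(paths)


# ---------------------------------------------------------------------------
# one-stop bundle

@dataclass
class SimulatedData:
    spec: SimulationSpec
    pedigree: PedigreeTable
    phenotypes: PhenotypeTable
    genotypes: GenotypeMatrix          # genotyped animals only (analysis input)
    genotypes_all: GenotypeMatrix      # every pedigree animal (truth side)
    truth: TruthSet
    genotyped_ids: list[str]
    bulls: list[str]


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """Run the three generators off one seed and assemble the analysis inputs."""
    root = np.random.SeedSequence(spec.seed)
    r_ped, r_gen, r_phe = (np.random.default_rng(s) for s in root.spawn(3))
    ped, meta = simulate_pedigree(spec, r_ped)
    g_all = simulate_genotypes(spec, ped, r_gen)
    phen, truth = simulate_phenotypes(spec, ped, g_all, meta["bulls"], r_phe)
    gidx = [ped.index_of(a) for a in meta["genotyped"]]
    g_sub = GenotypeMatrix(meta["genotyped"], g_all.codes[gidx], g_all.marker_map.copy())
    return SimulatedData(spec, ped, phen, g_sub, g_all, truth,
                         meta["genotyped"], meta["bulls"])
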