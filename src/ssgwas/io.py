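"""Readers, writers and in-memory domain types for the pipeline inputs.

All downstream modules consume only the containers defined here: a pedigree
with breed composition, a table of repeated phenotypic records, a 0/1/2
genotype matrix with a marker map, a gene annotation, a pathway database
(GMT) and the run configuration.  External formats are plain TSV with a
header, GFF3/BED for genes and GMT for pathways; every tabular type
round-trips through its writer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

UNKNOWN_PARENT = "0"
#: sentinel used in pedigree files for a missing sire/dam

MISSING_CODE = np.nan


class DataError(ValueError):
    """Fatal problem in an input file or a domain-type invariant."""


def _natural_chrom_key(chrom: str):
    """Sort chromosomes 1,2,...,10,...,X as a human would, not lexically."""
    s = str(chrom)
    return (0, int(s)) if s.isdigit() else (1, s)


# ---------------------------------------------------------------------------
# pedigree

@dataclass
class PedigreeTable:
    """Pedigree in topological order plus per-animal breed composition.

    ``animals``/``sires``/``dams`` are aligned lists; unknown parents carry
    :data:`UNKNOWN_PARENT`.  ``breed_fractions`` is indexed by animal id with
    one column per breed; rows sum to 1.
    """

    animals: list[str]
    sires: list[str]
    dams: list[str]
    breed_fractions: pd.DataFrame

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.animals)}
        if len(self._index) != len(self.animals):
            raise DataError("duplicate animal ids in pedigree")
        for a, s, d in zip(self.animals, self.sires, self.dams):
            for p in (s, d):
                if p != UNKNOWN_PARENT and self._index.get(p, len(self.animals)) >= self._index[a]:
                    raise DataError(f"pedigree not in topological order near animal {a!r}")
        if self.breed_fractions.shape[1]:
            sums = self.breed_fractions.sum(axis=1)
            bad = sums.index[(sums - 1.0).abs() > 1e-9]
            if len(bad):
                raise DataError(f"breed fractions do not sum to 1 for: {list(bad[:5])}")

    def __len__(self) -> int:
        return len(self.animals)

    def index_of(self, animal: str) -> int:
        return self._index[animal]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions, -1 for unknown."""
        out = np.full((len(self.animals), 2), -1, dtype=int)
        for i, (s, d) in enumerate(zip(self.sires, self.dams)):
            if s != UNKNOWN_PARENT:
                out[i, 0] = self._index[s]
            if d != UNKNOWN_PARENT:
                out[i, 1] = self._index[d]
        return out

    def holstein_fraction(self, animal: str, breed: str = "holstein") -> float:
        return float(self.breed_fractions.loc[animal, breed])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal": self.animals, "sire": self.sires, "dam": self.dams})
        if self.breed_fractions.shape[1]:
            bf = self.breed_fractions.reindex(self.animals).reset_index(drop=True)
            df = pd.concat([df, bf], axis=1)
        return df


def _toposort_pedigree(df: pd.DataFrame) -> pd.DataFrame:
    """Kahn's algorithm on parent->offspring edges; fatal on cycles."""
    ids = list(df["animal"])
    idset = set(ids)
    parents = {
        r.animal: [p for p in (r.sire, r.dam) if p != UNKNOWN_PARENT]
        for r in df.itertuples()
    }
    for a, ps in parents.items():
        if a in ps:
            raise DataError(f"pedigree cycle: animal {a!r} is its own parent")
    indeg = {a: sum(1 for p in ps if p in idset) for a, ps in parents.items()}
    children: dict[str, list[str]] = {a: [] for a in ids}
    for a, ps in parents.items():
        for p in ps:
            if p in idset:
                children[p].append(a)
    order = [a for a in ids if indeg[a] == 0]
    head = 0
    while head < len(order):
        for c in children[order[head]]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
        head += 1
    if len(order) != len(ids):
        cyclic = sorted(a for a in ids if indeg[a] > 0)
        raise DataError(f"cycle in pedigree involving: {cyclic[:10]}")
    return df.set_index("animal").loc[order].reset_index()


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a TSV with columns ``animal, sire, dam[, <breed>...]``.

    Parents absent from the file (founder parents) are treated as unknown.
    The result is topologically sorted; a cycle is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"animal", "sire", "dam"}
    if not required.issubset(df.columns):
        raise DataError(f"pedigree file {path} must have columns {sorted(required)}")
    df = df.fillna(UNKNOWN_PARENT)
    idset = set(df["animal"])
    # a parent not listed as an animal is an implicit founder -> unknown
    for col in ("sire", "dam"):
        df[col] = [p if p in idset or p == UNKNOWN_PARENT else UNKNOWN_PARENT
                   for p in df[col]]
    df = _toposort_pedigree(df)
    breed_cols = [c for c in df.columns if c not in ("animal", "sire", "dam")]
    bf = df.set_index("animal")[breed_cols].astype(float) if breed_cols else pd.DataFrame(index=df["animal"])
    return PedigreeTable(list(df["animal"]), list(df["sire"]), list(df["dam"]), bf)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes

#: covariate columns expected in a phenotype table, besides the trait columns
PHENOTYPE_COVARIATES = ["contemporary_group", "ejaculate_order", "age_months",
                        "ambient_temp_C", "heterozygosity"]


@dataclass
class PhenotypeTable:
    """Repeated records: one row per collection, trait values may be missing.

    ``traits`` names the trait columns of ``df`` (default VOL/NS/MOT order).
    Every row must have at least one non-missing trait value and an animal id
    present in the pedigree when the two are combined downstream.
    """

    df: pd.DataFrame
    traits: list[str]

    def __post_init__(self):
        missing = [c for c in ["animal", *self.traits, *PHENOTYPE_COVARIATES]
                   if c not in self.df.columns]
        if missing:
            raise DataError(f"phenotype table lacks columns: {missing}")
        if len(self.df):
            all_nan = self.df[self.traits].isna().all(axis=1)
            if all_nan.any():
                raise DataError(
                    f"{int(all_nan.sum())} record(s) have no trait value at all")

    def __len__(self) -> int:
        return len(self.df)

    def n_records_per_trait(self) -> pd.Series:
        return self.df[self.traits].notna().sum()


def read_phenotypes(path: str | Path, traits: list[str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "contemporary_group": str,
                                            "ejaculate_order": str})
    if traits is None:
        traits = [c for c in df.columns if c not in ("animal", *PHENOTYPE_COVARIATES)]
    return PhenotypeTable(df, list(traits))


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    phen.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class GenotypeMatrix:
    """0/1/2 allele-2 dosage matrix with its marker map.

    ``codes`` is ``float`` so missing entries can be NaN (and mean imputation
    can fill them); ``marker_map`` has columns ``marker, chrom, pos`` sorted
    by (chromosome, position).
    """

    animal_ids: list[str]
    codes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.animal_ids), len(self.marker_map)):
            raise DataError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_map)} markers")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional dosages; only raw input is strict
        self._raw_valid = bool(valid.all())

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def allele_frequencies(self) -> np.ndarray:
        """Observed frequency of allele 2 per marker (missing ignored)."""
        return np.nanmean(self.codes, axis=0) / 2.0

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=0)


def _sort_marker_map(mm: pd.DataFrame) -> pd.DataFrame:
    key = mm.assign(_ck=[_natural_chrom_key(c) for c in mm["chrom"]])
    return key.sort_values(["_ck", "pos", "marker"]).drop(columns="_ck").reset_index(drop=True)


def read_genotypes(path_matrix: str | Path, path_map: str | Path) -> GenotypeMatrix:
    """Read the genotype matrix (rows=animals) and its marker map.

    Matrix TSV: first column ``animal``, remaining columns marker ids, cells
    0/1/2 or NA.  Map TSV: ``marker, chrom, pos``.  Markers are reordered to
    the map sorted by (chromosome, position, marker id).
    """
    mat = pd.read_csv(path_matrix, sep="\t", dtype={"animal": str})
    if "animal" not in mat.columns:
        raise DataError(f"{path_matrix}: first column must be 'animal'")
    mm = pd.read_csv(path_map, sep="\t", dtype={"marker": str, "chrom": str})
    if not {"marker", "chrom", "pos"}.issubset(mm.columns):
        raise DataError(f"{path_map}: needs columns marker, chrom, pos")
    if (mm["pos"] <= 0).any():
        raise DataError(f"{path_map}: positions must be positive")
    markers = [c for c in mat.columns if c != "animal"]
    if set(markers) != set(mm["marker"]):
        raise DataError("marker sets of matrix and map differ")
    codes = mat[markers].to_numpy(dtype=float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DataError(
            f"invalid genotype code {codes[r, c]!r} for animal "
            f"{mat['animal'].iloc[r]!r}, marker {markers[c]!r}")
    mm = _sort_marker_map(mm)
    order = [markers.index(m) for m in mm["marker"]]
    return GenotypeMatrix(list(mat["animal"]), codes[:, order], mm)


def write_genotypes(g: GenotypeMatrix, path_matrix: str | Path, path_map: str | Path) -> None:
    arr = g.codes.astype(object)
    # keep integer look for clean codes so the round trip is exact
    whole = ~np.isnan(g.codes) & (g.codes == np.round(g.codes))
    arr[whole] = g.codes[whole].astype(int)
    df = pd.DataFrame(arr, columns=list(g.marker_map["marker"]))
    df.insert(0, "animal", g.animal_ids)
    df.to_csv(path_matrix, sep="\t", index=False, na_rep="NA")
    g.marker_map.to_csv(path_map, sep="\t", index=False)


def qc_filter(g: GenotypeMatrix, min_call_rate: float = 0.90,
              min_maf: float = 0.05) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers with call rate *below* ``min_call_rate`` or MAF *below*
    ``min_maf`` (exact ties are kept), then mean-impute remaining missing
    codes to 2p.  Returns the filtered matrix and a report of removed markers.
    """
    if not (0 < min_call_rate <= 1 and 0 < min_maf <= 1):
        raise DataError("QC thresholds must lie in (0, 1]")
    cr = g.call_rates()
    p = g.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    low_cr = cr < min_call_rate
    low_maf = np.where(np.isnan(maf), True, maf < min_maf)
    drop = low_cr | low_maf
    reasons = np.where(low_cr, "call_rate", "maf")
    report = pd.DataFrame({
        "marker": g.marker_map["marker"][drop],
        "reason": reasons[drop],
        "call_rate": cr[drop],
        "maf": maf[drop],
    }).reset_index(drop=True)
    keep = ~drop
    if not keep.any():
        raise DataError("QC removed every marker")
    codes = g.codes[:, keep].copy()
    means = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(codes))
    codes[nan_r, nan_c] = means[nan_c]
    mm = g.marker_map.loc[keep].reset_index(drop=True)
    return GenotypeMatrix(g.animal_ids, codes, mm), report


# ---------------------------------------------------------------------------
# gene annotation

@dataclass
class GeneAnnotation:
    """Genes with 1-based inclusive coordinates (columns
    ``gene_id, chrom, start, end, strand``)."""

    genes: pd.DataFrame

    def __post_init__(self):
        need = {"gene_id", "chrom", "start", "end", "strand"}
        if not need.issubset(self.genes.columns):
            raise DataError(f"annotation needs columns {sorted(need)}")
        if (self.genes["start"] > self.genes["end"]).any():
            bad = self.genes.loc[self.genes["start"] > self.genes["end"], "gene_id"]
            raise DataError(f"gene(s) with start > end: {list(bad[:5])}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes["gene_id"])


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read genes from GFF3 (1-based inclusive) or BED (0-based half-open).

    The format is decided by extension (.bed vs .gff/.gff3); everything is
    normalised to 1-based inclusive coordinates internally.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed(path)
    return _read_gff3(path)


def _read_bed(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) > 5 else "+"
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i >= end_i:
                raise DataError(f"{path}:{lineno}: empty or inverted BED interval")
            rows.append((name, chrom, start_i + 1, end_i, strand))
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def _read_gff3(path: Path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.start > feat.end:
            raise DataError(f"{path}: gene {feat.id} has start > end")
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    if not rows:
        raise DataError(f"{path}: no gene features found")
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def write_annotation_bed(ann: GeneAnnotation, path: str | Path) -> None:
    df = ann.genes.copy()
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"] - 1, "end": df["end"],
        "name": df["gene_id"], "score": 0, "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# pathways

@dataclass
class PathwayDB:
    """GMT-style gene sets: pathway id -> (name, frozenset of gene ids)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise DataError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return out


def read_gmt(path: str | Path) -> PathwayDB:
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs id, "
                                "description and at least one gene")
            pid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise DataError(f"{path}:{lineno}: pathway {pid!r} lists no genes")
            pathways[pid] = (desc, frozenset(genes))
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in db.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# run configuration

DEFAULT_THRESHOLDS = {1: 0.001, 10: 0.01, 30: 0.03, 50: 0.05, 100: 0.1}
#: per-window-size minimum percentage of additive variance for SNP selection


@dataclass
class RunConfig:
    """Whole-run configuration mirroring the YAML config file."""

    window_sizes: list[int] = field(default_factory=lambda: [1, 10, 30, 50, 100])
    overlap_modes: list[str] = field(default_factory=lambda: ["overlapping", "non_overlapping"])
    thresholds: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    seed: int = 0
    reml_max_iter: int = 200
    reml_tol: float = 1e-8
    significance_alpha: float = 0.05

    def __post_init__(self):
        for w in self.window_sizes:
            if w not in self.thresholds:
                raise DataError(f"no selection threshold configured for window size {w}")
        bad = set(self.overlap_modes) - {"overlapping", "non_overlapping"}
        if bad:
            raise DataError(f"unknown overlap mode(s): {sorted(bad)}")


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "thresholds" in raw:
        raw["thresholds"] = {int(k): float(v) for k, v in raw["thresholds"].items()}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Uniform TSV writer for all tabular pipeline outputs."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
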