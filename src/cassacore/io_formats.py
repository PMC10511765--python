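"""Shared data model and file formats for the core-collection pipeline.

Genotypes are stored as reference- or alternate-allele dosages (0/1/2 for a
diploid) with an explicit missing sentinel; phenotypes travel in long format
(quantitative trial records and qualitative class records); selections are
binary accession-by-method membership matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reserved integer marking a missing dosage; never a valid diploid dosage.
MISSING = -1

PLOIDY = 2


class PipelineError(ValueError):
    """Base class for contract violations in pipeline inputs."""


def trait_values(series: pd.Series) -> np.ndarray:
    """Trait column as a float array with NaN for any missing marker."""
    return pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)


class ParseError(PipelineError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeMatrix:
    """Accessions x loci dosage matrix for biallelic diploid SNPs.

    ``dosages[i, l]`` counts copies of the counted allele (ALT by default)
    carried by accession ``i`` at locus ``l``; entries are in {0, 1, 2} or
    :data:`MISSING`. Within-individual allele frequency is ``dosage / 2``.
    """

    accession_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    dosages: np.ndarray  # int8/int16 N x L

    def __post_init__(self) -> None:
        dos = np.asarray(self.dosages)
        if dos.ndim != 2:
            raise PipelineError("dosages must be a 2-D accession x locus array")
        n, l = dos.shape
        if n < 2 or l < 1:
            raise PipelineError(f"need >=2 accessions and >=1 locus, got {n}x{l}")
        if len(self.accession_ids) != n or len(self.locus_ids) != l:
            raise PipelineError("id lists do not match dosage matrix shape")
        if len(set(self.accession_ids)) != n:
            raise PipelineError("duplicate accession ids")
        if len(set(self.locus_ids)) != l:
            raise PipelineError("duplicate locus ids")
        valid = np.isin(dos, (0, 1, 2, MISSING))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise PipelineError(
                f"invalid dosage {dos[i, j]} at accession "
                f"{self.accession_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        object.__setattr__(self, "dosages", dos)

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def allele_frequencies(self) -> np.ndarray:
        """Within-individual counted-allele frequencies (N x L, missing -> nan)."""
        p = self.dosages.astype(float) / PLOIDY
        p[self.missing_mask] = np.nan
        return p

    def subset(self, accession_idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(accession_idx, dtype=int)
        return GenotypeMatrix(
            accession_ids=tuple(self.accession_ids[i] for i in idx),
            locus_ids=self.locus_ids,
            dosages=self.dosages[idx],
        )


def read_genotypes_vcf(
    path,
    *,
    count_allele: str = "alt",
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read biallelic diploid genotypes from a VCF 4.x file.

    Parameters
    ----------
    count_allele
        ``"alt"`` (default) codes dosages as ALT-allele counts, ``"ref"``
        flips the orientation. All downstream distances are invariant to
        the choice for biallelic loci.
    skip_multiallelic
        Skip records with more than one ALT allele (with a warning); if
        False, such records raise :class:`ParseError`.
    """
    from cyvcf2 import VCF

    if count_allele not in ("alt", "ref"):
        raise PipelineError("count_allele must be 'alt' or 'ref'")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                if skip_multiallelic:
                    n_skipped += 1
                    continue
                raise ParseError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                    f"(line for variant {rec.ID or '.'})"
                )
            gts = np.array(rec.genotypes, dtype=int)[:, :2]  # allele indices, -1 = missing
            col = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
            if count_allele == "ref":
                col = np.where(col == MISSING, MISSING, PLOIDY - col)
            locus_ids.append(f"{rec.CHROM}:{rec.POS}")
            columns.append(col.astype(np.int8))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed VCF record in {path}: {exc}") from exc
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic record(s) in {path}")
    if not columns:
        raise PipelineError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        accession_ids=tuple(samples),
        locus_ids=tuple(locus_ids),
        dosages=np.column_stack(columns),
    )


def read_genotypes_csv(path) -> GenotypeMatrix:
    """Read a dosage CSV: first column accession ids, header of locus ids,
    cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PipelineError(f"duplicate accession id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise PipelineError(f"duplicate locus id {dup!r} in {path}")
    dos = np.empty(df.shape, dtype=np.int8)
    cells = df.to_numpy()
    for val, code in (("0", 0), ("1", 1), ("2", 2), ("NA", MISSING), ("", MISSING)):
        dos[cells == val] = code
    bad = ~np.isin(cells, ("0", "1", "2", "NA", ""))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PipelineError(
            f"invalid dosage cell {cells[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    return GenotypeMatrix(
        accession_ids=tuple(df.index),
        locus_ids=tuple(df.columns),
        dosages=dos,
    )


def write_genotypes_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        g.dosages.astype(object), index=list(g.accession_ids), columns=list(g.locus_ids)
    )
    df = df.where(g.dosages != MISSING, "NA")
    df.to_csv(path, index_label="accession_id")


def write_genotypes_vcf(g: GenotypeMatrix, path, *, chrom: str = "1") -> None:
    """Write a minimal biallelic VCF (plumbing for interchange; A/C alleles)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        for j, locus in enumerate(g.locus_ids):
            if ":" in locus:
                c, pos = locus.split(":", 1)
            else:
                c, pos = chrom, str(j + 1)
            gts = "\t".join(code[int(d)] for d in g.dosages[:, j])
            fh.write(f"{c}\t{pos}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the locus mean rounded to {0, 1, 2}.

    Plumbing only — statistical imputation is expected upstream; this keeps
    distance kernels well-defined. Non-missing entries are never changed.
    """
    if not g.has_missing():
        return g
    dos = g.dosages.astype(float)
    miss = g.missing_mask
    dos[miss] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(dos, axis=0)
    all_missing = np.isnan(means)
    if all_missing.any():
        loci = [g.locus_ids[j] for j in np.flatnonzero(all_missing)]
        raise PipelineError(f"all calls missing at loci: {', '.join(loci)}")
    filled = g.dosages.copy()
    rounded = np.clip(np.rint(means), 0, PLOIDY).astype(filled.dtype)
    filled[miss] = np.broadcast_to(rounded, filled.shape)[miss]
    return replace(g, dosages=filled)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    kind: str  # "quantitative" | "qualitative"
    classes: tuple[int, ...] = ()  # qualitative class codes
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "qualitative"):
            raise PipelineError(f"unknown trait kind {self.kind!r}")
        if self.kind == "qualitative" and len(self.classes) < 2:
            raise PipelineError(
                f"qualitative trait {self.trait_id!r} must declare >=2 classes"
            )


@dataclass(frozen=True)
class TraitCatalog:
    """Registry of traits, partitioned into quantitative and qualitative."""

    traits: tuple[TraitSpec, ...]

    def __post_init__(self) -> None:
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise PipelineError("duplicate trait ids in catalog")

    def __getitem__(self, trait_id: str) -> TraitSpec:
        for t in self.traits:
            if t.trait_id == trait_id:
                return t
        raise KeyError(trait_id)

    def __contains__(self, trait_id: str) -> bool:
        return any(t.trait_id == trait_id for t in self.traits)

    @property
    def quantitative(self) -> tuple[str, ...]:
        return tuple(t.trait_id for t in self.traits if t.kind == "quantitative")

    @property
    def qualitative(self) -> tuple[str, ...]:
        return tuple(t.trait_id for t in self.traits if t.kind == "qualitative")


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format phenotype records.

    ``quantitative``: columns accession_id, trial_id, block_id, trait_id, value.
    ``qualitative``: columns accession_id, year, trait_id, class_code.
    """

    quantitative: pd.DataFrame
    qualitative: pd.DataFrame

    QUANT_COLS = ("accession_id", "trial_id", "block_id", "trait_id", "value")
    QUAL_COLS = ("accession_id", "year", "trait_id", "class_code")

    def __post_init__(self) -> None:
        for df, cols in (
            (self.quantitative, self.QUANT_COLS),
            (self.qualitative, self.QUAL_COLS),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise PipelineError(f"phenotype table missing columns {missing}")
        vals = self.quantitative["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise PipelineError("non-finite quantitative phenotype value")

    def accession_ids(self) -> tuple[str, ...]:
        ids = pd.concat(
            [self.quantitative["accession_id"], self.qualitative["accession_id"]]
        ).unique()
        return tuple(ids)

    def validate(self, catalog: TraitCatalog, registry: Iterable[str] | None = None):
        """Check trait ids, class codes, and optionally the accession registry."""
        reg = set(registry) if registry is not None else None
        for _, rec in self.quantitative.iterrows():
            if rec["trait_id"] not in catalog:
                raise PipelineError(f"unknown trait {rec['trait_id']!r} in record {dict(rec)}")
        for _, rec in self.qualitative.iterrows():
            tid = rec["trait_id"]
            if tid not in catalog:
                raise PipelineError(f"unknown trait {tid!r} in record {dict(rec)}")
            if int(rec["class_code"]) not in catalog[tid].classes:
                raise PipelineError(
                    f"class code {rec['class_code']} outside catalog for trait "
                    f"{tid!r} (record {dict(rec)})"
                )
        if reg is not None:
            unknown = set(self.accession_ids()) - reg
            if unknown:
                raise PipelineError(f"accessions not in registry: {sorted(unknown)[:5]}")
        return self


def read_phenotypes_csv(quant_path, qual_path, catalog: TraitCatalog) -> PhenotypeTable:
    """Read and validate long-format quantitative and qualitative CSVs."""
    quant = pd.read_csv(quant_path, dtype={"accession_id": str, "trial_id": str,
                                           "block_id": str, "trait_id": str})
    qual = pd.read_csv(qual_path, dtype={"accession_id": str, "trait_id": str})
    table = PhenotypeTable(quantitative=quant, qualitative=qual)
    return table.validate(catalog)


def write_phenotypes_csv(table: PhenotypeTable, quant_path, qual_path) -> None:
    table.quantitative.to_csv(quant_path, index=False)
    table.qualitative.to_csv(qual_path, index=False)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionMatrix:
    """Binary accession x method membership matrix, plus optional consolidation."""

    accession_ids: tuple[str, ...]
    method_names: tuple[str, ...]
    membership: np.ndarray  # N x M in {0,1}
    consolidated: np.ndarray | None = None  # N-vector in {0,1}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=np.int8)
        if m.shape != (len(self.accession_ids), len(self.method_names)):
            raise PipelineError("membership shape does not match ids")
        if len(set(self.method_names)) != len(self.method_names):
            raise PipelineError("duplicate method names")
        if not np.isin(m, (0, 1)).all():
            raise PipelineError("membership entries must be 0/1")
        object.__setattr__(self, "membership", m)
        if self.consolidated is not None:
            c = np.asarray(self.consolidated, dtype=np.int8)
            if c.shape != (len(self.accession_ids),) or not np.isin(c, (0, 1)).all():
                raise PipelineError("consolidated vector malformed")
            object.__setattr__(self, "consolidated", c)

    def column(self, method: str) -> np.ndarray:
        return self.membership[:, self.method_names.index(method)]

    def selected_ids(self, method: str) -> tuple[str, ...]:
        col = self.column(method)
        return tuple(a for a, s in zip(self.accession_ids, col) if s)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.membership, index=list(self.accession_ids),
            columns=list(self.method_names),
        )
        if self.consolidated is not None:
            df["consolidated"] = self.consolidated
        return df


def write_selection(sel: SelectionMatrix, path) -> None:
    sel.to_frame().to_csv(path, index_label="accession_id")


def read_selection(path) -> SelectionMatrix:
    df = pd.read_csv(path, index_col=0)
    consolidated = None
    if "consolidated" in df.columns:
        consolidated = df.pop("consolidated").to_numpy(dtype=np.int8)
    return SelectionMatrix(
        accession_ids=tuple(str(i) for i in df.index),
        method_names=tuple(df.columns),
        membership=df.to_numpy(dtype=np.int8),
        consolidated=consolidated,
    )


def write_trait_catalog_csv(catalog: TraitCatalog, path) -> None:
    rows = [
        {
            "trait_id": t.trait_id,
            "kind": t.kind,
            "classes": ";".join(map(str, t.classes)),
            "units": t.units,
        }
        for t in catalog.traits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trait_catalog_csv(path) -> TraitCatalog:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    traits = []
    for _, row in df.iterrows():
        classes = tuple(int(c) for c in row["classes"].split(";") if c != "")
        traits.append(
            TraitSpec(row["trait_id"], row["kind"], classes, row.get("units", ""))
        )
    return TraitCatalog(tuple(traits))
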