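"""Accession-by-accession dissimilarity matrices.

Four kinds are produced, matching the strategies used to drive core
selection:

* **Gower** on mixed consensus phenotypes — per-variable dissimilarity
  (range-normalized absolute difference for quantitative, 0/1 mismatch for
  qualitative), averaged over the variables available for each pair.
* **Modified Rogers** on SNP dosages —
  ``MR_ij = sqrt( (1/2L) sum_l sum_a (p_ila - p_jla)^2 )`` on within-
  individual allele frequencies, which for biallelic loci reduces to
  ``sqrt( (1/L) sum_l dp_l^2 )``.
* **Czekanowski (Manhattan)** on SNP dosages —
  ``(1/2L) sum |x - y|`` over the 2L allele-frequency coordinates, i.e.
  ``(1/L) sum_l |dp_l|`` for biallelic loci.
* **Blended** — a convex combination ``w * phenotypic + (1-w) * genotypic``
  for the pooled-data strategies (default ``w = 0.5``).

All four are symmetric, zero on the diagonal and bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, squareform

from .io_formats import GenotypeMatrix, PipelineError, TraitCatalog, trait_values
from .phenotype_consensus import ConsensusPhenotype

__all__ = [
    "DistanceMatrix",
    "gower_distance",
    "modified_rogers",
    "czekanowski_manhattan",
    "blend_distances",
]

KINDS = ("gower", "modified_rogers", "czekanowski", "blended")


@dataclass(frozen=True)
class DistanceMatrix:
    accession_ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if v.shape != (n, n):
            raise PipelineError("distance matrix shape mismatch")
        if self.kind not in KINDS:
            raise PipelineError(f"unknown distance kind {self.kind!r}")
        if np.isnan(v).any():
            raise PipelineError("distance matrix contains missing entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise PipelineError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise PipelineError("distance matrix diagonal not zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise PipelineError("distance entries outside [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.accession_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="accession_id")

    @classmethod
    def read_csv(cls, path, kind: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float), kind)


def _check_imputed(g: GenotypeMatrix) -> None:
    if g.has_missing():
        raise PipelineError(
            "genotype matrix has missing dosages; impute first (mean_impute)"
        )


# ---------------------------------------------------------------------------
# Gower
# ---------------------------------------------------------------------------


def gower_distance(
    cp: ConsensusPhenotype,
    catalog: TraitCatalog | None = None,
    *,
    ranges: dict[str, float] | None = None,
) -> DistanceMatrix:
    """Gower dissimilarity on the mixed consensus table.

    Quantitative ranges default to the table itself (the complete
    collection); pass ``ranges`` frozen from the complete collection when
    computing distances on a subset so values stay comparable. Constant
    quantitative traits are dropped with a warning; a pair of accessions
    sharing no non-missing trait raises.
    """
    catalog = catalog or cp.catalog
    df = cp.data
    n = len(df)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used = 0
    for spec in catalog.traits:
        if spec.trait_id not in df.columns:
            continue
        x = trait_values(df[spec.trait_id])
        avail = ~np.isnan(x)
        delta = np.outer(avail, avail).astype(float)
        if spec.kind == "quantitative":
            if ranges is not None and spec.trait_id in ranges:
                r = float(ranges[spec.trait_id])
            else:
                r = float(np.nanmax(x) - np.nanmin(x)) if avail.any() else 0.0
            if r <= 0:
                warnings.warn(
                    f"constant quantitative trait {spec.trait_id!r} dropped "
                    "from Gower distance"
                )
                continue
            diff = np.abs(np.subtract.outer(x, x)) / r
        else:
            diff = (np.subtract.outer(x, x) != 0).astype(float)
        diff = np.where(delta > 0, diff, 0.0)
        num += diff
        den += delta
        used += 1
    if used == 0:
        raise PipelineError("no usable traits for Gower distance")
    uncomparable = den == 0
    np.fill_diagonal(uncomparable, False)
    if uncomparable.any():
        i, j = np.argwhere(uncomparable)[0]
        raise PipelineError(
            f"accessions {df.index[i]!r} and {df.index[j]!r} share no "
            "non-missing trait"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(tuple(str(i) for i in df.index), d, "gower")


def complete_ranges(cp: ConsensusPhenotype, catalog: TraitCatalog | None = None) -> dict:
    """Quantitative trait ranges on the complete collection, for freezing."""
    catalog = catalog or cp.catalog
    out = {}
    for t in catalog.quantitative:
        if t in cp.data.columns:
            x = trait_values(cp.data[t])
            out[t] = float(np.nanmax(x) - np.nanmin(x))
    return out


# ---------------------------------------------------------------------------
# SNP distances
# ---------------------------------------------------------------------------


def modified_rogers(g: GenotypeMatrix, *, explicit: bool = False) -> DistanceMatrix:
    """Modified Rogers distance on within-individual allele frequencies.

    The fast path uses the biallelic reduction ``sqrt((1/L) sum dp^2)``; with
    ``explicit=True`` the full double sum over both alleles of every locus is
    evaluated instead (identical to 1e-12; kept as a cross-check).
    """
    _check_imputed(g)
    p = g.dosages.astype(float) / 2.0  # counted-allele frequency per locus
    l = g.n_loci
    if explicit:
        # stack both allele coordinates: (p, 1-p) per locus -> 2L columns
        coords = np.concatenate([p, 1.0 - p], axis=1)
        sq = cdist(coords, coords, metric="sqeuclidean")
        d = np.sqrt(sq / (2.0 * l))
    else:
        sq = cdist(p, p, metric="sqeuclidean")
        d = np.sqrt(sq / l)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(g.accession_ids, d, "modified_rogers")


def czekanowski_manhattan(g: GenotypeMatrix) -> DistanceMatrix:
    """Czekanowski distance: mean absolute allele-frequency difference.

    Computed as ``(1/2L)`` times the Manhattan distance over the 2L allele
    coordinates, which for biallelic loci equals ``(1/L) sum_l |dp_l|``.
    """
    _check_imputed(g)
    p = g.dosages.astype(float) / 2.0
    d = cdist(p, p, metric="cityblock") / g.n_loci
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(g.accession_ids, d, "czekanowski")


def blend_distances(
    d_pheno: DistanceMatrix, d_geno: DistanceMatrix, w: float = 0.5
) -> DistanceMatrix:
    """Convex combination ``w * phenotypic + (1 - w) * genotypic``."""
    if not (0.0 <= w <= 1.0):
        raise PipelineError("blend weight must be in [0, 1]")
    if d_pheno.accession_ids != d_geno.accession_ids:
        raise PipelineError("blend inputs have mismatched accession registries")
    v = w * d_pheno.values + (1.0 - w) * d_geno.values
    return DistanceMatrix(d_pheno.accession_ids, v, "blended")
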