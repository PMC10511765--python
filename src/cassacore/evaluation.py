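"""Diversity-evaluation battery for core collections.

Quantifies how well each collection represents the complete one:

* per-locus observed heterozygosity ``Ho``, within-population gene diversity
  ``Hs`` (with the harmonic-size small-sample correction) and inbreeding
  coefficient ``Fis = 1 - Ho/Hs``;
* allele retention (distinct alleles observed per biallelic locus, <=2);
* normalized Shannon-Weaver indices (entropy over trait classes divided by
  ``ln`` of the class count; quantitative traits binned into six equal-width
  classes over the complete collection's range);
* Cohen's kappa agreement between binary selection vectors;
* per-trait mean/variance comparisons with the complete collection
  (|d mean| > 5% and variance change > 50% flags) and qualitative class
  coverage;
* PCA of phenotype and genotype spaces with per-collection quadrant shares
  on the PC1 x PC2 plane.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .io_formats import (
    GenotypeMatrix,
    PipelineError,
    SelectionMatrix,
    TraitCatalog,
    trait_values,
)
from .phenotype_consensus import ConsensusPhenotype

__all__ = [
    "DiversityStats",
    "genetic_diversity_stats",
    "allele_retention",
    "shannon_weaver",
    "kappa",
    "kappa_matrix",
    "compare_distributions",
    "pca_validate",
]


# ---------------------------------------------------------------------------
# Molecular diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    per_locus: pd.DataFrame  # columns Ho, Hs, Fis (Fis NaN where Hs == 0)
    mean_ho: float
    mean_hs: float
    mean_fis: float  # mean of per-locus Fis over polymorphic loci
    range_ho: tuple[float, float]
    range_hs: tuple[float, float]
    range_fis: tuple[float, float]
    n_monomorphic: int  # loci excluded from the Fis summary
    total_alleles: int
    n_accessions: int


def genetic_diversity_stats(
    g: GenotypeMatrix, subset=None
) -> DiversityStats:
    """Per-locus and summary Ho/Hs/Fis for one collection.

    A single population is assumed (each collection is analyzed on its own),
    so the harmonic sample size reduces to the collection size. ``Hs`` uses
    the small-sample correction

        Hs = n/(n-1) * (1 - sum_i mean(p_i)^2 - Ho/(2n))

    and ``Fis = 1 - Ho/Hs`` wherever ``Hs > 0``; loci monomorphic within the
    collection are excluded from the Fis summary and counted.
    """
    if g.has_missing():
        raise PipelineError("impute missing dosages before diversity analysis")
    dos = g.dosages if subset is None else g.dosages[np.asarray(list(subset), int)]
    n = dos.shape[0]
    if n < 2:
        raise PipelineError("diversity statistics need >=2 accessions")
    ho = (dos == 1).mean(axis=0)
    p = dos.mean(axis=0) / 2.0  # counted-allele frequency
    sum_p2 = p**2 + (1.0 - p) ** 2
    hs = (n / (n - 1.0)) * (1.0 - sum_p2 - ho / (2.0 * n))
    hs = np.clip(hs, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(hs > 0, 1.0 - ho / hs, np.nan)
    poly = hs > 0
    per_locus = pd.DataFrame(
        {"Ho": ho, "Hs": hs, "Fis": fis}, index=list(g.locus_ids)
    )
    alleles = np.where((p > 0) & (p < 1), 2, 1).sum()
    fis_poly = fis[poly]
    return DiversityStats(
        per_locus=per_locus,
        mean_ho=float(ho.mean()),
        mean_hs=float(hs.mean()),
        mean_fis=float(fis_poly.mean()) if poly.any() else float("nan"),
        range_ho=(float(ho.min()), float(ho.max())),
        range_hs=(float(hs.min()), float(hs.max())),
        range_fis=(
            (float(np.nanmin(fis_poly)), float(np.nanmax(fis_poly)))
            if poly.any()
            else (float("nan"), float("nan"))
        ),
        n_monomorphic=int((~poly).sum()),
        total_alleles=int(alleles),
        n_accessions=n,
    )


def allele_retention(g: GenotypeMatrix, subset) -> tuple[int, int, float]:
    """(alleles in subset, alleles in complete, retained fraction).

    Each biallelic locus contributes 2 alleles when polymorphic in the group
    and 1 when fixed.
    """
    if g.has_missing():
        raise PipelineError("impute missing dosages before allele counting")
    idx = np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        raise PipelineError("empty subset")

    def count(dos: np.ndarray) -> int:
        has_counted = (dos > 0).any(axis=0)  # any copy of the counted allele
        has_other = (dos < 2).any(axis=0)
        return int(has_counted.sum() + has_other.sum())

    total = count(g.dosages)
    in_subset = count(g.dosages[idx])
    return in_subset, total, in_subset / total


# ---------------------------------------------------------------------------
# Shannon-Weaver
# ---------------------------------------------------------------------------

N_QUANT_CLASSES = 6


def shannon_weaver(
    values,
    kind: str,
    *,
    classes: tuple[int, ...] | None = None,
    complete_range: tuple[float, float] | None = None,
) -> float:
    """Normalized Shannon-Weaver index ``H' / ln(n_classes)`` in [0, 1].

    Qualitative: frequencies over the *declared* class set (absent classes
    contribute 0 under the 0*log 0 := 0 convention), normalized by the
    declared class count so core and complete indices are comparable.
    Quantitative: six equal-width bins spanning the complete collection's
    [min, max]; out-of-range values clamp to the edge bins.
    """
    x = np.asarray(pd.Series(values).dropna().to_numpy(), dtype=float)
    if x.size == 0:
        raise PipelineError("no observations for Shannon-Weaver index")
    if kind == "qualitative":
        if classes is None or len(classes) < 2:
            raise PipelineError("qualitative ISW needs >=2 declared classes")
        k = len(classes)
        counts = np.array([(x == c).sum() for c in classes], dtype=float)
    elif kind == "quantitative":
        if complete_range is None:
            lo, hi = float(x.min()), float(x.max())
        else:
            lo, hi = map(float, complete_range)
        if hi <= lo:
            return 0.0  # constant trait: monomorphic by definition
        k = N_QUANT_CLASSES
        edges = np.linspace(lo, hi, k + 1)
        bins = np.clip(np.digitize(x, edges[1:-1]), 0, k - 1)
        counts = np.bincount(bins, minlength=k).astype(float)
    else:
        raise PipelineError(f"unknown trait kind {kind!r}")
    p = counts / counts.sum()
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(k))


def isw_report(
    cp: ConsensusPhenotype,
    sel: SelectionMatrix,
    *,
    flag_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per trait x collection normalized Shannon-Weaver indices.

    Collections are each method column plus ``consolidated`` (if present)
    and ``complete``; |ISW - complete ISW| > ``flag_threshold`` is flagged.
    """
    catalog = cp.catalog
    collections = _collections(sel)
    rows = []
    for spec in catalog.traits:
        if spec.trait_id not in cp.data.columns:
            continue
        col = pd.Series(trait_values(cp.data[spec.trait_id]), index=cp.data.index)
        if spec.kind == "quantitative":
            vals = col.to_numpy()
            rng = (np.nanmin(vals), np.nanmax(vals))
            kw = {"complete_range": rng}
        else:
            kw = {"classes": spec.classes}
        base = shannon_weaver(col, spec.kind, **kw)
        for name, members in collections.items():
            sub = col[np.asarray(members, dtype=bool)]
            if sub.dropna().empty:
                continue
            val = shannon_weaver(sub, spec.kind, **kw)
            rows.append(
                {
                    "trait_id": spec.trait_id,
                    "kind": spec.kind,
                    "collection": name,
                    "isw": val,
                    "isw_complete": base,
                    "delta": val - base,
                    "flagged": abs(val - base) > flag_threshold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kappa
# ---------------------------------------------------------------------------


def kappa(sel_a, sel_b) -> float:
    """Cohen's kappa between two binary selection vectors.

    Identical vectors return exactly 1 even when chance agreement ``p_e`` is
    1 (e.g. both vectors all-zero).
    """
    a = np.asarray(sel_a, dtype=int)
    b = np.asarray(sel_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise PipelineError("kappa needs two equal-length vectors of >=2 entries")
    if np.array_equal(a, b):
        return 1.0
    n = a.size
    po = float((a == b).mean())
    pe = float(
        (a == 1).mean() * (b == 1).mean() + (a == 0).mean() * (b == 0).mean()
    )
    if pe >= 1.0:
        return 0.0  # disagreement is impossible only if identical (handled)
    return (po - pe) / (1.0 - pe)


def kappa_matrix(sel: SelectionMatrix, include_consolidated: bool = True) -> pd.DataFrame:
    cols = _collections(sel)
    names = list(cols)
    if not include_consolidated and "consolidated" in names:
        names.remove("consolidated")
    k = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            k[i, j] = k[j, i] = kappa(cols[names[i]], cols[names[j]])
    return pd.DataFrame(k, index=names, columns=names)


# ---------------------------------------------------------------------------
# Phenotypic distribution comparison
# ---------------------------------------------------------------------------


def _collections(sel: SelectionMatrix) -> dict[str, np.ndarray]:
    out = {name: sel.column(name) for name in sel.method_names}
    if sel.consolidated is not None:
        out["consolidated"] = sel.consolidated
    return out


def compare_distributions(
    cp: ConsensusPhenotype,
    sel: SelectionMatrix,
    *,
    mean_flag: float = 0.05,
    var_flag: float = 0.50,
) -> pd.DataFrame:
    """Mean/variance and class-coverage comparison against the complete set.

    Quantitative rows carry relative mean and variance deltas with flags at
    |d mean| > 5% and |d var| > 50%; qualitative rows carry the fraction of
    complete-collection classes present in each core.
    """
    if tuple(cp.data.index) != sel.accession_ids:
        raise PipelineError("consensus table does not cover the selection registry")
    rows = []
    collections = _collections(sel)
    for name, members in collections.items():
        if not members.any():
            raise PipelineError(f"collection {name!r} is empty")
    for spec in cp.catalog.traits:
        if spec.trait_id not in cp.data.columns:
            continue
        col = pd.Series(trait_values(cp.data[spec.trait_id]), index=cp.data.index)
        full = col.dropna()
        for name, members in collections.items():
            sub = col[np.asarray(members, dtype=bool)].dropna()
            if sub.empty:
                continue
            if spec.kind == "quantitative":
                m0, v0 = full.mean(), full.var(ddof=1)
                m1, v1 = sub.mean(), sub.var(ddof=1)
                dm = (m1 - m0) / abs(m0) if m0 != 0 else np.nan
                dv = (v1 - v0) / v0 if v0 > 0 else np.nan
                rows.append(
                    {
                        "trait_id": spec.trait_id,
                        "kind": spec.kind,
                        "collection": name,
                        "complete_mean": m0,
                        "core_mean": m1,
                        "complete_var": v0,
                        "core_var": v1,
                        "rel_mean_diff": dm,
                        "rel_var_diff": dv,
                        "mean_flag": bool(abs(dm) > mean_flag) if np.isfinite(dm) else False,
                        "var_flag": bool(abs(dv) > var_flag) if np.isfinite(dv) else False,
                        "class_coverage": np.nan,
                    }
                )
            else:
                present_full = set(full.astype(int).unique())
                present_sub = set(sub.astype(int).unique())
                cov = len(present_sub & present_full) / len(present_full)
                rows.append(
                    {
                        "trait_id": spec.trait_id,
                        "kind": spec.kind,
                        "collection": name,
                        "complete_mean": np.nan,
                        "core_mean": np.nan,
                        "complete_var": np.nan,
                        "core_var": np.nan,
                        "rel_mean_diff": np.nan,
                        "rel_var_diff": np.nan,
                        "mean_flag": False,
                        "var_flag": False,
                        "class_coverage": cov,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA validation
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # accessions x components
    variance_explained: np.ndarray  # percentages, non-increasing
    quadrant_shares: pd.DataFrame  # collections x 4 quadrants (rows sum to 1)
    space: str  # "phenotype" | "genotype"


def _quadrant_shares(scores: np.ndarray, collections: dict) -> pd.DataFrame:
    pc1, pc2 = scores[:, 0], scores[:, 1]
    quads = (pc1 >= 0).astype(int) * 1 + (pc2 >= 0).astype(int) * 2
    rows = {}
    for name, members in collections.items():
        mask = np.asarray(members, dtype=bool)
        counts = np.bincount(quads[mask], minlength=4).astype(float)
        rows[name] = counts / counts.sum() if counts.sum() else counts
    return pd.DataFrame(rows, index=["Q--", "Q+-", "Q-+", "Q++"]).T


def _pca(x: np.ndarray, ids, collections, space: str, n_components: int) -> PcaResult:
    from sklearn.decomposition import PCA

    if x.shape[1] < 2 or np.allclose(x.var(axis=0).sum(), 0):
        raise PipelineError("zero-variance feature set for PCA")
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    ve = pca.explained_variance_ratio_ * 100.0
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=list(ids), columns=[f"PC{i + 1}" for i in range(k)]
        ),
        variance_explained=ve,
        quadrant_shares=_quadrant_shares(scores, collections),
        space=space,
    )


def pca_validate(
    cp: ConsensusPhenotype | None,
    g: GenotypeMatrix | None,
    sel: SelectionMatrix,
    n_components: int = 10,
) -> dict[str, PcaResult]:
    """PCA of phenotype and genotype spaces with collection quadrant shares.

    Phenotype space standardizes quantitative traits and one-hot encodes
    qualitative ones (then centers); genotype space centers the dosage
    matrix. Either input may be None to skip that space.
    """
    collections = dict(_collections(sel))
    collections["complete"] = np.ones(len(sel.accession_ids), dtype=np.int8)
    out = {}
    if cp is not None:
        if tuple(cp.data.index) != sel.accession_ids:
            raise PipelineError("consensus registry mismatch")
        feats = []
        for spec in cp.catalog.traits:
            if spec.trait_id not in cp.data.columns:
                continue
            col = pd.Series(trait_values(cp.data[spec.trait_id]), index=cp.data.index)
            filled = col.fillna(col.mean() if spec.kind == "quantitative" else col.mode().iloc[0])
            if spec.kind == "quantitative":
                v = filled.to_numpy()
                sd = v.std()
                if sd > 0:
                    feats.append((v - v.mean()) / sd)
            else:
                for c in spec.classes:
                    onehot = (filled.to_numpy() == c).astype(float)
                    feats.append(onehot - onehot.mean())
        if not feats:
            raise PipelineError("zero-variance feature set for PCA")
        x = np.column_stack(feats)
        out["phenotype"] = _pca(x, cp.data.index, collections, "phenotype", n_components)
    if g is not None:
        if g.accession_ids != sel.accession_ids:
            raise PipelineError("genotype registry mismatch")
        if g.has_missing():
            raise PipelineError("impute before PCA")
        x = g.dosages.astype(float)
        x = x - x.mean(axis=0)
        out["genotype"] = _pca(x, g.accession_ids, collections, "genotype", n_components)
    return out
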