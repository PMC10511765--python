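"""Synthetic germplasm generator.

Emulates the statistical structure of a clonally propagated, outcrossing
germplasm bank: subpopulation-structured biallelic SNP genotypes with excess
heterozygosity (negative within-collection Fis), multi-environment
quantitative trials following ``y = Zg + Wb + Ti + e``, and multi-class
qualitative descriptors observed over several years, including rare classes.

Subpopulation allele frequencies follow the Balding–Nichols model: given an
ancestral frequency ``p`` and a differentiation parameter ``F`` (an Fst-like
drift variance), each subpopulation draws its frequency from
``Beta(p (1-F)/F, (1-p)(1-F)/F)``, so E[freq] = p and Var = F p (1-p).
Excess heterozygosity is produced by forcing a heterozygote with probability
``h_excess`` at polymorphic loci — the simplest mechanism reproducing the
negative Fis typical of clonal collections of outcrossers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenotypeMatrix,
    PhenotypeTable,
    PipelineError,
    TraitCatalog,
    TraitSpec,
)

__all__ = [
    "PopulationModel",
    "QuantitativeTraitModel",
    "QualitativeTraitModel",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_quantitative_trials",
    "simulate_qualitative_observations",
    "default_scenario",
]


@dataclass(frozen=True)
class PopulationModel:
    """Population-level parameters for genotype simulation.

    Defaults describe the study conditions this pipeline is exercised under:
    a moderately structured clonal collection (K=3, differentiation 0.05)
    with heterozygote excess tuned so that the realized within-collection
    Fis is near -0.23.
    """

    n_accessions: int = 300
    n_loci: int = 500
    n_subpops: int = 3
    mixture: tuple[float, ...] | None = None  # default: equal proportions
    differentiation: float = 0.05  # Balding–Nichols F (Fst-like)
    maf_min: float = 0.05  # ancestral MAF ~ U(maf_min, 0.5)
    h_excess: float = 0.3  # P(force heterozygote) at polymorphic loci
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.mixture
        if props is None:
            props = tuple([1.0 / self.n_subpops] * self.n_subpops)
            object.__setattr__(self, "mixture", props)
        if len(props) != self.n_subpops:
            raise PipelineError("mixture length must equal n_subpops")
        if abs(sum(props) - 1.0) > 1e-9:
            raise PipelineError("mixture proportions must sum to 1")
        if not (0 < self.maf_min <= 0.5):
            raise PipelineError("maf_min must be in (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise PipelineError("missing_rate must be in [0, 1)")
        if not (0 <= self.h_excess <= 1):
            raise PipelineError("h_excess must be in [0, 1]")
        if self.n_subpops > self.n_accessions:
            raise PipelineError("more subpopulations than accessions")


@dataclass(frozen=True)
class QuantitativeTraitModel:
    """Variance-component parameters for one quantitative trait."""

    trait_id: str
    n_causal_loci: int = 50
    var_genotype: float = 1.0  # sigma_g^2
    var_block: float = 0.25  # sigma_b^2, blocks nested in trials
    var_interaction: float = 0.25  # sigma_i^2, genotype x trial
    var_error: float = 1.0  # sigma_e^2
    n_trials: int = 3
    blocks_per_trial: int = 2
    replicates: int = 1  # records per accession per block

    def __post_init__(self) -> None:
        for v in (self.var_genotype, self.var_block, self.var_interaction, self.var_error):
            if v < 0:
                raise PipelineError("variance components must be >= 0")
        if self.n_trials < 1:
            raise PipelineError("need at least one trial")


@dataclass(frozen=True)
class QualitativeTraitModel:
    """Class-frequency parameters for one qualitative descriptor."""

    trait_id: str
    class_frequencies: tuple[float, ...]
    n_years: int = 3
    misclassification_rate: float = 0.05

    def __post_init__(self) -> None:
        f = np.asarray(self.class_frequencies, dtype=float)
        if (f < 0).any():
            raise PipelineError("class frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise PipelineError("class frequencies must sum to 1")
        if len(f) < 2:
            raise PipelineError("need >=2 classes")
        if self.n_years < 1:
            raise PipelineError("need >=1 observation year")
        if not (0 <= self.misclassification_rate < 1):
            raise PipelineError("misclassification rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset (for recovery tests)."""

    accession_ids: tuple[str, ...] = ()
    subpop_labels: np.ndarray | None = None
    genetic_values: pd.DataFrame | None = None  # accession x quantitative trait
    modal_classes: pd.DataFrame | None = None  # accession x qualitative trait


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(model: PopulationModel) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw structured biallelic genotypes under the Balding–Nichols model.

    Each accession's subpopulation is drawn from the mixture; its genotype at
    each locus is a Hardy–Weinberg binomial draw at the subpopulation allele
    frequency, then forced heterozygous with probability ``h_excess`` where
    the subpopulation frequency is polymorphic. Bit-reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(model.seed)
    n, l, k = model.n_accessions, model.n_loci, model.n_subpops
    labels = rng.choice(k, size=n, p=np.asarray(model.mixture))
    p_anc = rng.uniform(model.maf_min, 0.5, size=l)
    f = model.differentiation
    if f > 0:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a[None, :], b[None, :], size=(k, l))
    else:
        p_sub = np.broadcast_to(p_anc, (k, l)).copy()
    p_acc = p_sub[labels]  # N x L
    dosages = rng.binomial(2, p_acc).astype(np.int8)
    if model.h_excess > 0:
        polymorphic = (p_acc > 0) & (p_acc < 1)
        force = polymorphic & (rng.random((n, l)) < model.h_excess)
        dosages[force] = 1
    if model.missing_rate > 0:
        miss = rng.random((n, l)) < model.missing_rate
        # keep >=1 call per locus so mean imputation stays defined
        all_missing = miss.all(axis=0)
        miss[0, all_missing] = False
        dosages[miss] = MISSING
    ids = tuple(f"ACC{i:05d}" for i in range(n))
    loci = tuple(f"chr{1 + j % 18}:{1000 + j}" for j in range(l))
    g = GenotypeMatrix(accession_ids=ids, locus_ids=loci, dosages=dosages)
    truth = GroundTruth(accession_ids=ids, subpop_labels=labels)
    return g, truth


# ---------------------------------------------------------------------------
# Quantitative trials
# ---------------------------------------------------------------------------


def simulate_quantitative_trials(
    g: GenotypeMatrix, model: QuantitativeTraitModel, seed: int
) -> tuple[PhenotypeTable, GroundTruth]:
    """Simulate multi-environment trial records ``y = g + b + i + e``.

    The genetic value ``g`` of each accession is an additive score over
    ``n_causal_loci`` randomly chosen loci, standardized to variance
    ``var_genotype`` across accessions; block, interaction and error terms
    are independent normals at their declared variances.
    """
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    n_causal = min(model.n_causal_loci, g.n_loci)
    causal = rng.choice(g.n_loci, size=n_causal, replace=False)
    beta = rng.normal(size=n_causal)
    dos = g.dosages[:, causal].astype(float)
    dos[dos == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    raw = (dos - col_mean) @ beta
    sd = raw.std()
    if model.var_genotype > 0 and sd > 0:
        gv = raw / sd * np.sqrt(model.var_genotype)
    else:
        gv = np.zeros(n)

    blocks = {}  # (trial, block) -> effect
    records = []
    sb, si, se = (
        np.sqrt(model.var_block),
        np.sqrt(model.var_interaction),
        np.sqrt(model.var_error),
    )
    inter = rng.normal(0.0, si, size=(n, model.n_trials)) if si > 0 else np.zeros(
        (n, model.n_trials)
    )
    for t in range(model.n_trials):
        trial_id = f"T{t + 1}"
        for b in range(model.blocks_per_trial):
            block_id = f"B{b + 1}"
            blocks[(trial_id, block_id)] = rng.normal(0.0, sb) if sb > 0 else 0.0
    for t in range(model.n_trials):
        trial_id = f"T{t + 1}"
        for b in range(model.blocks_per_trial):
            block_id = f"B{b + 1}"
            be = blocks[(trial_id, block_id)]
            for _ in range(model.replicates):
                e = rng.normal(0.0, se, size=n) if se > 0 else np.zeros(n)
                y = gv + be + inter[:, t] + e
                for i, acc in enumerate(g.accession_ids):
                    records.append(
                        (acc, trial_id, block_id, model.trait_id, y[i])
                    )
    quant = pd.DataFrame(records, columns=list(PhenotypeTable.QUANT_COLS))
    table = PhenotypeTable(
        quantitative=quant,
        qualitative=pd.DataFrame(columns=list(PhenotypeTable.QUAL_COLS)),
    )
    truth = GroundTruth(
        accession_ids=g.accession_ids,
        genetic_values=pd.DataFrame({model.trait_id: gv}, index=list(g.accession_ids)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Qualitative descriptors
# ---------------------------------------------------------------------------


def simulate_qualitative_observations(
    model: QualitativeTraitModel, n_accessions: int, seed: int
) -> tuple[PhenotypeTable, GroundTruth]:
    """Simulate per-year qualitative class observations.

    Each accession carries a latent class drawn from the frequency vector;
    each year it is observed correctly with probability ``1 - m`` and
    otherwise uniformly over the other classes.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(model.class_frequencies, dtype=float)
    classes = np.arange(1, len(freqs) + 1)
    latent = rng.choice(classes, size=n_accessions, p=freqs)
    ids = tuple(f"ACC{i:05d}" for i in range(n_accessions))
    records = []
    m = model.misclassification_rate
    for year in range(model.n_years):
        obs = latent.copy()
        if m > 0:
            flip = rng.random(n_accessions) < m
            for i in np.flatnonzero(flip):
                others = classes[classes != latent[i]]
                obs[i] = rng.choice(others)
        for i, acc in enumerate(ids):
            records.append((acc, 2011 + year, model.trait_id, int(obs[i])))
    qual = pd.DataFrame(records, columns=list(PhenotypeTable.QUAL_COLS))
    table = PhenotypeTable(
        quantitative=pd.DataFrame(columns=list(PhenotypeTable.QUANT_COLS)),
        qualitative=qual,
    )
    truth = GroundTruth(
        accession_ids=ids,
        modal_classes=pd.DataFrame({model.trait_id: latent}, index=list(ids)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Default study scenario
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    catalog: TraitCatalog
    truth: GroundTruth


def default_scenario(
    seed: int,
    *,
    n_accessions: int = 300,
    n_loci: int = 500,
    n_quantitative: int = 3,
    n_qualitative: int = 4,
) -> SyntheticStudy:
    """Generate a complete synthetic study: genotypes, trials, descriptors.

    One qualitative descriptor carries a rare class at frequency 0.0188,
    matching the rare-class regime the evaluation battery must handle.
    """
    rng = np.random.default_rng(seed)
    pop = PopulationModel(n_accessions=n_accessions, n_loci=n_loci, seed=seed)
    g, truth = simulate_genotypes(pop)

    quant_frames, gv_cols = [], {}
    traits: list[TraitSpec] = []
    for q in range(n_quantitative):
        tm = QuantitativeTraitModel(trait_id=f"QT{q + 1}")
        tbl, tr = simulate_quantitative_trials(g, tm, seed=int(rng.integers(2**31)))
        quant_frames.append(tbl.quantitative)
        gv_cols[tm.trait_id] = tr.genetic_values[tm.trait_id]
        traits.append(TraitSpec(tm.trait_id, "quantitative", units="a.u."))

    qual_frames, modal_cols = [], {}
    for q in range(n_qualitative):
        if q == 0:
            freqs = (0.0188, 0.4812, 0.5)  # rare class regime
        else:
            k = int(rng.integers(3, 7))
            w = rng.dirichlet(np.full(k, 2.0))
            freqs = tuple(w / w.sum())
        qm = QualitativeTraitModel(trait_id=f"QL{q + 1}", class_frequencies=freqs)
        tbl, tr = simulate_qualitative_observations(
            qm, n_accessions, seed=int(rng.integers(2**31))
        )
        qual_frames.append(tbl.qualitative)
        modal_cols[qm.trait_id] = tr.modal_classes[qm.trait_id]
        traits.append(
            TraitSpec(qm.trait_id, "qualitative", tuple(range(1, len(freqs) + 1)))
        )

    phen = PhenotypeTable(
        quantitative=pd.concat(quant_frames, ignore_index=True),
        qualitative=pd.concat(qual_frames, ignore_index=True),
    )
    truth.genetic_values = pd.DataFrame(gv_cols)
    truth.modal_classes = pd.DataFrame(modal_cols)
    return SyntheticStudy(
        genotypes=g, phenotypes=phen, catalog=TraitCatalog(tuple(traits)), truth=truth
    )
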