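"""Consensus phenotypes: modal classes and mixed-model genetic values.

Multi-year qualitative observations collapse to the per-accession mode;
multi-environment quantitative records collapse to BLUPs of the random
genotype effect under the linear mixed model

    y = 1*mu + Z g + W b + T i + e

with genotype ``g ~ N(0, sigma_g^2)``, block-within-trial
``b ~ N(0, sigma_b^2)``, genotype-by-trial interaction
``i ~ N(0, sigma_i^2)`` and residual ``e ~ N(0, sigma_e^2)`` — all random,
a single fixed intercept. Variance components are estimated by EM-REML
(monotone, non-negativity preserving) and BLUPs are solved from Henderson's
mixed-model equations at the converged components.

The mixed-model equations are solved by Schur complement on the interaction
block, which is diagonal, so each EM sweep costs one dense factorization of
the (intercept + blocks + genotypes) system only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhenotypeTable, PipelineError, TraitCatalog

__all__ = [
    "MixedModelResult",
    "ConsensusPhenotype",
    "qualitative_mode",
    "fit_mixed_model",
    "assemble_consensus",
]

_VAR_FLOOR = 1e-12


@dataclass
class MixedModelResult:
    trait_id: str
    genetic_values: pd.Series  # BLUPs, indexed by accession id
    components: dict  # genotype/block/interaction/error variances
    intercept: float
    converged: bool
    n_iter: int
    notes: tuple[str, ...] = ()


def qualitative_mode(records: pd.DataFrame, trait_id: str) -> pd.Series:
    """Per-accession modal class for one qualitative trait.

    Ties break to the lowest class code; accessions without observations are
    simply absent from the result (callers keep them as missing cells).
    """
    sub = records[records["trait_id"] == trait_id]
    if sub.empty:
        return pd.Series(dtype="Int64", name=trait_id)
    counts = (
        sub.groupby(["accession_id", "class_code"]).size().reset_index(name="n")
    )
    # sort: highest count first, then lowest class code — first row per
    # accession is the deterministic mode
    counts = counts.sort_values(
        ["accession_id", "n", "class_code"], ascending=[True, False, True]
    )
    modes = counts.drop_duplicates("accession_id").set_index("accession_id")[
        "class_code"
    ]
    modes.name = trait_id
    return modes.astype("Int64")


# ---------------------------------------------------------------------------
# EM-REML for the all-random crossed model
# ---------------------------------------------------------------------------


def _design(sub: pd.DataFrame):
    """Integer codings for genotype, block-within-trial and genotype x trial."""
    geno = pd.Categorical(sub["accession_id"])
    block_key = sub["trial_id"].astype(str) + "//" + sub["block_id"].astype(str)
    block = pd.Categorical(block_key)
    inter_key = sub["accession_id"].astype(str) + "//" + sub["trial_id"].astype(str)
    inter = pd.Categorical(inter_key)
    return geno, block, inter


def fit_mixed_model(
    table: PhenotypeTable,
    trait_id: str,
    *,
    fixed_components: dict | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixedModelResult:
    """Fit the all-random mixed model for one quantitative trait.

    Parameters
    ----------
    fixed_components
        Mapping with any of ``genotype``, ``block``, ``interaction``,
        ``error``; components given here are held fixed (no EM update), which
        also allows solving the mixed-model equations at a known variance
        ratio. Components absent from the mapping are estimated.
    """
    sub = table.quantitative[table.quantitative["trait_id"] == trait_id]
    if sub.empty:
        raise PipelineError(f"no quantitative records for trait {trait_id!r}")
    y = sub["value"].to_numpy(dtype=float)
    geno, block, inter = _design(sub)
    ng, nb = len(geno.categories), len(block.categories)
    n_trials = sub["trial_id"].nunique()
    notes: list[str] = []
    if ng < 2:
        raise PipelineError(f"trait {trait_id!r} has <2 genotype levels")

    use_inter = n_trials > 1
    if not use_inter:
        notes.append("single-trial data: interaction component fixed at 0")
    cg = np.asarray(geno.codes)
    cb = np.asarray(block.codes)
    ci = np.asarray(inter.codes)
    n = len(y)
    ni = len(inter.categories) if use_inter else 0

    # ---- fixed parts of the mixed-model equations ----------------------
    ns = 1 + nb + ng  # intercept | blocks | genotypes ("small" block)
    counts_g = np.bincount(cg, minlength=ng).astype(float)
    counts_b = np.bincount(cb, minlength=nb).astype(float)
    A0 = np.zeros((ns, ns))
    A0[0, 0] = n
    A0[0, 1 : 1 + nb] = A0[1 : 1 + nb, 0] = counts_b
    A0[0, 1 + nb :] = A0[1 + nb :, 0] = counts_g
    A0[1 + np.arange(nb), 1 + np.arange(nb)] = counts_b
    A0[1 + nb + np.arange(ng), 1 + nb + np.arange(ng)] = counts_g
    bg = np.zeros((nb, ng))
    np.add.at(bg, (cb, cg), 1.0)
    A0[1 : 1 + nb, 1 + nb :] = bg
    A0[1 + nb :, 1 : 1 + nb] = bg.T
    rhs_small = np.concatenate(
        ([y.sum()], np.bincount(cb, weights=y, minlength=nb),
         np.bincount(cg, weights=y, minlength=ng))
    )
    if use_inter:
        counts_i = np.bincount(ci, minlength=ni).astype(float)
        B = np.zeros((ns, ni))
        B[0] = counts_i
        np.add.at(B, (1 + cb, ci), 1.0)
        # each interaction level belongs to exactly one genotype
        gi = np.full(ni, -1, dtype=int)
        gi[ci] = cg
        B[1 + nb + gi, np.arange(ni)] += counts_i
        rhs_i = np.bincount(ci, weights=y, minlength=ni)
    yty = float(y @ y)

    # ---- starting values / fixed components -----------------------------
    vy = max(float(np.var(y)), _VAR_FLOOR)
    comp = {"genotype": vy / 3, "block": vy / 6, "interaction": vy / 6, "error": vy / 3}
    fixed = dict(fixed_components or {})
    if not use_inter:
        fixed["interaction"] = 0.0
    comp.update(fixed)
    free = [k for k in comp if k not in fixed]

    def solve(comp):
        se = max(comp["error"], _VAR_FLOOR)
        lam_g = se / max(comp["genotype"], _VAR_FLOOR)
        lam_b = se / max(comp["block"], _VAR_FLOOR)
        A = A0.copy()
        A[1 + np.arange(nb), 1 + np.arange(nb)] += lam_b
        A[1 + nb + np.arange(ng), 1 + nb + np.arange(ng)] += lam_g
        if use_inter:
            lam_i = se / max(comp["interaction"], _VAR_FLOOR)
            d = counts_i + lam_i
            Bd = B / d
            S = A - Bd @ B.T
            r_small = rhs_small - Bd @ rhs_i
        else:
            S = A
            r_small = rhs_small
        try:
            M = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            M = np.linalg.pinv(S)
        x_small = M @ r_small
        if use_inter:
            x_i = (rhs_i - B.T @ x_small) / d
        else:
            x_i, d, Bd = None, None, None
        return M, x_small, x_i, d

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M, x_small, x_i, d = solve(comp)
        mu = x_small[0]
        u_b = x_small[1 : 1 + nb]
        u_g = x_small[1 + nb :]
        se = max(comp["error"], _VAR_FLOOR)
        new = dict(comp)
        if "genotype" not in fixed:
            tr_gg = np.trace(M[1 + nb :, 1 + nb :])
            new["genotype"] = (u_g @ u_g + se * tr_gg) / ng
        if "block" not in fixed:
            tr_bb = np.trace(M[1 : 1 + nb, 1 : 1 + nb])
            new["block"] = (u_b @ u_b + se * tr_bb) / nb
        if use_inter and "interaction" not in fixed:
            # tr(C^ii) from the Schur identity: D^-1 + D^-1 B' M B D^-1
            diag_BtMB = np.einsum("ij,ij->j", B, M @ B)
            tr_ii = np.sum(1.0 / d) + np.sum(diag_BtMB / d**2)
            new["interaction"] = (x_i @ x_i + se * tr_ii) / ni
        if "error" not in fixed:
            ssr = yty - x_small @ rhs_small
            if use_inter:
                ssr -= x_i @ rhs_i
            new["error"] = max(ssr / (n - 1), _VAR_FLOOR)  # rank(X) = 1
        # relative change; components that have collapsed to (numerical)
        # zero are excluded — their sub-floor wiggle is meaningless
        zero_tol = 1e-8 * vy
        rel = max(
            (
                abs(new[k] - comp[k]) / max(abs(comp[k]), zero_tol)
                for k in free
                if not (new[k] < zero_tol and comp[k] < zero_tol)
            ),
            default=0.0,
        )
        comp = new
        if rel < tol:
            converged = True
            break
    if not converged and free:
        warnings.warn(
            f"EM-REML did not converge for trait {trait_id!r} after {it} "
            "iterations; returning last iterate"
        )
        notes.append("EM-REML not converged; last iterate returned")

    M, x_small, x_i, d = solve(comp)
    blups = pd.Series(
        x_small[1 + nb :], index=list(geno.categories), name=trait_id
    )
    return MixedModelResult(
        trait_id=trait_id,
        genetic_values=blups,
        components={
            "genotype": comp["genotype"],
            "block": comp["block"],
            "interaction": comp["interaction"] if use_inter else 0.0,
            "error": comp["error"],
        },
        intercept=float(x_small[0]),
        converged=converged or not free,
        n_iter=it,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Consensus assembly
# ---------------------------------------------------------------------------


@dataclass
class ConsensusPhenotype:
    """Accession x trait consensus table.

    Qualitative cells hold modal class codes (nullable ints), quantitative
    cells hold BLUP genetic values; missing cells stay missing and are
    handled downstream by Gower availability weighting.
    """

    data: pd.DataFrame
    catalog: TraitCatalog
    variance_components: dict = field(default_factory=dict)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)


def assemble_consensus(
    modes: dict[str, pd.Series],
    blups: dict[str, pd.Series],
    catalog: TraitCatalog,
    registry: tuple[str, ...] | None = None,
    variance_components: dict | None = None,
) -> ConsensusPhenotype:
    """Combine modal classes and genetic values into one consensus table.

    ``registry`` fixes the accession universe; inputs naming accessions
    outside it raise. Accessions missing a trait keep a missing cell.
    """
    if not modes and not blups:
        raise PipelineError("empty trait set")
    observed: set[str] = set()
    for s in list(modes.values()) + list(blups.values()):
        observed.update(map(str, s.index))
    if registry is None:
        registry = tuple(sorted(observed))
    else:
        extra = observed - set(registry)
        if extra:
            raise PipelineError(
                f"accessions outside the registry: {sorted(extra)[:5]}"
            )
    df = pd.DataFrame(index=list(registry))
    for trait_id, s in blups.items():
        df[trait_id] = s.reindex(df.index).astype(float)
    for trait_id, s in modes.items():
        df[trait_id] = s.reindex(df.index).astype("Int64")
    return ConsensusPhenotype(
        data=df, catalog=catalog, variance_components=dict(variance_components or {})
    )


def consensus_from_table(
    table: PhenotypeTable,
    catalog: TraitCatalog,
    registry: tuple[str, ...] | None = None,
    **fit_kwargs,
) -> ConsensusPhenotype:
    """One-call consensus: modes for qualitative, BLUPs for quantitative."""
    modes = {
        t: qualitative_mode(table.qualitative, t)
        for t in catalog.qualitative
        if (table.qualitative["trait_id"] == t).any()
    }
    blups, vcs = {}, {}
    for t in catalog.quantitative:
        if not (table.quantitative["trait_id"] == t).any():
            continue
        res = fit_mixed_model(table, t, **fit_kwargs)
        blups[t] = res.genetic_values
        vcs[t] = res.components
    return assemble_consensus(modes, blups, catalog, registry, vcs)
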