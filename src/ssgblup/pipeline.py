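"""Orchestration helpers tying QC, relationships, models and validation.

These are the pieces the command-line interface and the analysis
scripts share: building the right relationship structure for each
model variant and running one evaluation end to end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import evaluate as ev
from .genomic import GenotypeMatrix, RelationshipSet, qc_filter, single_step_relationships
from .mme import (
    EvaluationResult,
    ModelSpec,
    VarianceComponents,
    pedigree_subset,
    run_evaluation,
    run_within_breed,
)
from .pedigree import PedigreeTable

log = logging.getLogger("ssgblup")

__all__ = [
    "qc_with_logging",
    "model_relationships",
    "evaluate_model",
    "truncation_validation",
]


def qc_with_logging(genos: GenotypeMatrix, maf_min=0.01, callrate_min=0.98):
    kept, filtered = qc_filter(genos, maf_min=maf_min, callrate_min=callrate_min,
                               single_breed=len(genos.breeds()) < 2)
    log.info(
        "QC: %d SNPs validated out of %d (MAF > %g and call rate > %g in every breed)",
        len(kept), genos.n_snps, maf_min, callrate_min,
    )
    return kept, filtered


def model_relationships(
    ped: PedigreeTable,
    genos: GenotypeMatrix,
    kind: str,
    tau: float = 0.95,
    scaling: str = "mean_matching",
):
    """Relationship structures for one model variant.

    multi_breed / multiple_trait: one pooled-frequency H over the full
    pedigree.  within_breed: per-breed H from each breed's own allele
    frequencies over that breed's pedigree subset (the SNP set is the
    common QC-validated set).  Returns a RelationshipSet or a dict
    breed -> (pedigree subset, RelationshipSet).
    """
    if kind in ("multi_breed", "multiple_trait"):
        return single_step_relationships(
            ped, genos, freq_source="pooled", tau=tau, scaling=scaling
        )
    if kind == "within_breed":
        out = {}
        for b in genos.breeds():
            ped_b = pedigree_subset(ped, ped.breed == b)
            gen_b = genos.subset(animal_mask=genos.breed == b)
            out[b] = (
                ped_b,
                single_step_relationships(
                    ped_b, gen_b, freq_source="per_breed", tau=tau, scaling=scaling
                ),
            )
        return out
    raise ValueError(f"unknown model kind {kind!r}")


def evaluate_model(
    phenos: pd.DataFrame,
    ped: PedigreeTable,
    rels,
    kind: str,
    vc: VarianceComponents,
    spec: ModelSpec | None = None,
    rho: float | None = None,
    pev: bool = False,
) -> EvaluationResult:
    """Run one model variant on prepared relationships.

    ``rho`` overrides the across-breed correlation for the
    multiple-trait variant (e.g. 0, the REML estimate, or 0.99).
    """
    if spec is None:
        spec = ModelSpec(kind=kind)
    else:
        spec = ModelSpec(
            kind=kind, trait=spec.trait, fixed_effects=spec.fixed_effects,
            intercept=spec.intercept, repeatable=spec.repeatable,
            weight_col=spec.weight_col, breed_fixed=spec.breed_fixed,
        )
    if kind == "within_breed":
        rel_by_breed = {b: (pb, rs.h_inv) for b, (pb, rs) in rels.items()}
        hd = {b: rs.h_diag for b, (pb, rs) in rels.items()}
        return run_within_breed(
            phenos, ped, rel_by_breed, spec, vc, pev=pev, h_diag_by_breed=hd
        )
    if kind == "multiple_trait":
        if rho is not None:
            vc = vc.with_rho(min(max(rho, -0.99), 0.99))
        spec.rho_mode = rho
    assert isinstance(rels, RelationshipSet)
    return run_evaluation(phenos, ped, rels.h_inv, spec, vc, pev=pev, h_diag=rels.h_diag)


def truncation_validation(
    phenos: pd.DataFrame,
    ped: PedigreeTable,
    genos: GenotypeMatrix,
    vc_by_kind: dict,
    train_years: tuple,
    validation_years: tuple,
    kinds=("multi_breed", "within_breed", "multiple_trait"),
    rho_levels=(None,),
    spec: ModelSpec | None = None,
    tau: float = 0.95,
    truncation_year: int | None = None,
) -> pd.DataFrame:
    """Full cross-validation table for the requested model variants.

    DYD come from a full-data run of the multi-breed model; validation
    GEBV from truncated re-runs.  Within-breed GEBV are centered on
    the overall average before pooling.  Returns one row per model
    (and rho level) with Pearson r, slope and slope SE.
    """
    base_spec = spec or ModelSpec(kind="multi_breed")
    males = ped.sex == "M"
    train, valid, cutoff = ev.split_by_birth_year(
        ped.ids[males], ped.birth_year[males], train_years, validation_years,
        truncation_year=truncation_year,
    )
    ph_train = ev.truncate_phenotypes(phenos, ped, cutoff)

    # full-data reference run: yields YD, dam EBV and hence DYD
    rel_full = model_relationships(ped, genos, "multi_breed", tau=tau)
    full = evaluate_model(phenos, ped, rel_full, "multi_breed", vc_by_kind["multi_breed"],
                          spec=base_spec)
    yd = ev.yield_deviations(phenos, full.solutions["all"])
    dyd = ev.compute_dyd(yd, ped, full.gebv_series())
    dyd_s = dyd.set_index("sire")["dyd"]
    valid_with_dyd = [s for s in valid if s in dyd_s.index]
    log.info("validation split: %d training, %d validation males (%d with DYD); "
             "phenotypes truncated at birth year %d",
             len(train), len(valid), len(valid_with_dyd), cutoff)

    rows = []
    rel_cache = {}
    for kind in kinds:
        rel_cache.setdefault(kind, model_relationships(ped, genos, kind, tau=tau)
                             if kind != "multiple_trait" else rel_full)
        levels = rho_levels if kind == "multiple_trait" else (None,)
        for rho in levels:
            res = evaluate_model(ph_train, ped, rel_cache[kind], kind,
                                 vc_by_kind[kind], spec=base_spec, rho=rho)
            frame = res.frame
            if kind == "within_breed":
                frame = ev.center_gebv(frame, scope="overall")
            gebv = frame.set_index("animal")["gebv"].loc[valid_with_dyd]
            r = ev.pearson_validation(gebv, dyd_s)
            slope, intercept, se = ev.regression_dyd_on_gebv(gebv, dyd_s)
            rows.append({
                "model": kind,
                "rho": np.nan if rho is None else rho,
                "n_validation_males": len(valid_with_dyd),
                "pearson_r": r,
                "slope": slope,
                "slope_se": se,
            })
    return pd.DataFrame(rows)
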