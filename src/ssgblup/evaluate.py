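"""Cross-validation and accuracy assessment for genomic evaluations.

Implements the standard dairy validation design: progeny-tested males
are split by birth year into training and validation sets, GEBV are
re-estimated from phenotypes truncated at a birth-year cutoff, and
predictive quality is measured by the Pearson correlation between
GEBV and daughter yield deviations (DYD) from the full data, plus the
regression slope of DYD on GEBV (slope < 1: GEBV over-dispersed).
Also provides PEV-based candidate accuracy summaries against the
parent-average baseline, and a two-step GBLUP comparator that runs on
sire DYD only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
from scipy import stats

from .mme import EvaluationResult, MMESolution
from .pedigree import UNKNOWN, PedigreeTable, parent_average_accuracy

__all__ = [
    "ValidationError",
    "yield_deviations",
    "compute_dyd",
    "split_by_birth_year",
    "truncate_phenotypes",
    "pearson_validation",
    "regression_dyd_on_gebv",
    "center_gebv",
    "two_step_gblup",
    "candidate_accuracy_report",
]


class ValidationError(ValueError):
    pass


def yield_deviations(phenos: pd.DataFrame, solution: MMESolution) -> pd.DataFrame:
    """Per-female yield deviations from a solved full-data evaluation.

    Each record is corrected for the estimated fixed effects and the
    female's permanent-environment solution (genetic effects are NOT
    removed); a female's records are then averaged with her record
    weights.  Returns a frame with yd, the summed weight (edc
    contribution) and the record count per female.
    """
    design = solution.system.design
    if len(phenos) != len(design.y):
        raise ValidationError("phenotypes do not match the solved system's records")
    correction = design.X @ solution.beta
    if design.W is not None and len(solution.pe):
        correction = correction + design.W @ solution.pe
    resid = design.y - correction
    w = design.weights
    df = pd.DataFrame(
        {"animal": phenos["animal"].to_numpy(), "wyd": w * resid, "w": w}
    )
    g = df.groupby("animal", sort=False).sum()
    out = pd.DataFrame(
        {
            "animal": g.index,
            "yd": g["wyd"] / g["w"],
            "sum_weight": g["w"],
            "n_records": df.groupby("animal", sort=False).size().reindex(g.index),
        }
    ).reset_index(drop=True)
    return out


def compute_dyd(
    yd_table: pd.DataFrame, ped: PedigreeTable, dam_ebv: pd.Series
) -> pd.DataFrame:
    """Daughter yield deviations on the sire-EBV scale.

    DYD_s = 2 * sum_d w_d (YD_d - 0.5 u_dam(d)) / sum_d w_d over the
    sire's phenotyped daughters d; the factor 2 and the dam adjustment
    put DYD on the sire breeding-value scale so the expected regression
    of DYD on an unbiased GEBV is 1.  The effective daughter
    contribution (edc) is the sum of the daughters' record weights.
    """
    idx = ped.indices_of(yd_table["animal"])
    sire_pos = ped.sire[idx]
    keep = sire_pos != UNKNOWN
    if not keep.any():
        return pd.DataFrame(columns=["sire", "dyd", "edc", "n_daughters"])
    dam_pos = ped.dam[idx]
    u_dam = np.zeros(len(yd_table))
    known_dam = dam_pos != UNKNOWN
    dam_ids = np.array(
        [ped.ids[p] if p != UNKNOWN else None for p in dam_pos], dtype=object
    )
    lookup = dam_ebv.to_dict()
    for i in np.nonzero(known_dam)[0]:
        u_dam[i] = lookup.get(dam_ids[i], 0.0)
    w = yd_table["sum_weight"].to_numpy(float)
    adj = yd_table["yd"].to_numpy(float) - 0.5 * u_dam
    df = pd.DataFrame(
        {
            "sire": [ped.ids[s] for s in sire_pos[keep]],
            "num": (w * adj)[keep],
            "w": w[keep],
        }
    )
    g = df.groupby("sire", sort=False).agg(num=("num", "sum"), w=("w", "sum"))
    counts = df.groupby("sire", sort=False).size()
    return pd.DataFrame(
        {
            "sire": g.index,
            "dyd": 2.0 * g["num"] / g["w"],
            "edc": g["w"],
            "n_daughters": counts.reindex(g.index),
        }
    ).reset_index(drop=True)


def split_by_birth_year(
    male_ids,
    birth_years,
    train_years: tuple,
    validation_years: tuple,
    truncation_year: int | None = None,
):
    """Truncation split of males by birth year.

    Returns ``(train_ids, validation_ids, truncation_year)`` where the
    truncation year is the birth-year cutoff for the phenotype file of
    the training run (females born before it): by default the last
    training year + 3, when the youngest training sires' daughters
    have their first lactation.
    """
    t0, t1 = train_years
    v0, v1 = validation_years
    if not (t0 <= t1 < v0 <= v1):
        raise ValidationError(
            f"training years {train_years} must precede validation years {validation_years}"
        )
    by = np.asarray(birth_years)
    ids = np.asarray(male_ids, dtype=object)
    train = list(ids[(by >= t0) & (by <= t1)])
    valid = list(ids[(by >= v0) & (by <= v1)])
    if truncation_year is None:
        truncation_year = t1 + 3
    return train, valid, truncation_year


def truncate_phenotypes(
    phenos: pd.DataFrame, ped: PedigreeTable, born_before: int
) -> pd.DataFrame:
    """Records of females born before the cutoff year (training data)."""
    idx = ped.indices_of(phenos["animal"])
    return phenos[ped.birth_year[idx] < born_before].reset_index(drop=True)


def _align(gebv: pd.Series, dyd: pd.Series):
    common = gebv.index.intersection(dyd.index)
    if len(common) < 3:
        raise ValidationError(f"need >= 3 animals with both GEBV and DYD, have {len(common)}")
    return gebv.loc[common].to_numpy(float), dyd.loc[common].to_numpy(float)


def pearson_validation(gebv: pd.Series, dyd: pd.Series) -> float:
    """Pearson r between truncated-run GEBV and full-data DYD."""
    x, y = _align(gebv, dyd)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in GEBV or DYD: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def regression_dyd_on_gebv(gebv: pd.Series, dyd: pd.Series):
    """OLS of DYD on GEBV: returns (slope, intercept, slope_SE).

    A slope above 1 indicates under-dispersed GEBV, below 1
    over-dispersed GEBV.
    """
    x, y = _align(gebv, dyd)
    if np.std(x) == 0:
        raise ValidationError("zero variance in GEBV: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


def center_gebv(frame: pd.DataFrame, scope: str = "overall") -> pd.DataFrame:
    """Subtract the mean GEBV over the chosen scope.

    'overall' centers on the average across the two breeds (used to
    pool within-breed GEBV); 'per_breed' deviates each animal from its
    breed mean (used for breed-wise comparisons).  Correlations and
    regression slopes are invariant to this shift.
    """
    out = frame.copy()
    if scope == "overall":
        out["gebv"] = out["gebv"] - out["gebv"].mean()
    elif scope == "per_breed":
        out["gebv"] = out["gebv"] - out.groupby("breed")["gebv"].transform("mean")
    else:
        raise ValueError(f"unknown centering scope {scope!r}")
    return out


def two_step_gblup(
    dyd_table: pd.DataFrame,
    G_b: np.ndarray,
    g_ids,
    sigma2_u: float,
    sigma2_resid: float,
) -> pd.Series:
    """GBLUP on sire DYD: the two-step comparator.

    Model dyd = 1 mu + u + eps with Var(u) = G_b sigma2_u and
    Var(eps_s) = sigma2_resid / edc_s.  Sires in ``g_ids`` without a
    DYD record (candidates, validation males) are predicted through
    their genomic relationships.  Returns GEBV indexed by id.
    """
    g_ids = list(g_ids)
    pos = {a: i for i, a in enumerate(g_ids)}
    missing = [s for s in dyd_table["sire"] if s not in pos]
    if missing:
        raise ValidationError(f"sire {missing[0]!r} has DYD but is not in G")
    n = len(g_ids)
    obs = dyd_table["sire"].map(pos).to_numpy(int)
    edc = dyd_table["edc"].to_numpy(float)
    y = dyd_table["dyd"].to_numpy(float)
    rinv = edc / sigma2_resid
    Ginv = la.inv(np.asarray(G_b, float) + 1e-10 * np.eye(n))
    # equations: [mu, u]
    C = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    C[0, 0] = rinv.sum()
    np.add.at(C[0, 1:], obs, rinv)
    C[1:, 0] = C[0, 1:]
    np.add.at(C, (obs + 1, obs + 1), rinv)
    C[1:, 1:] += Ginv / sigma2_u
    rhs[0] = rinv @ y
    np.add.at(rhs, obs + 1, rinv * y)
    sol = la.solve(C, rhs, assume_a="sym")
    return pd.Series(sol[1:], index=pd.Index(g_ids), name="gebv")


@dataclass
class CandidateAccuracyReport:
    frame: pd.DataFrame
    mean_model_accuracy: float
    mean_parent_average_accuracy: float


def candidate_accuracy_report(
    result: EvaluationResult, ped: PedigreeTable, candidate_ids
) -> CandidateAccuracyReport:
    """Mean PEV-derived accuracy of candidates vs the parent-average baseline.

    Parent-average accuracy uses the parents' PEV-derived reliabilities
    from the same run; unknown parents contribute reliability 0.
    """
    cand = list(candidate_ids)
    if not cand:
        return CandidateAccuracyReport(pd.DataFrame(), float("nan"), float("nan"))
    fr = result.frame.set_index("animal")
    if "reliability" not in fr.columns:
        raise ValidationError("run the evaluation with pev=True first")
    rel = fr["reliability"]
    rows = []
    for a in cand:
        i = ped.indices_of([a])[0]
        rs = rel.get(ped.ids[ped.sire[i]], 0.0) if ped.sire[i] != UNKNOWN else 0.0
        rd = rel.get(ped.ids[ped.dam[i]], 0.0) if ped.dam[i] != UNKNOWN else 0.0
        rows.append(
            {
                "animal": a,
                "model_accuracy": fr.loc[a, "accuracy"],
                "parent_average_accuracy": parent_average_accuracy(rs, rd),
            }
        )
    frame = pd.DataFrame(rows)
    return CandidateAccuracyReport(
        frame=frame,
        mean_model_accuracy=float(frame["model_accuracy"].mean()),
        mean_parent_average_accuracy=float(frame["parent_average_accuracy"].mean()),
    )
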