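"""Synthetic two-breed dairy populations for exercising the pipeline.

Emulates the statistical structure the evaluation models assume: two
breeds drifted apart from a common ancestral population (Balding-
Nichols model at a chosen Fst), sire-centric multi-generation
pedigrees, per-SNP effects for the two breed-traits drawn with a
controllable across-breed correlation rho, repeated weighted lactation
records with per-breed heritability and repeatability, herd and parity
fixed effects, and sporadic missing genotype calls.

SNPs are treated as unlinked (gene dropping without a genetic map):
the models under test use relationships, not linkage.  Males carry no
own records, as dairy sires do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .pedigree import UNKNOWN, PedigreeTable

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_population",
    "realized_heritability",
    "mendelian_consistency",
]


class SimParameterError(ValueError):
    pass


class SimStructureError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated population.

    Defaults describe a milk-yield-like regime in a two-breed dairy
    goat population: per-breed heritabilities 0.31/0.26 with
    repeatability 0.50, genetic variances 9962/7278 (kg^2), an
    across-breed genetic correlation of 0.45, modest breed divergence
    (Fst 0.10) and 0.1% missing genotype calls.
    """

    n_founders_per_breed: int = 300  # founder males + females per breed
    n_generations: int = 3
    n_sires_per_gen: int = 30
    n_daughters_per_sire: int = 40
    n_sons_per_sire: int = 2
    n_snps: int = 5000
    fst_divergence: float = 0.10
    ancestral_freq_range: tuple = (0.1, 0.9)
    rho_breeds: float = 0.45
    h2_per_breed: tuple = (0.31, 0.26)
    repeatability_per_breed: tuple = (0.50, 0.50)
    genetic_var_per_breed: tuple = (9962.0, 7278.0)
    n_records_per_female: int = 3
    record_weights: tuple = (1.0, 0.5)  # (full, short) lactation weights
    short_lactation_rate: float = 0.2
    n_herds: int = 50
    herd_sd: float = 90.0
    missing_rate: float = 0.001
    breeds: tuple = ("alpine", "saanen")
    breed_means: tuple = (800.0, 760.0)
    trait: str = "milk_yield"
    n_genotyped_females: int = 0
    base_year: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for b in (0, 1):
            h2, t = self.h2_per_breed[b], self.repeatability_per_breed[b]
            if not (0.0 < h2 < 1.0):
                raise SimParameterError(f"heritability must lie in (0,1); got {h2}")
            if t < h2:
                raise SimParameterError(
                    f"repeatability ({t}) must be >= heritability ({h2}) for breed {b}"
                )
            if not t < 1.0:
                raise SimParameterError("repeatability must be < 1")
            if self.genetic_var_per_breed[b] <= 0:
                raise SimParameterError("genetic variances must be positive")
        if not (0.0 <= self.fst_divergence < 1.0):
            raise SimParameterError("fst_divergence must lie in [0, 1)")
        if not (-1.0 <= self.rho_breeds <= 1.0):
            raise SimParameterError("rho_breeds must lie in [-1, 1]")
        if any(w <= 0 for w in self.record_weights):
            raise SimParameterError("record weights must all be positive")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise SimParameterError("ancestral_freq_range must be inside (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimParameterError("missing_rate must lie in [0, 1)")
        if self.n_founders_per_breed < self.n_sires_per_gen + 2:
            raise SimStructureError(
                "n_founders_per_breed too small to supply "
                f"{self.n_sires_per_gen} founder sires plus dams"
            )
        if self.n_generations >= 1 and self.n_sons_per_sire == 0 and self.n_generations > 1:
            raise SimStructureError("later generations need sons: set n_sons_per_sire >= 1")


@dataclass
class SimOutput:
    """Everything a downstream stage (or a test) needs, with truth attached."""

    config: SimConfig
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix  # genotyped subset, with missing calls masked
    phenotypes: pd.DataFrame  # animal, breed, trait, parity, herd, year, weight, value
    true_bv: np.ndarray  # (n_animals, 2): breed-trait BVs for every animal
    true_pe: np.ndarray  # (n_animals,), nan for animals without records
    snp_effects: np.ndarray  # (n_snps, 2) per-breed-trait allele substitution effects
    herd_effects: np.ndarray
    parity_effects: np.ndarray
    true_params: dict  # per-breed sigma2_u / sigma2_p / sigma2_e and rho
    sire_ids: list
    candidate_ids: list

    @property
    def genotyped_ids(self) -> list:
        return list(self.genotypes.ids)

    def true_fixed_part(self, phenos: pd.DataFrame | None = None) -> np.ndarray:
        """mu_breed + herd + parity actually added to each record."""
        ph = self.phenotypes if phenos is None else phenos
        bmap = {b: m for b, m in zip(self.config.breeds, self.config.breed_means)}
        mu = ph["breed"].map(bmap).to_numpy(float)
        return (
            mu
            + self.herd_effects[ph["herd"].to_numpy(int)]
            + self.parity_effects[ph["parity"].to_numpy(int) - 1]
        )


def _pe_resid_var(cfg: SimConfig, b: int) -> tuple[float, float]:
    h2, t = cfg.h2_per_breed[b], cfg.repeatability_per_breed[b]
    total = cfg.genetic_var_per_breed[b] / h2
    return (t - h2) * total, (1.0 - t) * total


def simulate_population(config: SimConfig) -> SimOutput:
    """Simulate pedigree, genotypes, breeding values and records.

    Fully reproducible from ``config.seed``; identical configs give
    byte-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- allele frequencies: ancestral, then Balding-Nichols drift per breed
    lo, hi = cfg.ancestral_freq_range
    q0 = rng.uniform(lo, hi, size=cfg.n_snps)
    fst = cfg.fst_divergence
    breed_freq = np.empty((2, cfg.n_snps))
    if fst == 0.0:
        breed_freq[:] = q0
    else:
        c = (1.0 - fst) / fst
        for b in (0, 1):
            breed_freq[b] = rng.beta(q0 * c, (1.0 - q0) * c)
        breed_freq = np.clip(breed_freq, 1e-4, 1.0 - 1e-4)

    # --- pedigree construction (per breed; breeds never cross)
    ids: list = []
    sire_idx: list[int] = []
    dam_idx: list[int] = []
    sex: list[str] = []
    breed_of: list[int] = []
    byear: list[int] = []
    all_sires: list[int] = []
    candidates: list[int] = []

    def new_animal(tag, s, d, sx, b, year):
        ids.append(tag)
        sire_idx.append(s)
        dam_idx.append(d)
        sex.append(sx)
        breed_of.append(b)
        byear.append(year)
        return len(ids) - 1

    for b, bname in enumerate(cfg.breeds):
        n_fm = cfg.n_sires_per_gen  # founder males
        n_ff = cfg.n_founders_per_breed - n_fm
        males = [
            new_animal(f"{bname}_M0_{k}", UNKNOWN, UNKNOWN, "M", b, cfg.base_year)
            for k in range(n_fm)
        ]
        females = [
            new_animal(f"{bname}_F0_{k}", UNKNOWN, UNKNOWN, "F", b, cfg.base_year)
            for k in range(n_ff)
        ]
        for g in range(1, cfg.n_generations + 1):
            if len(males) < cfg.n_sires_per_gen:
                raise SimStructureError(
                    f"generation {g} of breed {bname} has only {len(males)} "
                    f"candidate sires for {cfg.n_sires_per_gen} needed"
                )
            sires = list(rng.choice(males, size=cfg.n_sires_per_gen, replace=False))
            all_sires.extend(sires)
            year = cfg.base_year + g
            next_males: list[int] = []
            next_females: list[int] = []
            for si, s in enumerate(sires):
                dams = rng.choice(females, size=cfg.n_daughters_per_sire + cfg.n_sons_per_sire)
                for k in range(cfg.n_daughters_per_sire):
                    next_females.append(
                        new_animal(f"{bname}_F{g}_{si}_{k}", s, dams[k], "F", b, year)
                    )
                for k in range(cfg.n_sons_per_sire):
                    next_males.append(
                        new_animal(
                            f"{bname}_M{g}_{si}_{k}",
                            s,
                            dams[cfg.n_daughters_per_sire + k],
                            "M",
                            b,
                            year,
                        )
                    )
            males, females = next_males, females + next_females
        candidates.extend(males)  # final-generation males: genotyped, no progeny

    n = len(ids)
    sire_arr = np.array(sire_idx, dtype=np.int64)
    dam_arr = np.array(dam_idx, dtype=np.int64)
    breed_arr = np.array(breed_of, dtype=np.int64)
    ped = PedigreeTable(
        ids=np.array(ids, dtype=object),
        sire=sire_arr,
        dam=dam_arr,
        birth_year=np.array(byear),
        breed=np.array([cfg.breeds[b] for b in breed_of], dtype=object),
        sex=np.array(sex, dtype=object),
    )

    # --- gene dropping (construction order is parents-first by design)
    dos = np.empty((n, cfg.n_snps), dtype=np.int8)
    founder = sire_arr == UNKNOWN
    for b in (0, 1):
        rows = founder & (breed_arr == b)
        dos[rows] = rng.binomial(2, breed_freq[b], size=(int(rows.sum()), cfg.n_snps))
    for i in np.nonzero(~founder)[0]:
        ts = rng.random(cfg.n_snps) < dos[sire_arr[i]] / 2.0
        td = rng.random(cfg.n_snps) < dos[dam_arr[i]] / 2.0
        dos[i] = ts.astype(np.int8) + td.astype(np.int8)

    # --- SNP effects: bivariate normal with correlation rho, rescaled so
    # realized additive variance per breed hits the target exactly
    rho = cfg.rho_breeds
    cov = np.array([[1.0, rho], [rho, 1.0]])
    Lc = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    effects = rng.standard_normal((cfg.n_snps, 2)) @ Lc.T
    # scale and center on the breed's FOUNDERS: sigma2_u is a base-population
    # variance (founders are unrelated, diag(A) = 1), matching what the
    # evaluation models mean by the genetic variance
    true_bv = np.empty((n, 2))
    for b in (0, 1):
        base = founder & (breed_arr == b)
        p_base = dos[base].mean(axis=0) / 2.0
        u = (dos - 2.0 * p_base) @ effects[:, b]
        v = float(np.var(u[base]))
        if v <= 0:
            raise SimStructureError("degenerate genotypes: zero additive variance")
        scale = np.sqrt(cfg.genetic_var_per_breed[b] / v)
        effects[:, b] *= scale
        true_bv[:, b] = u * scale

    # --- fixed effects and permanent environment
    herd_effects = rng.normal(0.0, cfg.herd_sd, size=cfg.n_herds)
    parity_effects = rng.normal(0.0, cfg.herd_sd / 2.0, size=max(cfg.n_records_per_female, 1))
    parity_effects[0] = 0.0  # first lactation is the reference level
    true_pe = np.full(n, np.nan)

    female_mask = (np.array(sex) == "F") & ~founder
    pheno_females = np.nonzero(female_mask)[0]
    w_full, w_short = cfg.record_weights

    rec_animal: list[int] = []
    rec_parity: list[int] = []
    rec_herd: list[int] = []
    rec_weight: list[float] = []
    rec_value: list[float] = []
    rec_year: list[int] = []

    sd_pe = {b: np.sqrt(_pe_resid_var(cfg, b)[0]) for b in (0, 1)}
    var_e = {b: _pe_resid_var(cfg, b)[1] for b in (0, 1)}
    herd_of = rng.integers(0, cfg.n_herds, size=n)

    for i in pheno_females:
        b = breed_arr[i]
        pe = rng.normal(0.0, sd_pe[b])
        true_pe[i] = pe
        for par in range(1, cfg.n_records_per_female + 1):
            # first lactations are complete; later ones may be short
            w = w_full if par == 1 or rng.random() >= cfg.short_lactation_rate else w_short
            e = rng.normal(0.0, np.sqrt(var_e[b] / w))
            y = (
                cfg.breed_means[b]
                + herd_effects[herd_of[i]]
                + parity_effects[par - 1]
                + true_bv[i, b]
                + pe
                + e
            )
            rec_animal.append(i)
            rec_parity.append(par)
            rec_herd.append(int(herd_of[i]))
            rec_weight.append(w)
            rec_value.append(y)
            rec_year.append(int(byear[i] + par))

    phenos = pd.DataFrame(
        {
            "animal": [ids[i] for i in rec_animal],
            "breed": [cfg.breeds[breed_arr[i]] for i in rec_animal],
            "trait": cfg.trait,
            "parity": rec_parity,
            "herd": rec_herd,
            "year": rec_year,
            "weight": rec_weight,
            "value": rec_value,
        }
    )

    # --- genotyped subset: every sire, all candidates, optional females
    geno_set = sorted(set(all_sires) | set(candidates))
    if cfg.n_genotyped_females > 0:
        extra = rng.choice(pheno_females, size=min(cfg.n_genotyped_females, len(pheno_females)), replace=False)
        geno_set = sorted(set(geno_set) | set(int(i) for i in extra))
    gdos = dos[geno_set].astype(float)
    if cfg.missing_rate > 0:
        miss = rng.random(gdos.shape) < cfg.missing_rate
        gdos[miss] = np.nan
    genotypes = GenotypeMatrix(
        ids=np.array([ids[i] for i in geno_set], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(cfg.n_snps)], dtype=object),
        dosages=gdos,
        breed=np.array([cfg.breeds[breed_arr[i]] for i in geno_set], dtype=object),
    )

    true_params = {
        "breeds": cfg.breeds,
        "sigma2_u": tuple(cfg.genetic_var_per_breed),
        "sigma2_p": tuple(_pe_resid_var(cfg, b)[0] for b in (0, 1)),
        "sigma2_e": tuple(_pe_resid_var(cfg, b)[1] for b in (0, 1)),
        "rho": rho,
        "h2": tuple(cfg.h2_per_breed),
        "repeatability": tuple(cfg.repeatability_per_breed),
    }
    return SimOutput(
        config=cfg,
        pedigree=ped,
        genotypes=genotypes,
        phenotypes=phenos,
        true_bv=true_bv,
        true_pe=true_pe,
        snp_effects=effects,
        herd_effects=herd_effects,
        parity_effects=parity_effects,
        true_params=true_params,
        sire_ids=[ids[i] for i in sorted(set(all_sires))],
        candidate_ids=[ids[i] for i in candidates],
    )


def realized_heritability(sim: SimOutput, breed: str) -> float:
    """var(true BV) / var(first-record phenotype deviations) in one breed.

    Deviations remove the true fixed part (breed mean, herd, parity), so
    what remains is u + pe + e of the complete first lactations.
    """
    if breed not in sim.config.breeds:
        raise KeyError(f"breed {breed!r} not simulated")
    b = sim.config.breeds.index(breed)
    ph = sim.phenotypes
    first = ph[(ph["breed"] == breed) & (ph["parity"] == 1)]
    if len(first) < 500:
        raise ValueError(f"need >= 500 phenotyped females in breed {breed!r}, have {len(first)}")
    dev = first["value"].to_numpy() - sim.true_fixed_part(first)
    idx = sim.pedigree.indices_of(first["animal"])
    u = sim.true_bv[idx, b]
    return float(np.var(u) / np.var(dev))


def mendelian_consistency(sim: SimOutput) -> int:
    """Count offspring SNP dosages impossible given parental dosages.

    Uses genotyped parent-offspring pairs only and skips missing calls.
    Gene-dropped output must give zero; planted corruptions are counted
    one per offspring x SNP.
    """
    genos = sim.genotypes
    pos = {a: i for i, a in enumerate(genos.ids)}
    ped = sim.pedigree
    dos = genos.dosages
    violations = 0
    for a, row in pos.items():
        i = ped.indices_of([a])[0]
        lo = np.zeros(genos.n_snps)
        hi = np.full(genos.n_snps, 2.0)
        informative = np.zeros(genos.n_snps, dtype=bool)
        for p in (ped.sire[i], ped.dam[i]):
            if p == UNKNOWN or ped.ids[p] not in pos:
                continue
            pd_ = dos[pos[ped.ids[p]]]
            known = ~np.isnan(pd_)
            tmin = np.where(pd_ == 2, 1.0, 0.0)
            tmax = np.where(pd_ == 0, 0.0, 1.0)
            lo = lo + np.where(known, tmin, 0.0)
            hi = hi - np.where(known, 1.0 - tmax, 0.0)
            informative |= known
        c = dos[row]
        ok = ~np.isnan(c) & informative
        violations += int(np.sum(ok & ((c < lo) | (c > hi))))
    return violations
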