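"""Validation layer: YD/DYD arithmetic, splits, correlations, slopes."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import genomic
from ssgblup.evaluate import (
    ValidationError,
    candidate_accuracy_report,
    center_gebv,
    compute_dyd,
    pearson_validation,
    regression_dyd_on_gebv,
    split_by_birth_year,
    truncate_phenotypes,
    two_step_gblup,
    yield_deviations,
)
from ssgblup.mme import (
    ModelSpec,
    VarianceComponents,
    assemble_mme,
    build_design,
    run_evaluation,
    solve_mme,
)
from ssgblup.pedigree import PedigreeTable


def solved_fixture():
    """6 records on 3 females with known fixed-effect and PE solutions."""
    ped = PedigreeTable.from_frame(
        pd.DataFrame(
            {
                "animal": ["s", "d1", "d2", "f1", "f2", "f3"],
                "sire": [0, 0, 0, "s", "s", "s"],
                "dam": [0, 0, 0, "d1", "d1", "d2"],
                "breed": ["alpine"] * 6,
                "sex": ["M", "F", "F", "F", "F", "F"],
            }
        )
    )
    ph = pd.DataFrame(
        {
            "animal": ["f1", "f1", "f2", "f2", "f3", "f3"],
            "breed": ["alpine"] * 6,
            "herd": ["h1", "h2", "h1", "h2", "h1", "h2"],
            "value": [10.0, 12.0, 8.0, 9.0, 11.0, 14.0],
            "weight": [1.0, 0.5, 1.0, 1.0, 1.0, 0.5],
        }
    )
    spec = ModelSpec(kind="multi_breed", fixed_effects=("herd",), repeatable=True)
    vc = VarianceComponents.single(4.0, 8.0, sigma2_p=2.0)
    design = build_design(ph, spec, ped, breeds=("alpine", "alpine"))
    from ssgblup.pedigree import build_A_inverse

    sol = solve_mme(assemble_mme(design, build_A_inverse(ped), vc, spec))
    return ped, ph, design, sol


class TestYieldDeviations:
    def test_matches_hand_computed_weighted_residuals(self):
        ped, ph, design, sol = solved_fixture()
        yd = yield_deviations(ph, sol).set_index("animal")
        correction = design.X @ sol.beta + design.W @ sol.pe
        resid = ph["value"].to_numpy() - correction
        w = ph["weight"].to_numpy()
        for i, f in enumerate(["f1", "f2", "f3"]):
            rows = ph["animal"] == f
            expected = np.sum((w * resid)[rows]) / np.sum(w[rows])
            assert yd.loc[f, "yd"] == pytest.approx(expected)

    def test_zero_corrections_returns_raw_mean(self):
        ped, ph, design, sol = solved_fixture()
        sol.beta[:] = 0.0
        sol.pe[:] = 0.0
        yd = yield_deviations(ph, sol).set_index("animal")
        rows = ph["animal"] == "f2"
        assert yd.loc["f2", "yd"] == pytest.approx(
            np.average(ph.loc[rows, "value"], weights=ph.loc[rows, "weight"])
        )


class TestDyd:
    def _yd(self, animals, yds, weights):
        return pd.DataFrame({"animal": animals, "yd": yds, "sum_weight": weights,
                             "n_records": [1] * len(animals)})

    def _ped(self):
        return PedigreeTable.from_frame(
            pd.DataFrame(
                {
                    "animal": ["s", "d", "f1", "f2"],
                    "sire": [0, 0, "s", "s"],
                    "dam": [0, 0, "d", "d"],
                }
            )
        )

    def test_single_daughter_doubles_yd(self):
        dyd = compute_dyd(self._yd(["f1"], [1.0], [1.0]), self._ped(), pd.Series(dtype=float))
        assert dyd.set_index("sire").loc["s", "dyd"] == pytest.approx(2.0)

    def test_dam_adjustment_cancels(self):
        dam_ebv = pd.Series({"d": 2.0})
        dyd = compute_dyd(self._yd(["f1", "f2"], [1.0, 1.0], [1.0, 2.0]), self._ped(), dam_ebv)
        assert dyd.set_index("sire").loc["s", "dyd"] == pytest.approx(0.0)

    def test_edc_is_weight_sum(self):
        dyd = compute_dyd(self._yd(["f1", "f2"], [1.0, 2.0], [1.5, 2.5]), self._ped(),
                          pd.Series(dtype=float))
        row = dyd.set_index("sire").loc["s"]
        assert row["edc"] == pytest.approx(4.0)
        assert row["n_daughters"] == 2

    def test_unbiased_for_true_sire_bv(self):
        """Many daughters per sire: slope of DYD on true sire BV -> 1."""
        rng = np.random.default_rng(42)
        n_sires, n_d = 200, 100
        s2u, s2e = 1.0, 3.0
        u_sire = rng.normal(0, np.sqrt(s2u), n_sires)
        rows = []
        dam_ebv = {}
        for s in range(n_sires):
            u_dam = rng.normal(0, np.sqrt(s2u), n_d)
            mend = rng.normal(0, np.sqrt(s2u / 2), n_d)
            u_daughter = 0.5 * u_sire[s] + 0.5 * u_dam + mend
            yd = u_daughter + rng.normal(0, np.sqrt(s2e), n_d)
            for d in range(n_d):
                rows.append((f"s{s}", f"f{s}_{d}", yd[d]))
                dam_ebv[f"dam{s}_{d}"] = u_dam[d]
        ped = PedigreeTable.from_frame(
            pd.DataFrame(
                {
                    "animal": [f"s{s}" for s in range(n_sires)]
                    + list(dam_ebv)
                    + [r[1] for r in rows],
                    "sire": [0] * n_sires + [0] * len(dam_ebv) + [r[0] for r in rows],
                    "dam": [0] * n_sires + [0] * len(dam_ebv)
                    + [f"dam{r[1][1:]}" for r in rows],
                }
            )
        )
        yd_table = pd.DataFrame(
            {"animal": [r[1] for r in rows], "yd": [r[2] for r in rows],
             "sum_weight": 1.0, "n_records": 1}
        )
        dyd = compute_dyd(yd_table, ped, pd.Series(dam_ebv))
        x = u_sire
        y = dyd.set_index("sire").loc[[f"s{s}" for s in range(n_sires)], "dyd"].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestSplit:
    def test_fixture_membership(self):
        ids = [f"m{i}" for i in range(10)]
        years = [1993, 1999, 2005, 2005, 2006, 2007, 2009, 2010, 1990, 2006]
        train, valid, cutoff = split_by_birth_year(ids, years, (1993, 2005), (2006, 2009))
        assert train == ["m0", "m1", "m2", "m3"]
        assert valid == ["m4", "m5", "m6", "m9"]
        assert cutoff == 2008

    def test_partition_property(self):
        ids = [f"m{i}" for i in range(30)]
        years = np.random.default_rng(0).integers(1990, 2012, 30)
        train, valid, _ = split_by_birth_year(ids, years, (1993, 2005), (2006, 2009))
        out = [i for i, y in zip(ids, years) if y < 1993 or y > 2009]
        assert set(train) | set(valid) | set(out) == set(ids)
        assert not set(train) & set(valid)

    def test_all_in_train_empty_validation(self):
        _, valid, _ = split_by_birth_year(["a"], [2000], (1999, 2001), (2002, 2003))
        assert valid == []

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            split_by_birth_year(["a"], [2000], (1990, 2006), (2006, 2009))


class TestCorrelationAndSlope:
    def _pair(self):
        rng = np.random.default_rng(1)
        g = pd.Series(rng.normal(size=10), index=[f"m{i}" for i in range(10)])
        return g

    def test_exact_linear_relation(self):
        g = self._pair()
        assert pearson_validation(g, 2 * g + 1) == pytest.approx(1.0)

    def test_constructed_orthogonality(self):
        g = self._pair()
        noise = pd.Series(np.random.default_rng(2).normal(size=10), index=g.index)
        resid = noise - np.polyfit(g, noise, 1)[1] - np.polyfit(g, noise, 1)[0] * g
        assert pearson_validation(g, resid) == pytest.approx(0.0, abs=1e-10)

    def test_matches_textbook_formula(self):
        g = self._pair()
        d = g**2 + 0.3 * g
        x, y = g.to_numpy(), d.to_numpy()
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_validation(g, d) == pytest.approx(manual)

    def test_degenerate_inputs_flagged(self):
        g = self._pair()
        with pytest.raises(ValidationError):
            pearson_validation(g.iloc[:2], g.iloc[:2])
        with pytest.raises(ValidationError):
            pearson_validation(g * 0, g)

    def test_identity_slope(self):
        g = self._pair()
        slope, intercept, se = regression_dyd_on_gebv(g, g)
        assert slope == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        g = self._pair()
        d = g**2 + 0.3 * g
        s1, _, _ = regression_dyd_on_gebv(g, d)
        s2, _, _ = regression_dyd_on_gebv(g / 2.0, d)
        assert s2 == pytest.approx(2 * s1)

    def test_slope_se_matches_classical_formula(self):
        g = self._pair().iloc[:8]
        d = 0.7 * g + pd.Series(
            np.random.default_rng(3).normal(size=8), index=g.index
        )
        slope, intercept, se = regression_dyd_on_gebv(g, d)
        x, y = g.to_numpy(), d.to_numpy()
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        a = y.mean() - b * x.mean()
        resid = y - a - b * x
        se_manual = np.sqrt(np.sum(resid**2) / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
        assert slope == pytest.approx(b)
        assert se == pytest.approx(se_manual)


class TestCentering:
    def _frame(self):
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            {
                "animal": [f"m{i}" for i in range(12)],
                "breed": ["alpine"] * 6 + ["saanen"] * 6,
                "gebv": rng.normal(5, 2, 12),
            }
        )

    def test_overall_mean_zero(self):
        out = center_gebv(self._frame(), "overall")
        assert out["gebv"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_per_breed_means_zero(self):
        out = center_gebv(self._frame(), "per_breed")
        assert np.allclose(out.groupby("breed")["gebv"].mean(), 0.0)

    def test_r_and_slope_invariant(self):
        fr = self._frame()
        dyd = pd.Series(
            fr["gebv"].to_numpy() * 0.8 + np.random.default_rng(5).normal(size=12),
            index=fr["animal"],
        )
        g0 = fr.set_index("animal")["gebv"]
        g1 = center_gebv(fr, "overall").set_index("animal")["gebv"]
        assert pearson_validation(g0, dyd) == pytest.approx(pearson_validation(g1, dyd))
        assert regression_dyd_on_gebv(g0, dyd)[0] == pytest.approx(
            regression_dyd_on_gebv(g1, dyd)[0]
        )


class TestTwoStep:
    def test_single_sire_shrinkage(self):
        dyd = pd.DataFrame({"sire": ["s"], "dyd": [3.0], "edc": [4.0], "n_daughters": [4]})
        gebv = two_step_gblup(dyd, np.eye(1), ["s"], sigma2_u=2.0, sigma2_resid=8.0)
        # with an estimated mean soaking up the average, a single record
        # gives u = 0 (everything goes to mu)
        assert gebv["s"] == pytest.approx(0.0, abs=1e-9)

    def test_identity_G_preserves_dyd_ranking(self):
        rng = np.random.default_rng(6)
        sires = [f"s{i}" for i in range(8)]
        d = rng.normal(size=8)
        dyd = pd.DataFrame({"sire": sires, "dyd": d, "edc": 5.0, "n_daughters": 5})
        gebv = two_step_gblup(dyd, np.eye(8), sires, sigma2_u=1.0, sigma2_resid=2.0)
        assert list(np.argsort(gebv.loc[sires])) == list(np.argsort(d))

    def test_unknown_sire_rejected(self):
        dyd = pd.DataFrame({"sire": ["x"], "dyd": [1.0], "edc": [1.0], "n_daughters": [1]})
        with pytest.raises(ValidationError):
            two_step_gblup(dyd, np.eye(1), ["s"], 1.0, 1.0)


class TestCandidateAccuracy:
    def test_report_fields_and_bounds(self, small_sim):
        _, g = genomic.qc_filter(small_sim.genotypes)
        rs = genomic.single_step_relationships(small_sim.pedigree, g)
        tp = small_sim.true_params
        vc = VarianceComponents(
            breeds=small_sim.config.breeds, sigma2_u=tp["sigma2_u"],
            sigma2_e=tp["sigma2_e"], sigma2_p=tp["sigma2_p"],
            sigma_u_sa=tp["rho"] * float(np.sqrt(tp["sigma2_u"][0] * tp["sigma2_u"][1])),
        )
        res = run_evaluation(
            small_sim.phenotypes, small_sim.pedigree, rs.h_inv,
            ModelSpec(kind="multi_breed"), vc, pev=True, h_diag=rs.h_diag,
        )
        rep = candidate_accuracy_report(res, small_sim.pedigree, small_sim.candidate_ids)
        assert len(rep.frame) == len(small_sim.candidate_ids)
        assert rep.frame["model_accuracy"].between(0, 1).all()
        assert rep.frame["parent_average_accuracy"].between(0, 1).all()
        assert rep.mean_model_accuracy > 0

    def test_empty_candidates(self, small_sim):
        from ssgblup.mme import EvaluationResult

        res = EvaluationResult(
            frame=pd.DataFrame(columns=["animal"]), model="multi_breed",
            solutions={}, systems={},
        )
        out = candidate_accuracy_report(res, small_sim.pedigree, [])
        assert np.isnan(out.mean_model_accuracy)
        assert out.frame.empty


class TestTruncation:
    def test_truncate_by_birth_year(self, small_sim):
        ped = small_sim.pedigree
        cutoff = int(np.median(ped.birth_year)) + 1
        ph = truncate_phenotypes(small_sim.phenotypes, ped, cutoff)
        idx = ped.indices_of(ph["animal"])
        assert (ped.birth_year[idx] < cutoff).all()
        assert len(ph) < len(small_sim.phenotypes)
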