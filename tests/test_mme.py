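"""Henderson MME assembly, solving, PEV and model-variant behavior."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as la

from ssgblup import genomic
from ssgblup.mme import (
    ModelSpec,
    VarianceComponents,
    VarianceError,
    assemble_mme,
    build_design,
    compute_pev,
    reliability_from_pev,
    run_evaluation,
    solve_mme,
)
from ssgblup.pedigree import PedigreeTable


def one_animal_setup(weight=1.0, n_extra=0):
    ped = PedigreeTable.from_frame(
        pd.DataFrame(
            {
                "animal": ["x"] + [f"u{i}" for i in range(n_extra)],
                "sire": [0] * (1 + n_extra),
                "dam": [0] * (1 + n_extra),
                "breed": ["alpine"] * (1 + n_extra),
            }
        )
    )
    ph = pd.DataFrame(
        {"animal": ["x"], "breed": ["alpine"], "value": [10.0], "weight": [weight]}
    )
    spec = ModelSpec(kind="multi_breed", fixed_effects=(), intercept=False, repeatable=False)
    vc = VarianceComponents.single(30.0, 70.0)
    design = build_design(ph, spec, ped, breeds=("alpine", "alpine"))
    return assemble_mme(design, np.eye(1 + n_extra), vc, spec)


class TestMicroClosedForms:
    def test_single_record_shrinkage_is_h2(self):
        sol = solve_mme(one_animal_setup())
        assert sol.u[0][0] == pytest.approx(0.3 * 10.0)  # h2 * y

    def test_weighted_record_shrinkage(self):
        sol = solve_mme(one_animal_setup(weight=2.0))
        assert sol.u[0][0] == pytest.approx(10.0 * 30.0 / (30.0 + 35.0))

    def test_pev_closed_form(self):
        system = one_animal_setup()
        pev = compute_pev(system)
        assert pev[0, 0] == pytest.approx(1.0 / (1.0 / 30.0 + 1.0 / 70.0))  # 21

    def test_reliability_from_single_record(self):
        rel, acc = reliability_from_pev(21.0, 30.0, 1.0)
        assert rel == pytest.approx(0.30)
        assert acc == pytest.approx(np.sqrt(0.30))

    def test_reliability_bounds(self):
        assert reliability_from_pev(30.0, 30.0, 1.0)[0] == 0.0
        assert reliability_from_pev(0.0, 30.0, 1.0)[0] == 1.0
        with pytest.raises(ValueError):
            reliability_from_pev(1.0, -5.0, 1.0)

    def test_unobserved_unrelated_animal_has_prior_pev(self):
        system = one_animal_setup(n_extra=1)
        pev = compute_pev(system)
        assert pev[0, 1] == pytest.approx(30.0)  # sigma2_u: reliability 0

    def test_pev_shrinks_with_second_record(self):
        ped = PedigreeTable.from_frame(
            pd.DataFrame({"animal": ["x"], "sire": [0], "dam": [0], "breed": ["alpine"]})
        )
        spec = ModelSpec(kind="multi_breed", fixed_effects=(), intercept=False, repeatable=False)
        vc = VarianceComponents.single(30.0, 70.0)
        pevs = []
        for n_rec in (1, 2):
            ph = pd.DataFrame(
                {"animal": ["x"] * n_rec, "breed": ["alpine"] * n_rec,
                 "value": [10.0] * n_rec, "weight": [1.0] * n_rec}
            )
            design = build_design(ph, spec, ped, breeds=("alpine", "alpine"))
            pevs.append(compute_pev(assemble_mme(design, np.eye(1), vc, spec))[0, 0])
        assert pevs[1] < pevs[0]


class TestDesign:
    def test_intercept_only(self):
        ped = PedigreeTable.from_frame(
            pd.DataFrame({"animal": ["x"], "sire": [0], "dam": [0], "breed": ["alpine"]})
        )
        ph = pd.DataFrame({"animal": ["x"], "breed": ["alpine"], "value": [1.0]})
        spec = ModelSpec(kind="multi_breed", fixed_effects=(), repeatable=True)
        d = build_design(ph, spec, ped, breeds=("alpine", "alpine"))
        assert d.X.toarray().tolist() == [[1.0]]
        assert d.Z.toarray().tolist() == [[1.0]]
        assert d.W.toarray().tolist() == [[1.0]]

    def test_estimable_column_count(self):
        # 20 records, 3 herds, 2 parities, intercept:
        # 1 + (3-1) + (2-1) = 4 estimable fixed columns
        rng = np.random.default_rng(0)
        ped = PedigreeTable.from_frame(
            pd.DataFrame({"animal": [f"c{i}" for i in range(20)], "sire": [0] * 20,
                          "dam": [0] * 20, "breed": ["alpine"] * 20})
        )
        ph = pd.DataFrame(
            {
                "animal": [f"c{i}" for i in range(20)],
                "breed": ["alpine"] * 20,
                "herd": rng.choice(["h1", "h2", "h3"], 20).tolist(),
                "parity": rng.choice([1, 2], 20).tolist(),
                "value": rng.normal(size=20),
            }
        )
        ph.loc[:2, "herd"] = ["h1", "h2", "h3"]  # ensure all levels present
        ph.loc[:1, "parity"] = [1, 2]
        spec = ModelSpec(kind="multi_breed", fixed_effects=("herd", "parity"))
        d = build_design(ph, spec, ped, breeds=("alpine", "alpine"))
        assert d.X.shape[1] == 4

    def test_multiple_trait_block_structure(self, small_sim):
        spec = ModelSpec(kind="multiple_trait", fixed_effects=("herd",))
        d = build_design(small_sim.phenotypes, spec, small_sim.pedigree)
        N = small_sim.pedigree.n
        zc = d.Z.tocoo()
        trait_of_record = zc.col[np.argsort(zc.row)] // N
        np.testing.assert_array_equal(trait_of_record, d.rec_breed)

    def test_unknown_animal_raises(self, trio_pedigree):
        ph = pd.DataFrame({"animal": ["ghost"], "breed": ["alpine"], "value": [1.0]})
        spec = ModelSpec(kind="multi_breed")
        with pytest.raises(KeyError):
            build_design(ph, spec, trio_pedigree, breeds=("alpine", "alpine"))


@pytest.fixture(scope="module")
def sim_eval(small_sim):
    """Relationships + true-parameter VC for the shared simulation."""
    _, g = genomic.qc_filter(small_sim.genotypes)
    rs = genomic.single_step_relationships(small_sim.pedigree, g)
    tp = small_sim.true_params
    vc = VarianceComponents(
        breeds=small_sim.config.breeds,
        sigma2_u=tp["sigma2_u"],
        sigma2_e=tp["sigma2_e"],
        sigma2_p=tp["sigma2_p"],
        sigma_u_sa=tp["rho"] * float(np.sqrt(tp["sigma2_u"][0] * tp["sigma2_u"][1])),
    )
    return rs, vc


class TestSolver:
    def test_gls_oracle_small(self, small_sim, sim_eval):
        rs, vc = sim_eval
        ph = small_sim.phenotypes.head(8)
        spec = ModelSpec(kind="multi_breed", fixed_effects=(), intercept=True)
        d = build_design(ph, spec, small_sim.pedigree, breeds=vc.breeds)
        sol = solve_mme(assemble_mme(d, rs.h_inv, vc, spec))
        H = la.inv(rs.h_inv.to_dense())
        Z, W, X = d.Z.toarray(), d.W.toarray(), d.X.toarray()
        V = (
            Z @ H @ Z.T * vc.sigma2_u[0]
            + W @ W.T * vc.sigma2_p[0]
            + np.diag(vc.sigma2_e[0] / d.weights)
        )
        Vi = la.inv(V)
        beta = la.solve(X.T @ Vi @ X, X.T @ Vi @ d.y)
        u = vc.sigma2_u[0] * H @ Z.T @ Vi @ (d.y - X @ beta)
        np.testing.assert_allclose(sol.u[0], u, atol=1e-8)

    def test_direct_vs_pcg(self, small_sim, sim_eval):
        rs, vc = sim_eval
        spec = ModelSpec(kind="multi_breed")
        d = build_design(small_sim.phenotypes.head(400), spec, small_sim.pedigree, breeds=vc.breeds)
        system = assemble_mme(d, rs.h_inv, vc, spec)
        direct = solve_mme(system, method="direct")
        pcg = solve_mme(system, method="pcg", tol=1e-12, max_iter=20000)
        np.testing.assert_allclose(direct.vector, pcg.vector, atol=1e-6)

    def test_zero_data_zero_solutions(self, small_sim, sim_eval):
        rs, vc = sim_eval
        ph = small_sim.phenotypes.copy()
        ph["value"] = 0.0
        spec = ModelSpec(kind="multi_breed", fixed_effects=(), intercept=False)
        d = build_design(ph, spec, small_sim.pedigree, breeds=vc.breeds)
        sol = solve_mme(assemble_mme(d, rs.h_inv, vc, spec))
        np.testing.assert_allclose(sol.u[0], 0.0, atol=1e-12)

    def test_solver_determinism(self, small_sim, sim_eval):
        rs, vc = sim_eval
        spec = ModelSpec(kind="multi_breed")
        d = build_design(small_sim.phenotypes, spec, small_sim.pedigree, breeds=vc.breeds)
        system = assemble_mme(d, rs.h_inv, vc, spec)
        a = solve_mme(system, method="pcg", tol=1e-10)
        b = solve_mme(system, method="pcg", tol=1e-10)
        np.testing.assert_array_equal(a.vector, b.vector)


class TestModelVariants:
    def test_pedigree_blup_equals_collapsed_ssgblup(self, small_sim, sim_eval):
        rs, vc = sim_eval
        ped = small_sim.pedigree
        spec = ModelSpec(kind="multi_breed")
        collapsed = genomic.build_H_inverse(rs.A_inv, rs.A22, rs.A22, rs.genotyped_idx)
        res_a = run_evaluation(small_sim.phenotypes, ped, rs.A_inv, spec, vc)
        res_h = run_evaluation(small_sim.phenotypes, ped, collapsed, spec, vc)
        np.testing.assert_allclose(
            res_a.frame["gebv"], res_h.frame["gebv"], atol=1e-8
        )

    def test_scale_invariance_of_gebv(self, small_sim, sim_eval):
        rs, vc = sim_eval
        spec = ModelSpec(kind="multi_breed")
        doubled = VarianceComponents(
            breeds=vc.breeds,
            sigma2_u=tuple(2 * v for v in vc.sigma2_u),
            sigma2_e=tuple(2 * v for v in vc.sigma2_e),
            sigma2_p=tuple(2 * v for v in vc.sigma2_p),
            sigma_u_sa=2 * vc.sigma_u_sa,
        )
        a = run_evaluation(small_sim.phenotypes, small_sim.pedigree, rs.h_inv, spec, vc)
        b = run_evaluation(small_sim.phenotypes, small_sim.pedigree, rs.h_inv, spec, doubled)
        np.testing.assert_allclose(a.frame["gebv"], b.frame["gebv"], atol=1e-8)

    def test_rho_one_rejected(self, sim_eval):
        rs, vc = sim_eval
        with pytest.raises(VarianceError):
            vc.with_rho(1.0)

    def test_candidates_get_information_from_relatives(self, small_sim, sim_eval):
        rs, vc = sim_eval
        spec = ModelSpec(kind="multi_breed")
        res = run_evaluation(small_sim.phenotypes, small_sim.pedigree, rs.h_inv, spec, vc)
        cand_gebv = res.frame.set_index("animal").loc[small_sim.candidate_ids, "gebv"]
        assert np.all(np.abs(cand_gebv) > 0)

    def test_multiple_trait_rho_zero_decouples(self, small_sim, sim_eval):
        rs, vc0 = sim_eval
        vc = VarianceComponents(
            breeds=vc0.breeds, sigma2_u=vc0.sigma2_u, sigma2_e=vc0.sigma2_e,
            sigma2_p=vc0.sigma2_p, sigma_u_sa=0.0,
        )
        ped = small_sim.pedigree
        fx = ("herd",)
        mt = run_evaluation(
            small_sim.phenotypes, ped, rs.h_inv,
            ModelSpec(kind="multiple_trait", fixed_effects=fx), vc,
        )
        mt_g = mt.frame.set_index("animal")["gebv"]
        for bi, b in enumerate(vc.breeds):
            vcb = VarianceComponents.single(
                vc.sigma2_u[bi], vc.sigma2_e[bi], vc.sigma2_p[bi]
            )
            ph_b = small_sim.phenotypes[small_sim.phenotypes["breed"] == b]
            single = run_evaluation(
                ph_b, ped, rs.h_inv,
                ModelSpec(kind="multi_breed", fixed_effects=fx, breed_fixed=False), vcb,
            )
            sel = ped.breed == b
            diff = mt_g.loc[ped.ids[sel]] - single.frame.set_index("animal").loc[ped.ids[sel], "gebv"]
            assert np.abs(diff).max() < 1e-6
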