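"""Quality-control screens: EFA, Q3, discrimination, item fit, DIF, pipeline."""

import warnings

import numpy as np
import pytest

import catirt as ct
from catirt.qc import QCError


class TestUnidimensionality:
    def test_worked_eigenvalue_ratio(self):
        assert ct.eigenvalue_ratio([19.223, 3.721]) == pytest.approx(5.166, abs=5e-4)

    def test_independent_items_fail(self):
        rng = np.random.default_rng(2)
        rm = ct.ResponseMatrix(rng.integers(0, 2, (2000, 12)), [f"i{k}" for k in range(12)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = ct.unidimensionality_check(rm)
        assert rep.ratio_1_2 < 2.0
        assert not rep.passed

    def test_one_factor_data_pass_without_drops(self, clean_sim):
        rep = ct.unidimensionality_check(clean_sim.responses)
        assert rep.passed
        assert rep.dropped_items == []
        assert rep.ratio_1_2 > 4.0
        assert (np.diff(rep.eigenvalues) <= 1e-12).all()  # non-increasing

    def test_constant_column_excluded_with_warning(self, clean_sim):
        data = clean_sim.responses.data.copy()
        data[:, 0] = 1
        rm = ct.ResponseMatrix(data, clean_sim.responses.item_ids)
        with pytest.warns(UserWarning, match="constant"):
            rep = ct.unidimensionality_check(rm)
        assert clean_sim.responses.item_ids[0] in rep.dropped_items

    def test_too_few_items_rejected(self):
        rm = ct.ResponseMatrix(np.zeros((10, 2), dtype=int), ["a", "b"])
        with pytest.raises(QCError):
            ct.unidimensionality_check(rm)


class TestQ3:
    def test_duplicated_item_pair_flagged_and_one_dropped(self, small_bank, clean_sim):
        data = np.column_stack([clean_sim.responses.data, clean_sim.responses.data[:, 0]])
        rm = ct.ResponseMatrix(data, clean_sim.responses.item_ids + ["dup"])
        bank = ct.ItemBank(tuple(small_bank.items) + (
            ct.ItemParameters("dup", small_bank[0].a, small_bank[0].b),
        ))
        thetas, _ = ct.eap_thetas(rm, bank)
        rep = ct.q3_screen(rm, bank, thetas)
        pairs = {frozenset((a, b)) for a, b, _ in rep.flagged_pairs}
        assert frozenset(("i1", "dup")) in pairs
        assert len(rep.dropped_items) == 1
        assert rep.dropped_items[0] in ("i1", "dup")

    def test_boundary_is_strict(self, small_bank, clean_sim):
        thetas, _ = ct.eap_thetas(clean_sim.responses, small_bank)
        rep = ct.q3_screen(clean_sim.responses, small_bank, thetas)
        # raising the cut to exactly the max observed Q3 must flag nothing
        top = ct.q3_screen(
            clean_sim.responses, small_bank, thetas,
            threshold=max(v for _, _, v in rep.flagged_pairs) if rep.flagged_pairs
            else rep.q3.max().max(),
        )
        assert top.flagged_pairs == []

    def test_q3_matrix_symmetric(self, small_bank, clean_sim):
        thetas, _ = ct.eap_thetas(clean_sim.responses, small_bank)
        rep = ct.q3_screen(clean_sim.responses, small_bank, thetas)
        m = rep.q3.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()  # self-correlation excluded


class TestDiscriminationFilter:
    def test_strict_boundary(self):
        bank = ct.ItemBank((
            ct.ItemParameters("low", 0.49, (0.0,)),
            ct.ItemParameters("edge", 0.50, (0.0,)),
            ct.ItemParameters("high", 1.5, (0.0,)),
        ))
        kept, dropped = ct.discrimination_filter(bank)
        assert dropped == ["low"]
        assert kept == ["edge", "high"]  # sorted by a

    def test_narcissism_bank_loses_nothing(self, narc_bank):
        kept, dropped = ct.discrimination_filter(narc_bank)
        assert dropped == []
        assert len(kept) == 85


class TestItemFit:
    def test_well_fitting_data_rarely_flagged(self, small_bank, clean_sim):
        results = ct.s_chi2_item_fit(clean_sim.responses, small_bank)
        computable = [r for r in results if r.computable]
        assert len(computable) == 10
        assert all(0 <= r.p_value <= 1 and r.s_chi2 >= 0 and r.df >= 1 for r in computable)
        assert sum(r.p_value < 0.01 for r in computable) <= 1

    def test_misfitting_item_detected(self, small_bank, clean_sim):
        # score an item against wildly wrong parameters: strong misfit signal
        items = list(small_bank.items)
        wrong = ct.ItemParameters(items[0].item_id, 2.5, (-2.0,))
        bank = ct.ItemBank(tuple([wrong] + items[1:]))
        results = ct.s_chi2_item_fit(clean_sim.responses, bank)
        assert results[0].p_value < 0.01

    def test_tiny_sample_not_computable(self, small_bank, clean_sim):
        rm = ct.ResponseMatrix(
            clean_sim.responses.data[:8], clean_sim.responses.item_ids
        )
        results = ct.s_chi2_item_fit(rm, small_bank)
        assert any(not r.computable for r in results) or all(r.df >= 1 for r in results)


class TestDIF:
    def test_null_groups_not_flagged(self, small_bank, clean_sim):
        thetas, _ = ct.eap_thetas(clean_sim.responses, small_bank)
        results = ct.dif_logistic(clean_sim.responses, clean_sim.groups, thetas)
        assert sum(r.flagged for r in results) == 0
        assert all(r.delta_r2 >= 0 for r in results)

    def test_injected_uniform_dif_flagged(self, small_bank):
        sim = ct.simulate_responses(
            ct.SimulationDesign(
                bank=small_bank, n_persons=1000, seed=77,
                defects=(ct.DifShift("i2", 0.8),),
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank, _ = ct.fit_model(sim.responses, "GRM", max_iter=60)
            thetas, _ = ct.eap_thetas(sim.responses, bank)
            results = ct.dif_logistic(sim.responses, sim.groups, thetas)
        by_id = {r.item_id: r for r in results}
        assert by_id["i2"].flagged

    def test_boundary_is_strict(self, small_bank, clean_sim):
        thetas, _ = ct.eap_thetas(clean_sim.responses, small_bank)
        base = ct.dif_logistic(clean_sim.responses, clean_sim.groups, thetas)
        top = max(r.delta_r2 for r in base)
        # moving the cut onto the largest observed effect must leave it unflagged
        again = ct.dif_logistic(
            clean_sim.responses, clean_sim.groups, thetas, threshold=top
        )
        assert sum(r.flagged for r in again) == 0

    def test_requires_two_groups(self, small_bank, clean_sim):
        thetas, _ = ct.eap_thetas(clean_sim.responses, small_bank)
        with pytest.raises(QCError):
            ct.dif_logistic(clean_sim.responses, np.zeros(1000), thetas)


class TestPipeline:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_planted_defects_are_removed(self, seed):
        """Near-duplicates, weak items, and DIF items are all caught, with at
        most one misclassification per run."""
        bank = ct.generate_bank(30, n_categories=[2] * 22 + [5] * 8, seed=33)
        planted = {"i5", "i6", "i10", "i20", "i15", "i22"}
        defects = (
            ct.LocalDependence("i5", "i6", strength=1.5),
            ct.LowDiscrimination("i10", a=0.3),
            ct.LowDiscrimination("i20", a=0.3),
            ct.DifShift("i15", 0.8),
            ct.DifShift("i22", 0.8),
        )
        sim = ct.simulate_responses(
            ct.SimulationDesign(bank=bank, n_persons=1000, seed=seed, defects=defects)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.run_qc_pipeline(sim.responses, ct.QCConfig(max_iter=60),
                                     groups=sim.groups)
        dropped = {i for stage in res.audit for i in stage["dropped"]}
        # exactly one member of the dependent pair goes; the rest of the
        # planted set goes in full, with <= 1 misclassification either way
        ld_stage = next(s for s in res.audit if s["stage"] == "local_independence")
        assert len(set(ld_stage["dropped"]) & {"i5", "i6"}) == 1
        expected = planted - ({"i5", "i6"} - set(ld_stage["dropped"]))
        assert len(expected - dropped) <= 1  # missed planted defects
        assert len(dropped - planted) <= 1  # spurious deletions

    def test_clean_data_zero_deletions_and_idempotence(self, clean_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.run_qc_pipeline(clean_sim.responses, ct.QCConfig(max_iter=60),
                                     groups=clean_sim.groups)
        assert all(stage["dropped"] == [] for stage in res.audit)
        assert len(res.bank) == 10
        # pipeline output equals its input -> a second pass is a no-op too
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = ct.run_qc_pipeline(res.responses, ct.QCConfig(max_iter=60),
                                      groups=clean_sim.groups)
        assert all(stage["dropped"] == [] for stage in res2.audit)

    def test_audit_records_every_stage(self, clean_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.run_qc_pipeline(clean_sim.responses, ct.QCConfig(max_iter=40))
        stages = [s["stage"] for s in res.audit]
        assert stages == [
            "unidimensionality", "model_selection", "local_independence",
            "discrimination", "item_fit", "dif",
        ]
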