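"""Synthetic-data generators: determinism, multinomial moments, round trips."""

import numpy as np
import pytest

import slisy
from slisy.simulate import SimulationError


@pytest.fixture(scope="module")
def toy5():
    return slisy.toy_design(n_sites=5, seed=12)


def uniform_truth(design, hot_index=0, selectivity=10.0):
    hot = design.variants[hot_index].clone_id
    return slisy.PanningTruth.uniform_with_hot_clone(
        design, hot, selectivity=selectivity
    ), hot


class TestPanningTruth:
    def test_simplex_violation_rejected(self, toy5):
        ids = [c.clone_id for c in toy5.clones]
        n = len(ids)
        with pytest.raises(SimulationError):
            slisy.PanningTruth(ids, np.full(n, 0.5), np.full(n, 0.1), np.full(n, 0.1))

    def test_capture_probabilities_bounded(self, toy5):
        ids = [c.clone_id for c in toy5.clones]
        n = len(ids)
        with pytest.raises(SimulationError):
            slisy.PanningTruth(ids, np.full(n, 1 / n), np.full(n, 1.5),
                               np.full(n, 0.1))

    def test_affinity_link_is_an_occupancy(self):
        assert slisy.capture_from_affinity(0.0, 1e8) == 0.0
        # C = KD (KA = 1/KD) gives half occupancy
        assert slisy.capture_from_affinity(1e-8, 1e8) == pytest.approx(0.5)


class TestSimulatePanning:
    def test_same_seed_identical_counts(self, toy5):
        truth, _ = uniform_truth(toy5)
        cfg = slisy.SimConfig(depth=5000, seed=21)
        a = slisy.simulate_panning(truth, cfg, design=toy5)
        b = slisy.simulate_panning(truth, cfg, design=toy5)
        assert a.counts.equals(b.counts)
        assert a.metadata["seed"] == 21

    def test_single_clone_takes_all_counts(self, toy5):
        ids = [c.clone_id for c in toy5.clones]
        n = len(ids)
        f = np.zeros(n)
        f[3] = 1.0
        truth = slisy.PanningTruth(ids, f, np.full(n, 0.5), np.full(n, 0.5))
        table = slisy.simulate_panning(truth, slisy.SimConfig(depth=1000, seed=0))
        assert table.counts.iloc[3].sum() == 3000
        assert table.counts.drop(table.counts.index[3]).values.sum() == 0

    def test_bound_counts_match_multinomial_moments(self, toy5):
        truth, hot = uniform_truth(toy5)
        q2 = truth.input_fractions * truth.p2
        q2 = q2 / q2.sum()
        hot_idx = truth.clone_ids.index(hot)
        depth, reps = 2000, 300
        draws = np.array(
            [
                slisy.simulate_panning(truth, slisy.SimConfig(depth=depth, seed=s))
                .counts.iloc[hot_idx, 1]
                for s in range(reps)
            ]
        )
        expected = depth * q2[hot_idx]
        se = np.sqrt(depth * q2[hot_idx] * (1 - q2[hot_idx]) / reps)
        assert abs(draws.mean() - expected) < 3 * se

    def test_symmetric_capture_gives_flat_binding_ratios(self, toy5):
        ids = [c.clone_id for c in toy5.clones]
        n = len(ids)
        truth = slisy.PanningTruth(
            ids, np.full(n, 1 / n), np.full(n, 0.1), np.full(n, 0.1)
        )
        table = slisy.simulate_panning(truth, slisy.SimConfig(depth=200_000, seed=4))
        ranked = slisy.score_clones(table, slisy.ScoreConfig(use_ci=False))
        ratios = ranked["binding_ratio"]
        assert ratios.between(0.7, 1.4).all()


class TestEmitReads:
    def test_error_free_reads_round_trip_exactly(self, toy5):
        truth, _ = uniform_truth(toy5)
        cfg = slisy.SimConfig(depth=3000, error_rate=0.0, umi_dup_mean=1.0, seed=8)
        table = slisy.simulate_panning(truth, cfg, design=toy5)
        reads = slisy.emit_reads(table, toy5, cfg)
        index_map = {b: s for b, s in
                     zip(("ACGTAC", "TGCATG", "GTACGT"), table.counts.columns)}
        back, qc = slisy.count_reads(reads, toy5, index_map, cfg.roles)
        assert back.counts.equals(table.counts)
        for s in qc.per_sample.values():
            assert s["unassigned"] == 0 and s["untranslatable"] == 0

    def test_errors_produce_unassigned_but_conserve_molecules(self, toy5):
        truth, _ = uniform_truth(toy5)
        cfg = slisy.SimConfig(depth=4000, error_rate=0.01, umi_dup_mean=1.0, seed=8)
        table = slisy.simulate_panning(truth, cfg, design=toy5)
        reads = slisy.emit_reads(table, toy5, cfg)
        index_map = {b: s for b, s in
                     zip(("ACGTAC", "TGCATG", "GTACGT"), table.counts.columns)}
        back, qc = slisy.count_reads(reads, toy5, index_map, cfg.roles)
        total_unassigned = sum(s["unassigned"] for s in qc.per_sample.values())
        assert total_unassigned > 0
        for s in qc.per_sample.values():
            assert s["assigned"] + s["unassigned"] + s["untranslatable"] == \
                s["molecules"]
        assert qc.n_input_reads == len(reads)

    def test_zero_depth_gives_no_reads(self, toy5):
        truth, _ = uniform_truth(toy5)
        cfg = slisy.SimConfig(depth=0, seed=0)
        table = slisy.simulate_panning(truth, cfg, design=toy5)
        assert slisy.emit_reads(table, toy5, cfg) == []

    def test_duplication_inflates_reads_not_molecules(self, toy5):
        truth, _ = uniform_truth(toy5)
        cfg = slisy.SimConfig(depth=2000, error_rate=0.0, umi_dup_mean=3.0, seed=2)
        table = slisy.simulate_panning(truth, cfg, design=toy5)
        reads = slisy.emit_reads(table, toy5, cfg)
        assert len(reads) > 1.5 * int(table.counts.values.sum())
        index_map = {b: s for b, s in
                     zip(("ACGTAC", "TGCATG", "GTACGT"), table.counts.columns)}
        back, _ = slisy.count_reads(reads, toy5, index_map, cfg.roles)
        assert back.counts.equals(table.counts)


class TestFlowAndDoseSims:
    def test_quadrant_sim_matches_composition(self):
        comp = (0.35, 0.63, 0.01, 0.01)
        q = slisy.simulate_flow_quadrants(comp, n_cells=10_000, seed=6)
        pct = slisy.quadrant_percentages(q)
        for key, p in zip(("trbc1_only", "trbc2_only", "dual_pos", "dual_neg"), comp):
            se = 100 * np.sqrt(p * (1 - p) / 10_000)
            assert abs(pct[key] - 100 * p) < 3 * se + 1e-9

    def test_patient_sim_matches_generating_fraction(self):
        total = 20_000
        frac = 0.22
        p = slisy.simulate_patient_flow(frac, total, seed=3)
        got = slisy.malignant_fraction(p.cancer, p.total_T)
        se = 100 * np.sqrt(frac * (1 - frac) / total)
        assert abs(got - 22.0) < 3 * se

    def test_noiseless_dose_response_recovers_parameters(self):
        true = slisy.FourPLFit(top=100.0, bottom=2.0, hill=1.1, ic50=1.8)
        doses = np.geomspace(0.01, 1000, 10)
        df = slisy.simulate_dose_response(true, doses, noise_sd=0.0, seed=0)
        fit = slisy.fit_4pl(df["dose"], df["response"])
        assert fit.ic50 == pytest.approx(1.8, rel=1e-5)

    def test_dose_response_seed_recorded_and_reproducible(self):
        true = slisy.FourPLFit(top=100.0, bottom=0.0, hill=1.0, ic50=5.0)
        doses = np.geomspace(0.1, 100, 8)
        a = slisy.simulate_dose_response(true, doses, noise_sd=2.0, seed=9)
        b = slisy.simulate_dose_response(true, doses, noise_sd=2.0, seed=9)
        assert (a["response"] == b["response"]).all()
        assert (a["seed"] == 9).all()
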