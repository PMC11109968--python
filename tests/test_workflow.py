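import numpy as np
import pandas as pd
import pytest

from pbmotif.logo import frequency_to_energy, motif_report
from pbmotif.probeio import ProbeSet
from pbmotif.regressor import BindingModel, FitConfig, FitResult
from pbmotif.simulate import random_motif, synthetic_probes
from pbmotif.thermo import EnergyMatrix, normalize_matrix
from pbmotif.workflow import (ClusterReport, WorkflowConfig, WorkflowError,
                              build_subset, classification_threshold,
                              cluster_restarts, extend_motif, grow_borders,
                              prune_positions, run_workflow,
                              select_motif_length, t7_config)


def make_fit_result(matrix, ps, **kw):
    """FitResult wrapper around a hand-constructed matrix."""
    model = BindingModel(ps, motif_length=matrix.length)
    occ = model.predict(matrix)
    r = model.score(matrix)
    defaults = dict(matrix=matrix, pearson_r=r, mae=0.0, occupancies=occ,
                    max_occupancy=float(occ.max()), converged=True, n_iter=0,
                    seed=0, config=FitConfig(motif_length=matrix.length))
    defaults.update(kw)
    return FitResult(**defaults)


@pytest.fixture(scope="module")
def planted():
    """(probes, true 3-nt matrix): noiseless planted dataset, 400 probes."""
    ps = synthetic_probes(400, 30, seed=20)
    m = random_motif(3, 4.5, seed=21)
    model = BindingModel(ps, motif_length=3)
    m = model.calibrate_dG0(m, 1.2)
    return ps.with_signals(model.predict(m)), m


class TestBuildSubset:
    def test_four_percent_of_3149_gives_250(self):
        rng = np.random.default_rng(0)
        ps = synthetic_probes(3149, 20, seed=1).with_signals(
            rng.uniform(0, 1, 3149))
        cfg = WorkflowConfig()
        sub = build_subset(ps, cfg)
        assert len(sub) == 250  # floor(0.04 * 3149) per tail
        sorted_sig = np.sort(ps.signals)
        assert set(sub.signals) == set(sorted_sig[:125]) | set(sorted_sig[-125:])

    def test_cap_balances_500_and_500(self):
        rng = np.random.default_rng(1)
        ps = synthetic_probes(20000, 12, seed=2).with_signals(
            rng.uniform(0, 1, 20000))
        sub = build_subset(ps, WorkflowConfig())
        assert len(sub) == 1000
        median = np.median(ps.signals)
        assert (sub.signals > median).sum() == 500

    def test_no_downsampling_when_cap_large(self):
        rng = np.random.default_rng(2)
        ps = synthetic_probes(100, 12, seed=3).with_signals(
            rng.uniform(0, 1, 100))
        sub = build_subset(ps, WorkflowConfig(subset_cap=10_000))
        assert len(sub) == 8  # floor(0.04*100)=4 per tail

    def test_too_few_probes_raises(self):
        ps = synthetic_probes(30, 12, seed=4).with_signals(np.linspace(0, 1, 30))
        with pytest.raises(ValueError):
            build_subset(ps, WorkflowConfig())


class TestSelectMotifLength:
    def test_single_length_grid(self, planted):
        ps, _ = planted
        cfg = WorkflowConfig(length_grid=(3,), cv_folds=3, seed=5)
        L, table = select_motif_length(ps, cfg)
        assert L == 3 and len(table) == 1

    def test_criterion_column_matches_formula(self, planted):
        ps, _ = planted
        cfg = WorkflowConfig(length_grid=(2, 3), cv_folds=3, seed=6)
        L, table = select_motif_length(ps, cfg)
        np.testing.assert_allclose(
            table["criterion"],
            table["mean_r_val"] ** 2 / np.sqrt(table["motif_length"]))
        chosen = table.loc[table["criterion"].idxmax(), "motif_length"]
        assert L == chosen

    def test_r2_over_sqrt_length_prefers_shorter_on_tie(self):
        # criterion arithmetic: mean r^2 of 0.45 at L=2 beats 0.46 at L=3
        crit = {2: 0.45 / np.sqrt(2), 3: 0.46 / np.sqrt(3)}
        assert crit[2] == pytest.approx(0.3182, abs=1e-4)
        assert crit[3] == pytest.approx(0.2656, abs=1e-4)
        assert max(crit, key=crit.get) == 2


class TestClusterRestarts:
    def test_identical_matrices_do_not_crash(self, planted):
        ps, m = planted
        fr = make_fit_result(m, ps)
        rep = cluster_restarts([fr] * 20)
        assert rep.coordinates.shape == (20, 2)
        assert np.allclose(rep.coordinates, 0)

    def test_mixed_lengths_rejected(self, planted):
        ps, m = planted
        a = make_fit_result(m, ps)
        longer = EnergyMatrix(np.vstack([m.ddG, np.zeros((1, 4))]), m.dG0)
        b = make_fit_result(longer, ps)
        with pytest.raises(ValueError):
            cluster_restarts([a, a, b])

    def test_reverse_complement_twin_flagged(self):
        rng = np.random.default_rng(30)
        ps = synthetic_probes(50, 20, seed=31, strandedness="double")
        # dG0 high enough that double-strand sites do not saturate
        m = normalize_matrix(rng.normal(size=(3, 4)), 2.0)
        # signals generated by the motif itself, so it is the best restart
        ps = ps.with_signals(
            BindingModel(ps, motif_length=3, strandedness="double").predict(m))
        cfg_ds = FitConfig(motif_length=3, strandedness="double")
        fits = [make_fit_result(m, ps, config=cfg_ds),
                make_fit_result(m.reverse_complement(), ps, config=cfg_ds),
                make_fit_result(normalize_matrix(rng.normal(size=(3, 4)), 2.0),
                                ps, config=cfg_ds)]
        assert cluster_restarts(fits).rc_twin_present is True
        no_twin = [fits[0], fits[2],
                   make_fit_result(normalize_matrix(rng.normal(size=(3, 4)), 2.0),
                                   ps, config=cfg_ds)]
        assert cluster_restarts(no_twin).rc_twin_present is False

    def test_needs_three_results(self, planted):
        ps, m = planted
        with pytest.raises(ValueError):
            cluster_restarts([make_fit_result(m, ps)] * 2)


class TestExtendGrowPrune:
    def test_zero_gain_neighbour_not_included(self, planted):
        ps, m = planted
        core = make_fit_result(m, ps)  # true model: r = 1, nothing to gain
        cfg = WorkflowConfig(seed=1)
        res = extend_motif(ps, core, cfg)
        assert res.matrix.length == m.length

    def test_extension_recovers_truncated_motif(self):
        # plant a 4-nt motif but hand extend_motif only its 3' 3-nt core
        ps = synthetic_probes(400, 30, seed=40)
        freq = np.array([[0, 0, 1, 0], [0, 0, 0, 1], [0, 1, 0, 0],
                         [1, 0, 0, 0]], dtype=float)  # GTCA
        true4 = frequency_to_energy(freq)
        model4 = BindingModel(ps, motif_length=4)
        true4 = model4.calibrate_dG0(true4, 1.2)
        ps = ps.with_signals(model4.predict(true4))
        core3 = BindingModel(ps, motif_length=3).fit(
            seed=2, start=frequency_to_energy(freq[1:]).with_dG0(true4.dG0))
        cfg = WorkflowConfig(seed=2, extension_span=2)
        extended = extend_motif(ps, core3, cfg)
        assert extended.matrix.length >= 4
        assert extended.pearson_r > core3.pearson_r

    def test_grow_borders_flat_terminals_no_growth(self, planted):
        ps, m = planted
        flat = EnergyMatrix(np.vstack([np.zeros((1, 4)), m.ddG,
                                       np.zeros((1, 4))]), m.dG0)
        current = make_fit_result(flat, ps)
        res = grow_borders(ps, current, WorkflowConfig(seed=3))
        assert res is current

    def test_grow_borders_informative_terminal_grows(self, planted):
        ps, m = planted  # 4.5-bit 3-mer: terminals well above 0.25 bit
        current = make_fit_result(m, ps)
        res = grow_borders(ps, current, WorkflowConfig(seed=4))
        assert res.matrix.length == m.length + 2

    def test_prune_drops_appended_zero_column(self, planted):
        ps, m = planted
        padded = EnergyMatrix(np.vstack([m.ddG, np.zeros((1, 4))]), m.dG0)
        current = make_fit_result(padded, ps)
        res = prune_positions(ps, current, WorkflowConfig(seed=5))
        assert res.matrix.length == m.length

    def test_prune_keeps_dominant_interior_position(self, planted):
        ps, m = planted
        # zero borders around a strong core: only borders may go
        padded = EnergyMatrix(np.vstack([np.zeros((1, 4)), m.ddG,
                                         np.zeros((1, 4))]), m.dG0)
        current = make_fit_result(padded, ps)
        res = prune_positions(ps, current, WorkflowConfig(seed=6))
        assert res.matrix.length >= m.length
        # the informative core survives: r stays high
        assert res.pearson_r > 0.95

    def test_prune_never_lengthens_and_single_position_rejected(self, planted):
        ps, m = planted
        current = make_fit_result(m, ps)
        res = prune_positions(ps, current, WorkflowConfig(seed=7))
        assert res.matrix.length <= m.length
        one = make_fit_result(EnergyMatrix(m.ddG[:1].copy(), m.dG0), ps)
        with pytest.raises(ValueError):
            prune_positions(ps, one, WorkflowConfig())


class TestClassificationThreshold:
    def test_arithmetic(self):
        ps = synthetic_probes(3, 12, seed=8).with_signals([0.05, 0.10, 0.15])
        # mean 0.1, sample sd 0.05, k=4 -> 0.3
        assert classification_threshold(ps, WorkflowConfig()) == \
            pytest.approx(0.3)

    def test_monotone_in_multiplier(self):
        rng = np.random.default_rng(9)
        ps = synthetic_probes(50, 12, seed=9).with_signals(
            rng.uniform(0, 1, 50))
        ts = [classification_threshold(
            ps, WorkflowConfig(classification_sd_multiplier=k))
            for k in (2, 4, 6)]
        assert ts[0] < ts[1] < ts[2]

    def test_zero_variance_rejected(self):
        ps = synthetic_probes(5, 12, seed=10).with_signals(np.full(5, 0.4))
        with pytest.raises(ValueError):
            classification_threshold(ps, WorkflowConfig())


@pytest.fixture(scope="module")
def small_run():
    ps = synthetic_probes(600, 30, seed=50)
    m = random_motif(3, 4.0, seed=81)
    model = BindingModel(ps, motif_length=3)
    m = model.calibrate_dG0(m, 1.2)
    rng = np.random.default_rng(52)
    sig = np.clip(model.predict(m) + rng.normal(0, 0.03, len(ps)), 0, None)
    ps = ps.with_signals(sig)
    cfg = WorkflowConfig(length_grid=(2, 3, 4), n_restarts=6,
                         subset_cap=300, cv_folds=3, seed=0)
    return ps, m, cfg, run_workflow(ps, cfg)


class TestRunWorkflow:
    def test_recovers_planted_motif(self, small_run):
        from pbmotif.logo import aligned_motif_distance
        ps, m, cfg, report = small_run
        assert report.train_r > 0.95 and report.test_r > 0.9
        dist, _ = aligned_motif_distance(motif_report(m),
                                         motif_report(report.final.matrix))
        assert dist <= 0.5

    def test_history_records_stages(self, small_run):
        _, _, _, report = small_run
        stages = list(report.history["stage"])
        assert stages[0] == "integrity" and stages[-1] == "final"
        assert {"motif_length", "train_r", "test_r"} <= set(report.history.columns)

    def test_final_r_within_two_percent_of_core(self, small_run):
        _, _, _, report = small_run
        core_r = float(report.history.query("stage == 'core'")["train_r"].iloc[0])
        assert report.train_r >= core_r * 0.98

    def test_deterministic_rerun(self, small_run):
        ps, _, cfg, report = small_run
        again = run_workflow(ps, cfg)
        pd.testing.assert_frame_equal(report.history, again.history)

    def test_outputs_written(self, small_run, tmp_path):
        from pbmotif.workflow import save_report
        _, _, _, report = small_run
        save_report(report, tmp_path)
        for name in ("energy_matrix.json", "history.tsv", "motif_info.png",
                     "occupancy_vs_signal.png", "restart_pca.png"):
            assert (tmp_path / name).exists()

    def test_stage_tagged_error(self):
        ps = synthetic_probes(60, 8, seed=60).with_signals(np.full(60, 0.5))
        with pytest.raises(WorkflowError) as exc:
            run_workflow(ps, WorkflowConfig(length_grid=(3,)))
        assert exc.value.stage in ("split", "subset", "integrity")


def test_t7_preset_settings():
    cfg = t7_config()
    assert cfg.use_subset is False
    assert cfg.cv_repeats == 10
    assert cfg.n_restarts == 200
    assert cfg.fit_dG0 is True and cfg.occupancy_target == 1.0
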