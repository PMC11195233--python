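"""Generator-level tests: stimulus, paradigm, epochs, cohorts, clinical."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import chirpsa as c
from chirpsa.synthdata import ALL_COMPONENTS, TRAIT_SCALES

from conftest import GAMMA1_WINDOWS


class TestChirpStimulus:
    def test_modulator_instantaneous_frequency_endpoints(self):
        _, mod = c.generate_chirp_stimulus()
        assert c.edge_instantaneous_frequency(mod, 1000.0, "end") == pytest.approx(100.0, abs=0.5)
        assert c.edge_instantaneous_frequency(mod, 1000.0, "start", fit_samples=256) == pytest.approx(0.0, abs=1.0)

    def test_total_modulator_cycles(self):
        # integral of f(t) = 50 t Hz over 2 s is 100 cycles
        spec = c.StimulusSpec()
        assert spec.phase(np.array([2.0]))[0] / (2 * np.pi) == pytest.approx(100.0)

    def test_instantaneous_frequency_law_is_linear(self):
        _, mod = c.generate_chirp_stimulus()
        f = c.instantaneous_frequency(mod, 1000.0)
        # 25 ms boxcar damps the per-sample discretisation ripple of the
        # phase-derivative estimate without biasing a linear law
        f = np.convolve(f, np.ones(25) / 25, mode="same")
        t = np.arange(mod.size) / 1000.0
        sel = (t >= 0.1) & (t <= 1.9)
        slope, intercept = np.polyfit(t[sel], f[sel], 1)
        resid = f[sel] - (slope * t[sel] + intercept)
        r2 = 1 - resid.var() / f[sel].var()
        assert slope == pytest.approx(50.0, rel=0.01)
        assert r2 > 0.999

    def test_pink_carrier_spectrum_slope(self):
        rng = np.random.default_rng(0)
        x = c.pink_noise(2 ** 15, 1000.0, rng)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(2 ** 15, 1e-3)
        band = (freqs >= 2) & (freqs <= 400)
        slope = np.polyfit(np.log(freqs[band]), np.log(spec[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            c.StimulusSpec(duration=-1)
        with pytest.raises(ValueError):
            c.StimulusSpec(f_start=50, f_end=10)
        with pytest.raises(ValueError):
            c.ParadigmSpec(isi_min=2000, isi_max=1500)


class TestParadigm:
    def test_repetitions_isis_and_determinism(self):
        onsets = c.generate_paradigm(c.ParadigmSpec(seed=3))
        assert onsets.size == 200
        gaps = np.diff(onsets) - 2000.0  # offset-to-onset
        assert gaps.min() >= 1500.0 and gaps.max() <= 2000.0
        again = c.generate_paradigm(c.ParadigmSpec(seed=3))
        assert np.array_equal(onsets, again)


class TestEpochSynthesis:
    def test_component_additivity_and_seed_contract(self):
        profile = c.SubjectProfile(subject_id="s")
        kwargs = dict(nodes=("lh-superiortemporal",), n_trials=4, seed=9)
        full = c.synthesize_subject_epochs(profile, **kwargs)["lh-superiortemporal"].data
        parts = sum(
            c.synthesize_subject_epochs(profile, components=(comp,), **kwargs)[
                "lh-superiortemporal"].data
            for comp in ALL_COMPONENTS)
        np.testing.assert_allclose(parts, full, atol=1e-12)
        again = c.synthesize_subject_epochs(profile, **kwargs)["lh-superiortemporal"].data
        assert np.array_equal(full, again)

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            c.synthesize_subject_epochs(
                c.SubjectProfile(subject_id="s"), nodes=("lh-nowhere",),
                n_trials=4, seed=0)

    def test_perfect_locking_gives_near_unit_ridge_itpc(self, gamma1_plan):
        profile = c.SubjectProfile(
            subject_id="s", kappa_chirp=500.0, gamma_bg_power=0.0,
            alpha_power=0.0, noise_1f_scale=0.0, onset_gain=0.0)
        ep = c.synthesize_subject_epochs(
            profile, nodes=("lh-superiortemporal",), n_trials=200, seed=2,
        )["lh-superiortemporal"]
        m = c.compute_measures(ep.data, gamma1_plan)
        col = np.argmin(np.abs(m.times - 800))
        assert m.itpc_corrected[m.freqs == 39, col].item() >= 0.9

    def test_unlocked_subject_corrected_ridge_itpc_near_zero(self, gamma1_plan):
        vals = []
        for seed in range(5):
            profile = c.SubjectProfile(subject_id="s", kappa_chirp=0.0)
            ep = c.synthesize_subject_epochs(
                profile, nodes=("lh-superiortemporal",), n_trials=200,
                seed=seed)["lh-superiortemporal"]
            m = c.compute_measures(ep.data, gamma1_plan)
            col = np.argmin(np.abs(m.times - 800))
            vals.append(m.itpc_corrected[m.freqs == 39, col].item())
        assert abs(np.mean(vals)) <= 0.05

    def test_gamma_background_doubling_shifts_stp_6db(self, gamma1_plan):
        kwargs = dict(nodes=("lh-superiortemporal",), n_trials=30, seed=4,
                      components=("gamma",))
        low = c.synthesize_subject_epochs(
            c.SubjectProfile(subject_id="a", gamma_bg_power=1.0), **kwargs)
        high = c.synthesize_subject_epochs(
            c.SubjectProfile(subject_id="b", gamma_bg_power=2.0), **kwargs)
        m_low = c.compute_measures(low["lh-superiortemporal"].data, gamma1_plan)
        m_high = c.compute_measures(high["lh-superiortemporal"].data, gamma1_plan)
        sel = m_low.valid
        diff = (m_high.stp - m_low.stp)[sel].mean()
        assert diff == pytest.approx(10 * np.log10(4), abs=0.5)

    def test_ridge_itpc_monotone_in_locking_concentration(self, gamma1_plan):
        # trial-averaged over 2 seeds per kappa to damp sampling noise
        means = []
        for kappa in (0.0, 1.0, 5.0, 100.0):
            vals = []
            for seed in (0, 1):
                profile = c.SubjectProfile(subject_id="s", kappa_chirp=kappa)
                ep = c.synthesize_subject_epochs(
                    profile, nodes=("lh-superiortemporal",), n_trials=100,
                    seed=seed)["lh-superiortemporal"]
                m = c.compute_measures(ep.data, gamma1_plan)
                col = np.argmin(np.abs(m.times - 800))
                vals.append(m.itpc_corrected[m.freqs == 39, col].item())
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestLockingCalibration:
    def test_kappa_inverts_mean_resultant_length(self):
        for target in (0.05, 0.3, 0.6, 0.9):
            kappa = c.kappa_for_locking(target)
            assert c.mean_resultant_length(kappa) == pytest.approx(target, abs=1e-6)

    def test_degenerate_targets(self):
        assert c.kappa_for_locking(0.0) == 0.0
        with pytest.raises(ValueError):
            c.kappa_for_locking(1.0)


class TestCohort:
    def test_metadata_cells_and_determinism(self):
        cfg = c.SyntheticCohortConfig(
            n_per_cell=2, n_trials=4, node_set=("lh-superiortemporal",),
            seed=11)
        cohort = c.generate_cohort(cfg)
        counts = cohort.metadata.groupby(["group", "sex"]).size()
        assert (counts == 2).all() and len(counts) == 4
        sid = cohort.metadata["subject_id"].iloc[0]
        a = cohort.epochs(sid)["lh-superiortemporal"].data
        b = c.generate_cohort(cfg).epochs(sid)["lh-superiortemporal"].data
        assert np.array_equal(a, b)

    def test_single_subject_cell_builds_but_stats_reject(self):
        cfg = c.SyntheticCohortConfig(
            n_per_cell=1, n_trials=4, node_set=("lh-superiortemporal",),
            seed=0)
        cohort = c.generate_cohort(cfg)
        table = pd.DataFrame({
            "subject_id": cohort.metadata["subject_id"],
            "node": "lh-superiortemporal",
            "region": "left_temporal",
            "gamma1_stp": np.arange(len(cohort.metadata), dtype=float),
        })
        with pytest.raises(ValueError, match="insufficient replication"):
            c.fit_region_model(table, cohort.metadata, "gamma1_stp")

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            c.SyntheticCohortConfig(n_per_cell=0)
        with pytest.raises(ValueError):
            c.SyntheticCohortConfig(node_set=("lh-atlantis",))

    def test_designed_locking_deficit_recovers_cohens_d(self, gamma1_plan):
        """Designed d = -0.75 on temporal gamma1 ITPC, male cells of 20.

        Recovery is averaged over 10 cohort draws (sampling SD of d at this
        cell size is ~0.33 per draw); the long-trial setting keeps the
        trial-count measurement noise from attenuating the standardized
        effect.
        """
        effect = (c.EffectSpec("chirp_locking", d=-0.75, group="FXS", sex="M",
                               regions=("left_temporal", "right_temporal")),)
        nodes = ("lh-superiortemporal", "rh-superiortemporal")
        ds = []
        for seed in range(10):
            cfg = c.SyntheticCohortConfig(
                n_per_cell=20, n_trials=150, node_set=nodes,
                effect_map=effect, seed=seed, sexes=("M",))
            cohort = c.generate_cohort(cfg)
            measures = {(sid, node): c.compute_measures(ep.data, gamma1_plan)
                        for sid, eps in cohort.iter_epochs()
                        for node, ep in eps.items()}
            table = c.compute_feature_table(measures, windows=GAMMA1_WINDOWS[:1])
            means = (c.region_means(table)
                     .merge(cohort.metadata, on="subject_id")
                     .groupby(["subject_id", "group"])["gamma1_itpc"]
                     .mean().reset_index())
            a = means.loc[means.group == "FXS", "gamma1_itpc"]
            b = means.loc[means.group == "TDC", "gamma1_itpc"]
            ds.append(c.cohens_d(a, b))
        assert np.mean(ds) == pytest.approx(-0.75, abs=0.35)


class TestClinicalScores:
    @staticmethod
    def _fxs_frame(n=36, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i:03d}" for i in range(n)]
        features = pd.DataFrame({"sa_temporal": rng.standard_normal(n)}, index=idx)
        features.index.name = "subject_id"
        metadata = pd.DataFrame({"subject_id": idx, "group": "FXS", "sex": "M"})
        return features, metadata

    def test_designed_rho_recovered(self):
        features, metadata = self._fxs_frame()
        rho_map = {"WJ3": {"feature": "sa_temporal", "rho": 0.70}}
        rhos = [spearmanr(
            c.generate_clinical_scores(metadata, features, rho_map, seed=s)["WJ3"],
            features["sa_temporal"])[0] for s in range(20)]
        inside = np.sum((np.array(rhos) >= 0.55) & (np.array(rhos) <= 0.85))
        assert inside >= 18

    def test_null_rho_stays_small(self):
        features, metadata = self._fxs_frame()
        rhos = [abs(spearmanr(
            c.generate_clinical_scores(metadata, features, {}, seed=s)["WJ3"],
            features["sa_temporal"])[0]) for s in range(40)]
        assert np.mean(np.array(rhos) < 0.35) >= 0.95

    def test_score_calibration_matches_population(self):
        features, metadata = self._fxs_frame(n=400)
        clinical = c.generate_clinical_scores(metadata, features, {}, seed=1)
        assert clinical["WJ3"].mean() == pytest.approx(65.2, rel=0.10)
        assert clinical["WJ3"].std() == pytest.approx(17.9, rel=0.10)

    def test_invalid_rho_rejected(self):
        features, metadata = self._fxs_frame()
        with pytest.raises(ValueError):
            c.generate_clinical_scores(
                metadata, features,
                {"WJ3": {"feature": "sa_temporal", "rho": 1.0}}, seed=0)
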