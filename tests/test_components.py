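"""Component quantification: windowed means, FRN peak-to-peak, validation."""

import numpy as np
import pandas as pd
import pytest

from chronoerp.components import (
    CNV_WINDOWS,
    ComponentWindows,
    extract_cnv,
    extract_frn,
    validate_selection,
    window_mean,
)


def _meta(categories, conditions=None):
    n = len(categories)
    df = pd.DataFrame({
        "trial_index": np.arange(n),
        "rt_ms": np.full(n, 1200.0),
        "category": categories,
        "kept": [True] * n,
    })
    if conditions is not None:
        df["condition"] = conditions
    return df


class TestWindowMean:
    def test_constant_erp(self, epochs_factory):
        data = np.full((4, 2, 64), 10.0)
        ep = epochs_factory(data, units_tag="µV/m²", ch_names=("Cz", "FCz"))
        assert window_mean(ep, "Cz", (0.0, 100.0)) == pytest.approx(10.0)

    def test_electrode_averaging(self, epochs_factory):
        data = np.zeros((1, 2, 64))
        data[:, 0] = 10.0
        data[:, 1] = -10.0
        ep = epochs_factory(data, units_tag="µV/m²", ch_names=("a", "b"))
        assert window_mean(ep, ("a", "b"), (0.0, 100.0)) == pytest.approx(0.0)

    def test_linearity_in_signal(self, epochs_factory):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((6, 3, 64))
        ep1 = epochs_factory(data, units_tag="µV/m²")
        ep2 = epochs_factory(3.0 * data, units_tag="µV/m²")
        w1 = window_mean(ep1, "ch0", (20.0, 120.0))
        w2 = window_mean(ep2, "ch0", (20.0, 120.0))
        assert w2 == pytest.approx(3.0 * w1, rel=1e-12)

    def test_requires_current_density_units(self, epochs_factory):
        ep = epochs_factory(np.zeros((1, 1, 8)), units_tag="µV")
        with pytest.raises(ValueError):
            window_mean(ep, "ch0", (0.0, 10.0))

    def test_missing_condition_gives_nan(self, epochs_factory):
        ep = epochs_factory(np.zeros((2, 1, 64)), units_tag="µV/m²",
                            meta=_meta(["early", "late"]))
        assert np.isnan(window_mean(ep, "ch0", (0.0, 50.0), condition="correct"))


class TestCnv:
    def _relocked(self, epochs_factory, values_by_window, n_trials=4):
        rate = 256.0  # lock at sample 512
        n_samp = 769
        data = np.zeros((n_trials, 1, n_samp))
        times = -512 * (1000.0 / rate) + np.arange(n_samp) * (1000.0 / rate)
        for (w0, w1), v in values_by_window.items():
            sel = (times >= w0 - 2.0) & (times <= w1 + 2.0)
            data[:, :, sel] = v
        cats = ["correct", "error"] * (n_trials // 2)
        return epochs_factory(data, rate=rate, lock="response", t0_ms=times[0],
                              ch_names=("Cz",), units_tag="µV/m²",
                              baseline_applied=True, meta=_meta(cats))

    def test_window_extraction(self, epochs_factory):
        vals = {CNV_WINDOWS["w1"]: -5.0, CNV_WINDOWS["w2"]: 3.0,
                CNV_WINDOWS["w3"]: -1.0, CNV_WINDOWS["w4"]: -20.0}
        ep = self._relocked(epochs_factory, vals)
        out = extract_cnv(ep)
        got = out.loc[out["condition"] == "correct", "value"].to_numpy()
        assert got == pytest.approx([-5.0, 3.0, -1.0, -20.0])

    def test_zero_signal(self, epochs_factory):
        ep = self._relocked(epochs_factory, {})
        assert np.allclose(extract_cnv(ep)["value"], 0.0)


class TestFrn:
    def _feedback(self, epochs_factory, wave_correct, wave_error):
        rate = 256.0
        n_samp = 436
        data = np.zeros((2, 1, n_samp))
        data[0, 0] = wave_correct
        data[1, 0] = wave_error
        t0 = -51 * (1000.0 / rate)
        meta = _meta(["correct", "early"], conditions=["correct", "error"])
        return epochs_factory(data, rate=rate, lock="response", t0_ms=t0,
                              ch_names=("FCz",), units_tag="µV/m²",
                              baseline_applied=True, meta=meta)

    def _wave(self, rate=256.0, n=436, peak1=(205.0, -5.0), peak2=(305.0, -15.0)):
        t = -51 * (1000.0 / rate) + np.arange(n) * (1000.0 / rate)
        w = np.zeros(n)
        for c, a in (peak1, peak2):
            w += a * np.exp(-0.5 * ((t - c) / 15.0) ** 2)
        return w

    def test_identical_waveforms_give_zero_difference(self, epochs_factory):
        w = self._wave()
        ep = self._feedback(epochs_factory, w, w)
        out = extract_frn(ep, "control")
        assert out["frn_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_peak_to_peak_sign_convention(self, epochs_factory):
        wc = self._wave(peak1=(205.0, -5.0), peak2=(305.0, -25.0))  # p2p = -20
        we = self._wave(peak1=(205.0, -5.0), peak2=(305.0, -10.0))  # p2p = -5
        ep = self._feedback(epochs_factory, wc, we)
        out = extract_frn(ep, "control")
        assert out["p2p_correct"] == pytest.approx(-20.0, abs=0.3)
        assert out["p2p_error"] == pytest.approx(-5.0, abs=0.3)
        assert out["frn_difference"] == pytest.approx(-15.0, abs=0.5)

    def test_offset_invariance(self, epochs_factory):
        wc = self._wave(peak2=(305.0, -25.0))
        we = self._wave(peak2=(305.0, -10.0))
        base = extract_frn(self._feedback(epochs_factory, wc, we), "control")
        shifted = extract_frn(self._feedback(epochs_factory, wc + 40.0, we - 7.0), "control")
        assert shifted["p2p_correct"] == pytest.approx(base["p2p_correct"], abs=1e-9)
        assert shifted["p2p_error"] == pytest.approx(base["p2p_error"], abs=1e-9)

    def test_group_specific_windows(self, epochs_factory):
        # ADHD-C peaks sit later; a control-window waveform must not leak in
        w_late = self._wave(peak1=(230.0, -6.0), peak2=(325.0, -18.0))
        ep = self._feedback(epochs_factory, w_late, w_late)
        out = extract_frn(ep, "ADHD-C")
        assert out["p2p_correct"] == pytest.approx(-12.0, abs=0.5)


class TestValidateSelection:
    @staticmethod
    def _subject_epochs(factory, rng, n_ch=60, effect_ch=0, effect=0.0, polarity=-1.0):
        data = rng.normal(0.0, 1.0, (1, n_ch, 32))
        data[0, effect_ch, 10:20] += polarity * effect
        names = tuple(f"c{i}" for i in range(n_ch))
        return factory(data, rate=256.0, ch_names=names, units_tag="µV/m²")

    WINDOW = (10 * 1000.0 / 256.0, 19 * 1000.0 / 256.0)

    def test_injected_effect_detected_exactly(self, epochs_factory):
        rng = np.random.default_rng(10)
        eps = [self._subject_epochs(epochs_factory, rng, effect_ch=5, effect=10.0)
               for _ in range(16)]
        assert validate_selection(eps, self.WINDOW, "negative") == ["c5"]

    def test_wrong_polarity_not_selected(self, epochs_factory):
        rng = np.random.default_rng(11)
        eps = [self._subject_epochs(epochs_factory, rng, effect_ch=5, effect=10.0, polarity=+1.0)
               for _ in range(16)]
        assert "c5" not in validate_selection(eps, self.WINDOW, "negative")
        assert validate_selection(eps, self.WINDOW, "positive") == ["c5"]

    def test_false_positive_rate_bounded_under_null(self, epochs_factory):
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            eps = [self._subject_epochs(epochs_factory, rng) for _ in range(16)]
            total += len(validate_selection(eps, self.WINDOW, "negative"))
        assert total <= 3  # expected ~60 * 0.0007/2 * 20 ≈ 0.4 selections

    def test_needs_two_subjects(self, epochs_factory):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            validate_selection([self._subject_epochs(epochs_factory, rng)],
                               (0.0, 50.0), "negative")

    def test_selects_cnv_and_frn_electrodes_on_synthetic_cohort(self):
        """On simulated subjects the procedure picks exactly the generative
        sites: Cz for the late CNV window, FCz for the second FRN peak."""
        from chronoerp.components import CNV_WINDOWS, FRN_PEAK_WINDOWS
        from chronoerp.pipeline import PipelineConfig, analyze_subject
        from chronoerp.synthetic import DEFAULT_PROFILES, SimConfig, generate_subject

        sim = SimConfig(n_channels=16, n_trials=80)
        cfg = PipelineConfig(sim=sim, identity_spatial=True)
        relocked, feedback = [], []
        for seed in range(8):
            s = generate_subject(DEFAULT_PROFILES["control"], sim, seed=seed)
            r = analyze_subject(s.recording, "control", cfg)
            relocked.append(r["relocked"])
            feedback.append(r["feedback"])
        assert validate_selection(relocked, CNV_WINDOWS["w4"], "negative",
                                  condition="correct") == ["Cz"]
        peak2 = FRN_PEAK_WINDOWS["control"][1]
        assert validate_selection(feedback, peak2, "negative", condition="error") == ["FCz"]
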