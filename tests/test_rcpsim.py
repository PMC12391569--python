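import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lishlnr import codebook as cb, rcpsim as sim


@pytest.fixture(scope="module")
def small_setup():
    book = cb.generate_codebook(8, 4, 4, seed=1)
    targets = ["A", "B", "C"]
    panel = cb.assign_targets(book, targets, 0.10, seed=2)
    schedule = cb.build_schedule(book, n_channels=4, landmark_first_last=True)
    return book, panel, schedule


class TestSimulateField:
    def test_poisson_count_statistics(self, small_setup):
        _, panel, _ = small_setup
        counts = [
            len(sim.simulate_field(panel, {"A": 100.0}, 1000.0, 1000.0, seed=s).rcps)
            for s in range(200)
        ]
        se = np.sqrt(100.0 / 200)
        assert abs(np.mean(counts) - 100.0) < 3 * se

    def test_zero_density_empty_field(self, small_setup):
        _, panel, _ = small_setup
        field = sim.simulate_field(panel, {"A": 0.0}, 500.0, 500.0, seed=0)
        assert len(field.rcps) == 0

    def test_equal_densities_indistinguishable(self, small_setup):
        _, panel, _ = small_setup
        a, b = [], []
        for s in range(100):
            f = sim.simulate_field(panel, {"A": 200.0, "B": 200.0}, 500.0, 500.0, seed=s)
            c = f.counts()
            a.append(c.get("A", 0))
            b.append(c.get("B", 0))
        _, p = stats.mannwhitneyu(a, b)
        assert p > 0.01

    def test_positions_respect_bounds_and_separation(self, small_setup):
        _, panel, _ = small_setup
        f = sim.simulate_field(panel, {"A": 2000.0}, 300.0, 300.0, seed=4,
                               min_separation_um=4.0, edge_margin_um=3.0)
        xy = f.rcps[["x_um", "y_um"]].to_numpy()
        assert xy.min() >= 3.0 and xy.max() <= 297.0
        from scipy.spatial import cKDTree
        d, _ = cKDTree(xy).query(xy, k=2)
        assert d[:, 1].min() >= 4.0

    def test_zero_area_raises(self, small_setup):
        _, panel, _ = small_setup
        with pytest.raises(ValueError):
            sim.simulate_field(panel, {"A": 10.0}, 0.0, 100.0, seed=0)


class TestDecoy:
    @pytest.fixture()
    def field(self, small_setup):
        _, panel, _ = small_setup
        return sim.simulate_field(panel, {"A": 1000.0, "B": 500.0}, 1000.0, 1000.0,
                                  seed=7)

    def test_zero_fraction_is_identity(self, field):
        out = sim.apply_decoy(field, sim.DecoySpec("A", 0.0), seed=1)
        pd.testing.assert_frame_equal(out.rcps, field.rcps)

    def test_retention_within_binomial_ci(self, field):
        n = int((field.rcps["target"] == "A").sum())
        out = sim.apply_decoy(field, sim.DecoySpec("A", 0.9), seed=1)
        kept = int((out.rcps["target"] == "A").sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.1)
        assert lo <= kept <= hi

    def test_off_target_untouched(self, field):
        out = sim.apply_decoy(field, sim.DecoySpec("A", 0.99), seed=1)
        before = field.rcps[field.rcps["target"] == "B"].reset_index(drop=True)
        after = out.rcps[out.rcps["target"] == "B"].reset_index(drop=True)
        pd.testing.assert_frame_equal(before, after)

    def test_linearity_of_retained_fraction(self, field):
        n = int((field.rcps["target"] == "A").sum())
        fracs = [0.0, 0.5, 0.9, 0.99]
        kept = []
        for f in fracs:
            tot = 0
            for s in range(10):
                out = sim.apply_decoy(field, sim.DecoySpec("A", f), seed=s)
                tot += int((out.rcps["target"] == "A").sum())
            kept.append(tot / (10 * n))
        slope = stats.linregress(fracs, kept).slope
        assert slope == pytest.approx(-1.0, abs=0.05)


class TestDdntp:
    def test_zero_ratio_identity(self, small_setup):
        _, panel, _ = small_setup
        field = sim.simulate_field(panel, {"A": 300.0}, 500.0, 500.0, seed=3)
        out = sim.apply_ddntp(field, sim.DdntpSpec(0.0))
        pd.testing.assert_frame_equal(out.rcps, field.rcps)

    def test_dose_dependent_shrinkage_and_count_invariance(self, small_setup):
        _, panel, _ = small_setup
        field = sim.simulate_field(panel, {"A": 300.0}, 500.0, 500.0, seed=3)
        mean_radius = []
        for ratio in [0.0, 0.5, 1.0, 2.0, 5.0]:
            out = sim.apply_ddntp(field, sim.DdntpSpec(ratio))
            assert len(out.rcps) == len(field.rcps)
            mean_radius.append(out.rcps["radius_um"].mean())
        assert all(a >= b for a, b in zip(mean_radius, mean_radius[1:]))

    def test_size_scale_map(self):
        assert sim.DdntpSpec(0.0).size_scale == 1.0
        assert sim.DdntpSpec(1.0, coeff=1.0).size_scale == 0.5


class TestRender:
    def test_noiseless_bits_equal_codeword(self, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {t: 100.0 for t in panel.target_names},
                                   200.0, 200.0, seed=5, edge_margin_um=3.0)
        optics = sim.OpticsConfig(gaussian_noise_sd=0.0)
        _, truth = sim.render_stack(field, panel, book, schedule, optics,
                                    sim.ErrorModel(), seed=6)
        for _, row in truth.iterrows():
            assert row["bits_true"] == book.bitstring(row["codeword_id"])

    def test_landmark_cycles_light_every_rcp(self, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {"A": 100.0}, 200.0, 200.0, seed=5,
                                   edge_margin_um=3.0)
        optics = sim.OpticsConfig(gaussian_noise_sd=0.0, background_level=0.0)
        stack, _ = sim.render_stack(field, panel, book, schedule, optics,
                                    sim.ErrorModel(p_dropout=0.5), seed=6)
        lm = sorted(schedule.landmark_cycles)
        # landmark signal is unaffected by coding-bit dropout
        total = stack.images[lm[0], schedule.landmark_channel].sum()
        expected = 2 * np.pi * (
            field.rcps["amplitude"]
            * (np.sqrt(optics.psf_sigma_um**2 + field.rcps["radius_um"]**2)
               / optics.pixel_size_um) ** 2
        ).sum()
        assert total == pytest.approx(expected, rel=0.01)

    def test_summed_signal_proportional_to_lit_rcps(self, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {t: 200.0 for t in panel.target_names},
                                   300.0, 300.0, seed=8, edge_margin_um=4.0)
        optics = sim.OpticsConfig(gaussian_noise_sd=0.0, background_level=0.0)
        stack, truth = sim.render_stack(field, panel, book, schedule, optics,
                                        sim.ErrorModel(), seed=9)
        sigma_px = np.sqrt(optics.psf_sigma_um**2 + truth["radius_um"]**2) \
            / optics.pixel_size_um
        flux = 2 * np.pi * truth["amplitude"] * sigma_px**2  # Gaussian integral
        bits = np.array([[int(c) for c in b] for b in truth["bits_true"]])
        for bit in range(book.n_bits):
            cycle, channel = schedule.bit_slot(bit)
            expected = flux[bits[:, bit] == 1].sum()
            assert stack.images[cycle, channel].sum() == pytest.approx(
                expected, rel=0.01, abs=1e-6)

    def test_seed_determinism(self, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {"A": 100.0}, 200.0, 200.0, seed=5)
        optics = sim.OpticsConfig()
        err = sim.ErrorModel(p_dropout=0.1, p_spurious=0.01)
        s1, t1 = sim.render_stack(field, panel, book, schedule, optics, err, seed=3)
        s2, t2 = sim.render_stack(field, panel, book, schedule, optics, err, seed=3)
        assert np.array_equal(s1.images, s2.images)
        pd.testing.assert_frame_equal(t1, t2)

    def test_render_conserves_field(self, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {"A": 100.0}, 200.0, 200.0, seed=5)
        before = field.rcps.copy()
        sim.render_stack(field, panel, book, schedule, sim.OpticsConfig(),
                         sim.ErrorModel(), seed=3)
        pd.testing.assert_frame_equal(field.rcps, before)


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, small_setup):
        book, panel, schedule = small_setup
        field = sim.simulate_field(panel, {"A": 50.0}, 150.0, 150.0, seed=5)
        stack, truth = sim.render_stack(field, panel, book, schedule,
                                        sim.OpticsConfig(), sim.ErrorModel(), seed=3)
        sim.write_stack(tmp_path / "s", stack, truth)
        back = sim.read_stack(tmp_path / "s")
        assert np.array_equal(back.images, stack.images)
        assert back.schedule.landmark_cycles == stack.schedule.landmark_cycles
        assert back.optics.pixel_size_um == stack.optics.pixel_size_um
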