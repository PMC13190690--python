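import numpy as np
import pytest

from mdstab import relaxation as rx
from mdstab import synthetic as syn


# ---------------------------------------------------------------------------
# Independent literal-formula oracle (written against the standard 15N
# Redfield expressions before the module; numeric J evaluation only).
# ---------------------------------------------------------------------------

def oracle_J(omega, S2, tau_e_s, tau_c_s):
    tau_eff = 1.0 / (1.0 / tau_e_s + 1.0 / tau_c_s)
    return 0.4 * (
        S2 * tau_c_s / (1 + (omega * tau_c_s) ** 2)
        + (1 - S2) * tau_eff / (1 + (omega * tau_eff) ** 2)
    )


def oracle_backbone(S2, tau_e_ps, tau_c_ns, field_mhz):
    gh, gn = 2.6752218744e8, -2.7126189e7
    r = 1.02e-10
    d = 1e-7 * 1.054571817e-34 * gh * abs(gn) / r**3
    wh = 2 * np.pi * field_mhz * 1e6
    wn = wh * abs(gn) / gh
    c = 170e-6 * wn / np.sqrt(3)
    te, tc = tau_e_ps * 1e-12, tau_c_ns * 1e-9

    def J(w):
        return oracle_J(w, S2, te, tc)

    R1 = d**2 / 4 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn)) + c**2 * J(wn)
    R2 = d**2 / 8 * (4 * J(0) + J(wh - wn) + 3 * J(wn) + 6 * J(wh) + 6 * J(wh + wn)) \
        + c**2 / 6 * (4 * J(0) + 3 * J(wn))
    sigma = d**2 / 4 * (6 * J(wh + wn) - J(wh - wn))
    NOE = 1 + (gh / gn) * sigma / R1
    p2 = (3 * np.cos(np.deg2rad(17.0)) ** 2 - 1) / 2
    eta = d * c / 6 * p2 * (4 * J(0) + 3 * J(wn))
    return {"R1": R1, "R2": R2, "NOE": NOE, "eta_xy": eta}


def oracle_methyl(S2_axis, tau_e_ps, tau_c_ns, field_mhz):
    gh, gc = 2.6752218744e8, 6.728284e7
    r = 1.115e-10
    d = 1e-7 * 1.054571817e-34 * gh * gc / r**3
    wh = 2 * np.pi * field_mhz * 1e6
    wc = wh * gc / gh
    te, tc = tau_e_ps * 1e-12, tau_c_ns * 1e-9
    scale = ((3 * np.cos(np.deg2rad(110.5)) ** 2 - 1) / 2) ** 2

    def J(w):
        return scale * oracle_J(w, S2_axis, te, tc)

    R1 = 3 * d**2 / 4 * (J(wh - wc) + 3 * J(wc) + 6 * J(wh + wc))
    G2 = d**2 / 8 * (4 * J(0) + 3 * J(wc))
    return {"methyl_R1": R1, "methyl_G2": G2}


class TestAcf:
    def test_static_vectors_acf_is_one(self):
        vec = np.tile(np.array([0.0, 0.0, 1.0]), (100, 5, 1))
        acf = rx.vector_acf_p2(vec, 0.1, np.array([0.0, 0.5, 2.0]))
        np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)

    def test_independent_isotropic_vectors_decorrelate(self):
        rng = np.random.default_rng(0)
        n, T = 400, 2000
        vec = rng.standard_normal((T, n, 3))
        vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
        acf = rx.vector_acf_p2(vec, 1.0, np.array([0.0, 1.0, 10.0]))
        mean = acf.values.mean(axis=0)
        assert mean[0] == pytest.approx(1.0, abs=1e-12)
        # var(P2) = 1/5 under uniform sphere sampling
        tol = 3 * np.sqrt(0.2 / (n * (T - 10)))
        assert abs(mean[1]) < tol and abs(mean[2]) < tol

    def test_non_grid_lag_rejected(self):
        vec = np.tile(np.array([0.0, 0.0, 1.0]), (10, 2, 1))
        with pytest.raises(ValueError, match="multiple"):
            rx.vector_acf_p2(vec, 1.0, np.array([0.0, 0.5]))

    def test_nh_extraction_skips_residues_without_amide_h(self):
        vec, _ = syn.gen_modelfree_vectors(0.9, 20.0, np.inf, 10.0, 50, 4, seed=0)
        traj = syn.embed_nh_vectors(vec, dt_ns=0.01)
        # drop one residue's H atom (proline-like)
        import pandas as pd
        from mdstab.io_core import AtomTable, TrajectoryRecord

        keep = ~((traj.atom_table.df["residue_number"] == 461)
                 & (traj.atom_table.df["atom_name"] == "H"))
        traj2 = TrajectoryRecord(
            traj.frame_times, traj.coordinates[:, keep.to_numpy()],
            AtomTable(traj.atom_table.df[keep]),
        )
        vecs, residues = rx.extract_nh_vectors(traj2)
        assert 461 not in residues and len(residues) == 3


class TestModelFreeFit:
    def test_recovers_closed_form_parameters(self):
        t = rx.default_lag_grid(0.001, 10.0)
        y = 0.85 + 0.15 * np.exp(-t / 0.05)  # tau = 50 ps
        fit = rx.fit_acf_multiexp(t, y, 1)
        assert fit.S2 == pytest.approx(0.85, abs=0.01)
        assert fit.components[0][1] == pytest.approx(0.05, rel=0.05)

    def test_constant_one_gives_s2_one(self):
        t = rx.default_lag_grid(0.001, 10.0)
        fit = rx.fit_acf_multiexp(t, np.ones_like(t), 2)
        assert fit.S2 == pytest.approx(1.0, abs=1e-3)

    def test_grid_order_invariance(self):
        t = rx.default_lag_grid(0.001, 10.0)
        y = 0.7 + 0.3 * np.exp(-t / 0.2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(t))
        a = rx.fit_acf_multiexp(t, y, 1)
        b = rx.fit_acf_multiexp(t[perm], y[perm], 1)
        assert a.S2 == pytest.approx(b.S2, abs=1e-6)

    def test_time_rescaling_rescales_tau_exactly(self):
        t = rx.default_lag_grid(0.001, 10.0)
        y = 0.8 + 0.2 * np.exp(-t / 0.1)
        s = 3.0
        a = rx.fit_acf_multiexp(t, y, 1)
        b = rx.fit_acf_multiexp(t * s, y, 1)
        assert b.components[0][1] == pytest.approx(s * a.components[0][1], rel=1e-4)
        assert b.S2 == pytest.approx(a.S2, abs=1e-6)


class TestSpectralDensity:
    def test_j0_rigid_limit_exact(self):
        J = rx.modelfree_spectral_density(1.0, 50.0, 10.0)
        assert J(0.0) == pytest.approx(0.4 * 10e-9, rel=1e-10)

    def test_vanishes_at_high_frequency(self):
        J = rx.modelfree_spectral_density(0.85, 50.0, 10.0)
        assert J(1e15) < 1e-20
        # monotone non-increasing in |omega|
        w = np.logspace(6, 12, 30)
        vals = [J(x) for x in w]
        assert np.all(np.diff(vals) <= 0)

    def test_matches_numeric_cosine_transform(self):
        # J(w) = 2 * integral_0^inf C(t) cos(wt) dt with C = C_O * C_I
        from scipy.integrate import quad

        S2, tau_e, tau_c = 0.8, 100e-12, 8e-9
        J = rx.modelfree_spectral_density(S2, 100.0, 8.0)

        def C(t):
            CI = S2 + (1 - S2) * np.exp(-t / tau_e)
            return 0.4 * CI * np.exp(-t / tau_c)

        for w in (0.0, 5e8, 3e9):
            num = quad(lambda t: C(t) * np.cos(w * t), 0, 2e-6,
                       limit=2000, epsabs=1e-16)[0] * 2 / 2  # one-sided, (2/5) in C
            # numeric transform of 0.4*C equals J up to quadrature error
            assert J(w) == pytest.approx(num, rel=1e-3)

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            rx.SpectralDensity([(0.5, 10.0), (0.2, 0.05)], 10.0)


class TestBackboneRates:
    CONST = rx.NmrConstants(field_mhz=900.0)

    def test_zero_spectral_density_zero_rates(self):
        r = rx.backbone_rates(lambda w: 0.0, self.CONST)
        assert r["R1"] == 0.0 and r["R2"] == 0.0 and r["eta_xy"] == 0.0
        assert r["NOE"] == 1.0

    def test_extreme_narrowing_r1_equals_r2(self):
        # dipolar-only limit: CSA keeps R2/R1 = 7/6 even for w*tau << 1
        J = rx.modelfree_spectral_density(1.0, 50.0, 1e-3)
        const = rx.NmrConstants(field_mhz=900.0, csa_n_ppm=0.0)
        r = rx.backbone_rates(J, const)
        assert r["R1"] / r["R2"] == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("S2,tau_e,tau_c", [
        (1.0, 50.0, 10.0), (0.85, 50.0, 10.0), (0.6, 200.0, 8.0),
    ])
    def test_matches_literal_formula_oracle(self, S2, tau_e, tau_c):
        J = rx.modelfree_spectral_density(S2, tau_e, tau_c)
        got = rx.backbone_rates(J, self.CONST)
        want = oracle_backbone(S2, tau_e, tau_c, 900.0)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-6)

    def test_eta_xy_proportional_to_4j0_plus_3jwn(self):
        J = rx.modelfree_spectral_density(0.85, 50.0, 10.0)
        r1 = rx.backbone_rates(J, self.CONST)
        r2 = rx.backbone_rates(lambda w: 2 * J(w), self.CONST)
        assert r2["eta_xy"] == pytest.approx(2 * r1["eta_xy"], rel=1e-12)

    @pytest.mark.parametrize("tau_c", [1.0, 5.0, 20.0])
    def test_slow_tumbling_r2_exceeds_r1(self, tau_c):
        J = rx.modelfree_spectral_density(0.5, 50.0, tau_c)
        r = rx.backbone_rates(J, self.CONST)
        assert r["R2"] >= r["R1"]


class TestMethylRates:
    CONST = rx.NmrConstants(field_mhz=800.0)

    def test_zero_j_zero_rates(self):
        r = rx.methyl_rates(lambda w: 0.0, self.CONST)
        assert r["methyl_R1"] == 0.0 and r["methyl_G2"] == 0.0

    def test_axis_scaling_factor_near_one_ninth(self):
        scale = rx.p2(np.cos(np.deg2rad(110.5))) ** 2
        assert scale == pytest.approx(0.09988, abs=1e-4)
        assert scale == pytest.approx(1.0 / 9.0, rel=0.15)

    def test_rigid_axis_matches_oracle(self):
        J = rx.modelfree_spectral_density(1.0, 50.0, 10.0)
        got = rx.methyl_rates(J, self.CONST)
        want = oracle_methyl(1.0, 50.0, 10.0, 800.0)
        for k in want:
            assert got[k] == pytest.approx(want[k], rel=1e-6)


class TestBootstrap:
    def make_traj(self, coords):
        n = coords.shape[1]
        from mdstab.io_core import TrajectoryRecord

        return TrajectoryRecord(
            np.arange(float(len(coords))), coords, syn.make_chain_atoms(n)
        )

    def test_static_input_zero_sd(self):
        traj = self.make_traj(np.ones((200, 5, 3)))
        sd = rx.bootstrap_uncertainty(
            traj, lambda t: t.coordinates.mean(axis=(0, 2)), 10.0, 50, seed=0
        )
        np.testing.assert_allclose(sd, 0.0, atol=1e-14)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        traj = self.make_traj(rng.normal(size=(200, 4, 3)))
        est = lambda t: t.coordinates.mean(axis=(0, 2))
        a = rx.bootstrap_uncertainty(traj, est, 10.0, 50, seed=7)
        b = rx.bootstrap_uncertainty(traj, est, 10.0, 50, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_iid_mean_matches_analytic_se(self):
        rng = np.random.default_rng(2)
        n = 2000
        traj = self.make_traj(rng.normal(0, 1, (n, 3, 3)))
        est = lambda t: t.coordinates[:, :, 0].mean(axis=0)
        sd = rx.bootstrap_uncertainty(traj, est, 1.0, 200, seed=3)
        np.testing.assert_allclose(sd, 1 / np.sqrt(n), rtol=0.2)

    def test_too_few_blocks_rejected(self):
        traj = self.make_traj(np.ones((50, 3, 3)))
        with pytest.raises(ValueError, match="blocks"):
            rx.bootstrap_uncertainty(traj, lambda t: np.zeros(1), 10.0, 10, seed=0)


class TestEnsembleRates:
    def test_planted_modelfree_rates_within_10_percent(self):
        vec, _ = syn.gen_modelfree_vectors(0.85, 50.0, np.inf, 5.0, 20_000, 10, seed=11)
        traj = syn.embed_nh_vectors(vec, dt_ns=0.005)
        const = rx.NmrConstants(field_mhz=900.0)
        df = rx.ensemble_rates(traj, const, 10.0, max_lag_ns=20.0)
        true = oracle_backbone(0.85, 50.0, 10.0, 900.0)
        for obs in ("R1", "R2", "NOE", "eta_xy"):
            rel = np.abs(df[obs] - true[obs]) / abs(true[obs])
            assert rel.max() < 0.10

    def test_disjoint_slices_agree(self):
        vec, _ = syn.gen_modelfree_vectors(0.8, 50.0, np.inf, 5.0, 24_000, 6, seed=12)
        traj = syn.embed_nh_vectors(vec, dt_ns=0.005)
        const = rx.NmrConstants(field_mhz=900.0)
        a = rx.ensemble_rates(traj, const, 10.0, time_range_ns=(0.0, 60.0), max_lag_ns=15.0)
        b = rx.ensemble_rates(traj, const, 10.0, time_range_ns=(60.0, 120.0), max_lag_ns=15.0)
        for obs in ("R1", "R2", "eta_xy"):
            rel = np.abs(a[obs] - b[obs]) / a[obs]
            assert np.median(rel) < 0.05
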