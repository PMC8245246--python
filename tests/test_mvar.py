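"""MVAR estimation, BIC order selection, transfer matrix and the
ffDTF / partial-coherence / dDTF chain."""

import numpy as np
import pytest

from gaitnet.mvar import (MVAR, SpectralTransfer, VARProcess, build_network,
                          ddtf, fit_mvar, full_freq_dtf, partial_coherence,
                          select_order_bic, stabilize, transfer_matrix,
                          UnstableModelError)
from gaitnet.simulate import make_mvar_system, simulate_recording


def minors_oracle(s: np.ndarray) -> np.ndarray:
    """Literal partial coherence from minor determinants of one S matrix."""
    n = s.shape[0]
    m = np.empty((n, n), dtype=complex)
    for i in range(n):
        for j in range(n):
            m[i, j] = np.linalg.det(np.delete(np.delete(s, i, axis=0), j, axis=1))
    c = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = abs(m[i, j]) / np.sqrt(abs(m[i, i]) * abs(m[j, j]))
    return np.clip(c, 0, 1)


class TestFit:
    def test_recovers_known_coefficients(self):
        proc = make_mvar_system(3, 2, [(0, 1, 0.5), (2, 0, 0.4)], seed=2)
        rec = simulate_recording(proc, 10_000, seed=3)
        est = fit_mvar(rec.data, order=2)
        rmse = np.sqrt(np.mean((est.coeffs - proc.coeffs) ** 2))
        assert rmse < 0.05

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(4)
        est = fit_mvar(rng.standard_normal((3, 10_000)), order=2)
        assert np.abs(est.coeffs).max() < 0.05

    def test_pooling_never_straddles_trial_boundary(self):
        """Two half-trials must equal a pooled normal-equations fit that
        drops the straddling rows of the full series."""
        rng = np.random.default_rng(5)
        proc = make_mvar_system(2, 2, [(0, 1, 0.4)], seed=6)
        x = simulate_recording(proc, 2000, seed=7).data
        half = x.shape[1] // 2
        split_fit = fit_mvar([x[:, :half], x[:, half:]], order=2)
        # oracle: regression rows built from the full series, excluding rows
        # whose lags cross the cut
        p = 2
        ys, zs = [], []
        for t in range(p, x.shape[1]):
            if half <= t < half + p:
                continue
            ys.append(x[:, t])
            zs.append(np.concatenate([x[:, t - k] for k in range(1, p + 1)]))
        y, z = np.array(ys).T, np.array(zs).T
        b = np.linalg.lstsq(z.T, y.T, rcond=None)[0].T
        oracle = b.reshape(2, p, 2).transpose(1, 0, 2)
        np.testing.assert_allclose(split_fit.coeffs, oracle, atol=1e-10)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fit_mvar(np.zeros((4, 10)), order=5)


class TestOrderSelection:
    def test_pmax_one_returns_one(self):
        rng = np.random.default_rng(1)
        sel = select_order_bic(rng.standard_normal((2, 500)), p_max=1)
        assert sel.selected == 1

    def test_white_noise_selects_minimal_structure(self):
        rng = np.random.default_rng(2)
        sel = select_order_bic(rng.standard_normal((3, 5000)), p_max=8)
        est = fit_mvar(rng.standard_normal((3, 5000)), order=sel.selected)
        assert np.abs(est.coeffs).max() < 0.05

    def test_true_order_recovered_mostly(self):
        hits = 0
        for seed in range(10):
            proc = make_mvar_system(3, 4, [(0, 1, 0.4), (1, 2, 0.4)], seed=seed)
            rec = simulate_recording(proc, 5000, seed=1000 + seed)
            if select_order_bic(rec.data, p_max=8).selected == 4:
                hits += 1
        assert hits >= 9


class TestTransfer:
    def test_zero_coefficients_identity(self):
        proc = VARProcess(np.zeros((1, 3, 3)), np.eye(3))
        tr = transfer_matrix(proc, np.array([5.0, 10.0]), rate_hz=100.0)
        for fi in range(2):
            np.testing.assert_allclose(tr.A_f[fi], np.eye(3), atol=1e-12)
            np.testing.assert_allclose(tr.H_f[fi], np.eye(3), atol=1e-12)

    def test_scalar_ar1_closed_form(self):
        a = 0.5
        proc = VARProcess(np.array([[[a]]]), np.eye(1))
        freqs = np.linspace(1, 40, 25)
        tr = transfer_matrix(proc, freqs, rate_hz=100.0)
        expected = 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * freqs / 100.0)) ** 2
        np.testing.assert_allclose(np.abs(tr.H_f[:, 0, 0]) ** 2, expected,
                                   atol=1e-10)

    def test_spectral_matrix_hermitian_psd_diag(self):
        proc = make_mvar_system(4, 3, [(0, 2, 0.4), (3, 1, 0.3)], seed=8)
        tr = transfer_matrix(proc)
        for s in tr.S_f:
            np.testing.assert_allclose(s, s.conj().T, atol=1e-8)
            assert (np.real(np.diag(s)) >= 0).all()

    def test_unstable_model_refused(self):
        proc = VARProcess(np.array([[[1.05]]]), np.eye(1))
        with pytest.raises(UnstableModelError):
            transfer_matrix(proc)

    def test_stabilize_shrinks_exactly(self):
        proc = VARProcess(np.array([[[1.1]]]), np.eye(1))
        out = stabilize(proc, target_radius=0.99)
        assert out.spectral_radius == pytest.approx(0.99)


class TestFfdtf:
    def test_identity_transfer_hand_computed(self):
        f = 9
        freqs = np.arange(1.0, 10.0)
        eye = np.tile(np.eye(2)[None], (f, 1, 1)).astype(complex)
        tr = SpectralTransfer(freqs, eye, eye, eye)
        out = full_freq_dtf(tr)
        np.testing.assert_allclose(out[:, 0, 0], 1.0 / f)
        np.testing.assert_allclose(out[:, 0, 1], 0.0)

    def test_row_normalization_on_random_models(self):
        for seed in range(5):
            proc = make_mvar_system(4, 2, [(0, 1, 0.4), (2, 3, 0.5)], seed=seed)
            out = full_freq_dtf(transfer_matrix(proc))
            np.testing.assert_allclose(out.sum(axis=(0, 2)), 1.0, atol=1e-6)
            assert (out >= 0).all() and (out <= 1).all()

    def test_unidirectional_coupling_dominates(self):
        proc = make_mvar_system(2, 2, [(0, 1, 0.5)], seed=3)
        rec = simulate_recording(proc, 10_000, seed=4)
        est = fit_mvar(rec.data, order=2)
        out = full_freq_dtf(transfer_matrix(est))
        forward = out[:, 1, 0].sum()
        reverse = out[:, 0, 1].sum()
        assert forward / reverse >= 5


class TestPartialCoherence:
    def test_diagonal_spectrum_gives_zero_offdiag(self):
        freqs = np.arange(1.0, 6.0)
        s = np.tile(np.diag([1.0, 2.0, 3.0])[None], (5, 1, 1)).astype(complex)
        eye = np.tile(np.eye(3)[None], (5, 1, 1)).astype(complex)
        tr = SpectralTransfer(freqs, eye, eye, s)
        c = partial_coherence(tr)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(c[:, off]).max() < 1e-8

    def test_two_channel_scalar_minors(self):
        s = np.array([[[1.0, 0.6], [0.6, 1.0]]], dtype=complex)
        eye = np.eye(2)[None].astype(complex)
        tr = SpectralTransfer(np.array([10.0]), eye, eye, s)
        c = partial_coherence(tr)
        assert c[0, 0, 1] == pytest.approx(0.6, abs=1e-10)

    def test_matches_minor_determinant_oracle(self):
        for seed in range(5):
            proc = make_mvar_system(4, 2, [(0, 1, 0.5), (1, 2, 0.4)], seed=seed)
            tr = transfer_matrix(proc)
            c = partial_coherence(tr)
            for fi in (0, 10, 30):
                np.testing.assert_allclose(c[fi], minors_oracle(tr.S_f[fi]),
                                           atol=1e-8)

    def test_chain_suppresses_mediated_link(self):
        proc = make_mvar_system(3, 2, [(0, 1, 0.5), (1, 2, 0.5)], seed=1)
        rec = simulate_recording(proc, 10_000, seed=2)
        est = fit_mvar(rec.data, order=2)
        tr = transfer_matrix(est)
        c = partial_coherence(tr)
        band = (tr.freqs >= 8) & (tr.freqs <= 30)
        c13 = c[band, 2, 0].mean()
        assert c13 < c[band, 1, 0].mean()
        assert c13 < c[band, 2, 1].mean()


class TestDdtfAndNetwork:
    def test_ddtf_identity_and_annihilator(self):
        f2 = np.random.default_rng(0).random((5, 3, 3))
        ones = np.ones_like(f2)
        np.testing.assert_array_equal(ddtf(f2, ones), f2)
        np.testing.assert_array_equal(ddtf(f2, np.zeros_like(f2)), 0 * f2)

    def test_ddtf_never_exceeds_ffdtf(self):
        proc = make_mvar_system(4, 2, [(0, 1, 0.5), (2, 3, 0.4)], seed=12)
        tr = transfer_matrix(proc)
        f2 = full_freq_dtf(tr)
        chi = ddtf(f2, partial_coherence(tr))
        assert (chi <= f2 + 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ddtf(np.zeros((2, 3, 3)), np.zeros((2, 4, 4)))

    def test_threshold_extremes(self):
        freqs = np.arange(1.0, 46.0)
        chi = np.random.default_rng(1).random((45, 4, 4)) * 0.01
        w0, adj0, _ = build_network(chi, freqs, threshold=0.0)
        off = ~np.eye(4, dtype=bool)
        assert (adj0[off] == (w0[off] > 0) | (w0[off] >= 0)).all()
        _, adj1, _ = build_network(chi, freqs, threshold=1.01)
        assert adj1.sum() == 0

    def test_raw_band_mean_without_normalization(self):
        freqs = np.arange(1.0, 46.0)
        chi = np.full((45, 2, 2), 0.004)
        w, _, w_raw = build_network(chi, freqs, band=(8, 30), normalize="none")
        np.testing.assert_allclose(w, 0.004)
        np.testing.assert_allclose(w, w_raw)

    def test_planted_edges_recovered(self):
        edges = [(0, 3, 0.5), (1, 4, 0.5), (5, 2, 0.5), (6, 7, 0.5)]
        proc = make_mvar_system(8, 3, edges, seed=21)
        rec = simulate_recording(proc, 10_000, seed=22)
        res = MVAR(rec.data, order=3, rate=1000.0).fit()
        conn = res.connectivity(band=(8, 30), threshold=0.2)
        true = {(snk, src) for src, snk, _ in edges}
        found = {tuple(ij) for ij in np.argwhere(conn.adjacency == 1)}
        assert len(true & found) >= 3
        assert len(found - true) <= 2


class TestModelResults:
    def test_fit_selects_order_when_unset(self):
        proc = make_mvar_system(3, 2, [(0, 1, 0.5)], seed=2)
        rec = simulate_recording(proc, 4000, seed=3)
        res = MVAR(rec.data, rate=1000.0).fit(p_max=6)
        assert res.order_selection is not None
        assert res.order == res.order_selection.selected

    def test_summary_mentions_key_quantities(self):
        proc = make_mvar_system(2, 1, [], seed=1)
        rec = simulate_recording(proc, 2000, seed=1)
        res = MVAR(rec.data, order=1, rate=1000.0).fit()
        s = res.summary()
        assert "order (p)" in s and "BIC" in s and "stable" in s

    def test_agrees_with_statsmodels_var_single_trial(self):
        from statsmodels.tsa.api import VAR as SmVAR

        proc = make_mvar_system(3, 2, [(0, 1, 0.5)], seed=9)
        x = simulate_recording(proc, 5000, seed=10).data
        ours = fit_mvar(x, order=2)
        sm = SmVAR(x.T).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(
            ours.coeffs, sm.coefs, atol=1e-6
        )
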