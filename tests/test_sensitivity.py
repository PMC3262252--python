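"""Sensitivity operator, its SVD structure and phase sensitivities."""

import numpy as np
import pytest

import clockbalance as cb
from clockbalance.model import model_from_dict
from clockbalance.sensitivity import gram_matrix, hilbert_norm, trapezoid_weights


# -- analytic oracle: one-state linear forced system ------------------------
#
# dx/dt = -k1 x + k2 theta(t) with square light on [t_l, t_d].  The periodic
# solution and its parameter sensitivities are sums of exponentials on each
# segment, solvable in closed form from the periodic boundary condition.

def _linear_closed_form(k1, k2, t_l=6.0, t_d=18.0, tau=24.0):
    D, N = t_d - t_l, tau - (t_d - t_l)
    Ed, En = np.exp(-k1 * D), np.exp(-k1 * N)
    A = k2 / k1
    x_l = A * (1 - Ed) * En / (1 - Ed * En)  # state at dawn

    def x(t):
        tm = (t - t_l) % tau
        if tm < D:
            return A + (x_l - A) * np.exp(-k1 * tm)
        x_d = A + (x_l - A) * Ed
        return x_d * np.exp(-k1 * (tm - D))

    # S2 = dx/dk2 = x / k2 (solution is linear in k2)
    def S2(t):
        return x(t) / k2

    # S1 = dx/dk1 solves z' = -k1 z - x(t); on each segment the forcing is
    # const + resonant exponential, so z has an extra  -B s e^{-k1 s} term.
    B = x_l - A
    x_d_end = A + B * Ed
    # unknown z at dawn from periodicity: z(t_l + tau) = z(t_l)
    # day:   z(t_d) = (z_l + A/k1) Ed - A/k1 - B D Ed
    # night: z(t_l+tau) = z(t_d) En - x_d_end N En
    En_Ed = Ed * En
    rhs = ((A / k1) * Ed - A / k1 - B * D * Ed) * En - x_d_end * N * En
    z_l = rhs / (1 - En_Ed)

    def S1(t):
        tm = (t - t_l) % tau
        if tm < D:
            return (z_l + A / k1) * np.exp(-k1 * tm) - A / k1 - B * tm * np.exp(-k1 * tm)
        z_d = (z_l + A / k1) * Ed - A / k1 - B * D * Ed
        u = tm - D
        return z_d * np.exp(-k1 * u) - x_d_end * u * np.exp(-k1 * u)

    return x, S1, S2


@pytest.fixture(scope="module")
def linear_model_orbit():
    model = model_from_dict(
        {
            "states": ["x1"],
            "parameters": {"k1": 0.35, "k2": 0.6},
            "equations": ["-k1*x1 + k2*theta"],
            "light_params": ["k2"],
        }
    )
    orbit = cb.find_entrained_orbit(model)
    return model, orbit


@pytest.mark.parametrize("method", ["variational", "finite_difference"])
def test_linear_system_matches_closed_form(linear_model_orbit, method):
    model, orbit = linear_model_orbit
    sens = cb.compute_sensitivities(orbit, method=method)
    x_exact, S1, S2 = _linear_closed_form(0.35, 0.6)
    ts = orbit.ts
    assert np.allclose(orbit.values[0], [x_exact(t) for t in ts], atol=1e-8)
    assert np.allclose(sens.S[0, 0], [S1(t) for t in ts], atol=1e-6)
    assert np.allclose(sens.S[0, 1], [S2(t) for t in ts], atol=1e-6)


def test_unused_parameter_has_zero_sensitivity():
    model = model_from_dict(
        {
            "states": ["x1"],
            "parameters": {"a": 1.0, "m": 0.5, "unused": 2.0},
            "equations": ["a - m*x1"],
        }
    )
    orbit = cb.find_entrained_orbit(model)
    sens = cb.compute_sensitivities(orbit)
    j = model.param_index("unused")
    assert np.max(np.abs(sens.S[:, j, :])) < 1e-12


def test_variational_vs_finite_difference(demo_sens, demo_sens_fd):
    # cross-method agreement on every parameter column, relative H-norm
    ts = demo_sens.ts
    for j in range(demo_sens.S.shape[1]):
        diff = hilbert_norm(demo_sens.S[:, j, :] - demo_sens_fd.S[:, j, :], ts)
        scale = hilbert_norm(demo_sens.S[:, j, :], ts)
        assert diff < 0.01 * scale


def test_sensitivity_periodicity(demo_sens):
    assert np.max(np.abs(demo_sens.S[..., 0] - demo_sens.S[..., -1])) < 1e-6


class TestGramMatrix:
    def test_constant_single_column(self, demo_orbit):
        sens = cb.SensitivityMatrix(
            orbit=demo_orbit,
            ts=np.linspace(0, 24, 241),
            S=np.ones((1, 1, 241)),
            method="synthetic",
        )
        G = gram_matrix(sens)
        assert G.shape == (1, 1)
        assert G[0, 0] == pytest.approx(24.0)

    def test_duplicate_columns_rank_deficient(self, demo_sens):
        S2 = np.concatenate([demo_sens.S, demo_sens.S[:, :1, :]], axis=1)
        sens = cb.SensitivityMatrix(
            orbit=demo_sens.orbit, ts=demo_sens.ts, S=S2, method="synthetic"
        )
        evals = np.linalg.eigvalsh(gram_matrix(sens))
        assert abs(evals[0]) < 1e-8 * evals[-1]

    def test_quadrature_refinement(self, demo_model, demo_sens):
        fine_orbit = cb.find_entrained_orbit(demo_model, n_grid=4800)
        fine = cb.compute_sensitivities(fine_orbit)
        G1 = gram_matrix(demo_sens)
        G2 = gram_matrix(fine)
        assert np.max(np.abs(G1 - G2)) < 1e-6 * np.max(np.abs(G2))


class TestDecomposition:
    def test_sigma_descending_nonnegative(self, pc_abs):
        assert np.all(np.diff(pc_abs.sigma) <= 0)
        assert np.all(pc_abs.sigma >= 0)

    def test_trace_identity(self, pc_abs):
        assert np.sum(pc_abs.sigma**2) == pytest.approx(
            np.trace(pc_abs.G), rel=1e-10
        )

    def test_gram_symmetric_psd(self, pc_abs):
        assert np.allclose(pc_abs.G, pc_abs.G.T)
        assert np.min(np.linalg.eigvalsh(pc_abs.G)) > -1e-8 * np.max(pc_abs.G)

    def test_MV_equals_sigma_U_and_orthonormality(self, demo_sens, pc_abs):
        w = trapezoid_weights(pc_abs.ts)
        for i in range(pc_abs.n_components):
            MVi = np.einsum("mjt,j->mt", demo_sens.S, pc_abs.V[:, i])
            assert np.max(np.abs(MVi - pc_abs.sigma[i] * pc_abs.U[i])) < 1e-8 * max(
                pc_abs.sigma[0], 1.0
            )
        # <U_i, U_j> = delta_ij in the quadrature inner product
        gram_U = np.einsum("imt,jmt,t->ij", pc_abs.U, pc_abs.U, w)
        assert np.max(np.abs(gram_U - np.eye(pc_abs.n_components))) < 1e-8

    def test_sigma_decay_spans_decade(self, pc_abs):
        assert pc_abs.sigma[0] / pc_abs.sigma[-1] >= 10.0

    def test_eckart_young_truncation(self, demo_sens, pc_abs):
        # H-norm error of the rank-r reconstruction equals the sigma tail,
        # and decreases monotonically with r
        ts = pc_abs.ts
        w = trapezoid_weights(ts)
        errors = []
        for r in range(pc_abs.n_components + 1):
            recon = np.einsum(
                "i,imt,ji->mjt", pc_abs.sigma[:r], pc_abs.U[:r], pc_abs.V[:, :r]
            )
            diff = demo_sens.S - recon
            err = np.sqrt(np.einsum("mjt,mjt,t->", diff, diff, w))
            errors.append(err)
            tail = np.sqrt(np.sum(pc_abs.sigma[r:] ** 2))
            assert err == pytest.approx(tail, rel=1e-6, abs=1e-8)
        assert np.all(np.diff(errors) < 1e-12)

    def test_relative_mode_convention(self, pc_abs, pc_rel):
        assert np.allclose(pc_rel.sigma, pc_abs.sigma)
        assert np.allclose(pc_rel.U, pc_abs.U)
        assert np.allclose(pc_rel.W, pc_abs.W * pc_rel.k[None, :])
        assert np.allclose(pc_rel.V, pc_abs.V * pc_rel.k[:, None])

    def test_isotropic_case_equal_sigmas(self, demo_orbit):
        # orthogonal equal-norm synthetic columns: all sigma equal, V a
        # permutation of the identity
        ts = np.linspace(0, 24, 2401)
        S = np.zeros((3, 3, len(ts)))
        for j in range(3):
            S[j, j, :] = np.sqrt(2.0) * np.sin(2 * np.pi * (j + 1) * ts / 24.0)
        sens = cb.SensitivityMatrix(orbit=demo_orbit, ts=ts, S=S, method="synthetic")
        pc = cb.principal_components(sens)
        assert np.allclose(pc.sigma, pc.sigma[0], rtol=1e-6)
        perm = np.abs(pc.V)
        assert np.allclose(perm @ perm.T, np.eye(3), atol=1e-6)


class TestPredictedResponse:
    def test_zero_perturbation(self, pc_abs):
        assert np.max(np.abs(cb.predicted_response(pc_abs, np.zeros(len(pc_abs.k))))) == 0

    def test_eigendirection(self, pc_abs):
        h = 1e-3
        dg = cb.predicted_response(pc_abs, h * pc_abs.V[:, 0])
        assert np.allclose(dg, pc_abs.sigma[0] * h * pc_abs.U[0], atol=1e-12)

    def test_matches_reintegration(self, demo_model, demo_orbit, pc_abs):
        rng = np.random.default_rng(42)
        dk = rng.standard_normal(len(pc_abs.k))
        dk *= 1e-3 * np.linalg.norm(demo_orbit.k) / np.linalg.norm(dk)
        pred = cb.predicted_response(pc_abs, dk)
        pert = cb.find_entrained_orbit(
            demo_model, k=demo_orbit.k + dk, x0=demo_orbit.x0, tol=1e-12
        )
        actual = pert.values - demo_orbit.values
        rel = hilbert_norm(pred - actual, pc_abs.ts) / hilbert_norm(actual, pc_abs.ts)
        assert rel < 0.02


class TestPhaseSensitivity:
    def test_routes_agree(self, demo_orbit, demo_sens, pc_abs):
        direct = cb.phase_sensitivity(demo_orbit, demo_sens)
        via_pc = cb.phase_sensitivity(demo_orbit, demo_sens, pc=pc_abs, route="pc")
        scale = np.nanmax(np.abs(direct.dphi))
        assert np.nanmax(np.abs(direct.dphi - via_pc.dphi)) < 1e-6 * scale

    def test_matches_finite_difference_peak_shifts(self, demo_model, demo_orbit, demo_sens):
        ps = cb.phase_sensitivity(demo_orbit, demo_sens)
        h = 1e-4
        tau = demo_orbit.period
        for j, name in enumerate(demo_model.param_names):
            k = demo_orbit.k.copy()
            delta = h * k[j]
            k[j] += delta
            pert = cb.find_entrained_orbit(demo_model, k=k, x0=demo_orbit.x0, tol=1e-11)
            phases = cb.peak_phases(pert)
            for m, comp in enumerate(phases.components):
                shift = (comp.peak_time - ps.phases[m] + tau / 2) % tau - tau / 2
                fd = shift / delta
                formula = ps.dphi[m, j]
                if max(abs(fd), abs(formula)) < 1e-6:
                    continue  # both zero (pinned corner peak)
                assert abs(formula - fd) <= 0.02 * max(abs(formula), abs(fd)), (
                    f"state {m}, parameter {name}: {formula} vs {fd}"
                )

    def test_pinned_corner_peak_has_zero_row(self, demo_orbit, demo_sens):
        ps = cb.phase_sensitivity(demo_orbit, demo_sens)
        # x3 peaks exactly at dusk where the light switch pins the maximum
        assert ps.pinned[2]
        assert ps.phases[2] == pytest.approx(18.0)
        assert np.all(ps.dphi[2] == 0.0)

    def test_relative_mode_scales_columns(self, demo_orbit, demo_sens):
        abs_ps = cb.phase_sensitivity(demo_orbit, demo_sens)
        rel_ps = cb.phase_sensitivity(demo_orbit, demo_sens, mode="relative")
        assert np.allclose(
            rel_ps.dphi, abs_ps.dphi * np.asarray(demo_orbit.k)[None, :], equal_nan=True
        )


class TestPowerSpectrum:
    def test_dominant_parameter_ranks_first(self, pc_rel):
        df = cb.power_spectrum(pc_rel, top_i=4)
        best = df.iloc[0]
        mat = np.abs(pc_rel.sigma[:4, None] * pc_rel.W[:4, :])
        assert best["max_sigma_w"] == pytest.approx(mat.max())
        assert best["parameter"] == pc_rel.param_names[int(np.argmax(mat.max(axis=0)))]

    def test_threshold_filter_matches_bruteforce(self, pc_rel):
        full = cb.power_spectrum(pc_rel, top_i=4)
        kept = cb.power_spectrum(pc_rel, top_i=4, threshold=0.3)
        expected = full[full["max_sigma_w"] >= 0.3 * full["max_sigma_w"].max()]
        assert list(kept["parameter"]) == list(expected["parameter"])

    def test_ranking_invariant_to_uniform_state_rescaling(self, demo_sens, pc_rel):
        # a common unit change of all states scales every sigma_i W_ij by the
        # same factor and leaves the ranking unchanged (per-state rescaling
        # changes the inner product and is NOT an invariance; use
        # state_weights to express a deliberate weighting instead)
        sens2 = cb.SensitivityMatrix(
            orbit=demo_sens.orbit, ts=demo_sens.ts, S=1e3 * demo_sens.S, method="synthetic"
        )
        pc2 = cb.principal_components(sens2, mode="relative")
        r1 = cb.power_spectrum(pc_rel, top_i=4)
        r2 = cb.power_spectrum(pc2, top_i=4)
        assert list(r1["parameter"]) == list(r2["parameter"])
        assert np.allclose(r2["max_sigma_w"], 1e3 * r1["max_sigma_w"])

    def test_state_weights_equivalent_to_rescaled_sensitivities(self, demo_sens):
        weights = np.array([1.0, 4.0, 0.25])
        G_weighted = gram_matrix(demo_sens, state_weights=weights)
        sens2 = cb.SensitivityMatrix(
            orbit=demo_sens.orbit,
            ts=demo_sens.ts,
            S=np.sqrt(weights)[:, None, None] * demo_sens.S,
            method="synthetic",
        )
        assert np.allclose(G_weighted, gram_matrix(sens2))
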