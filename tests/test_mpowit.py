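import numpy as np
import pytest

from grouppca import (
    generate_group,
    make_provider,
    mpowit,
    orth_evd,
    power_iteration,
    stp,
)
from grouppca._linalg import max_principal_angle


class TestOrthEvd:
    def test_matches_qr_span_random(self, rng):
        m = rng.normal(size=(500, 40))
        Q = orth_evd(m)
        assert np.allclose(Q.T @ Q, np.eye(40), atol=1e-10)
        Qr, _ = np.linalg.qr(m)
        assert max_principal_angle(Q, Qr) < 1e-10

    def test_single_column_normalized(self, rng):
        m = rng.normal(size=(30, 1)) * 7.5
        Q = orth_evd(m)
        assert np.isclose(np.linalg.norm(Q), 1.0, atol=1e-12)
        assert max_principal_angle(Q, m) < 1e-12

    def test_orthonormal_input_spans_same_space(self, rng):
        Q0, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        Q = orth_evd(Q0)
        assert np.allclose(Q.T @ Q, np.eye(8), atol=1e-10)
        assert max_principal_angle(Q, Q0) < 1e-10

    def test_dependent_columns_dropped_with_warning(self, rng):
        m = rng.normal(size=(50, 3))
        m = np.hstack([m, m[:, :1]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            Q = orth_evd(m)
        assert Q.shape[1] == 3


class TestPowerIteration:
    def test_diagonal_dominant_pair(self):
        C = np.diag([4.0, 1.0])
        x, lam = power_iteration(lambda v: C @ v, 2, seed=0)
        assert np.isclose(lam, 4.0, atol=1e-8)
        assert abs(abs(x[0]) - 1.0) < 1e-6

    def test_identity_fixed_point(self):
        x, lam = power_iteration(lambda v: v, 5, seed=1)
        assert np.isclose(lam, 1.0, atol=1e-12)

    def test_random_psd_matches_dense_evd(self, rng):
        A = rng.normal(size=(30, 30))
        C = A @ A.T + np.diag(np.linspace(30, 1, 30))
        x, lam = power_iteration(lambda v: C @ v, 30, tol=1e-10, seed=2)
        w, V = np.linalg.eigh(C)
        assert np.isclose(lam, w[-1], atol=1e-8)
        assert min(np.linalg.norm(x - V[:, -1]), np.linalg.norm(x + V[:, -1])) < 1e-6

    def test_nonconvergence_carries_last_iterate(self):
        C = np.eye(3)
        C[0, 0] = 1.0 + 1e-12  # vanishing gap
        with pytest.raises(RuntimeError) as info:
            power_iteration(lambda v: C @ v, 3, tol=1e-15, max_iter=5, seed=3)
        assert hasattr(info.value, "last_iterate")


class TestMpowit:
    def test_matches_dense_oracle(self, small_bundle, small_oracle):
        U, lam = small_oracle
        res = mpowit(small_bundle.provider, k=10, l=5, seed=0)
        res.validate()
        assert np.linalg.norm(res.eigenvalues - lam[:10]) < 1e-6
        assert max_principal_angle(res.basis, U[:, :10]) < 1e-6

    def test_exact_rank_k_noiseless_with_l1(self):
        subjects, truth = generate_group(v=400, t=20, M=4, r=5,
                                         spectrum=np.array([10.0, 8, 6, 4, 2]))
        prov = make_provider([s.values for s in subjects])
        res = mpowit(prov, k=5, l=1, seed=0)
        assert np.allclose(res.eigenvalues, truth.group_spectrum, atol=1e-10)

    def test_enlarged_subspace_accelerates(self, small_bundle):
        prov = small_bundle.provider
        for k in (10, 25):
            it_l5 = mpowit(prov, k=k, l=5, seed=4, compute_backproj=False).extra["iterations"]
            it_l1 = mpowit(prov, k=k, l=1, seed=4, compute_backproj=False).extra["iterations"]
            assert it_l5 <= it_l1

    def test_warm_start_from_stp_converges_fast(self, small_bundle):
        P = small_bundle.params
        warm = stp(small_bundle.provider, k=P["k_intermediate"],
                   k_intermediate=P["k_intermediate"], g=P["g"])
        res = mpowit(small_bundle.provider, k=10, l=5, init=warm)
        assert res.trace.converged
        assert res.extra["iterations"] <= 3

    def test_rayleigh_ritz_bound_every_iteration(self, small_bundle, small_oracle):
        _, lam = small_oracle
        res = mpowit(small_bundle.provider, k=10, l=5, seed=5)
        for est in res.trace.history[1:]:  # skip the Lambda_0 = 0 reference
            assert np.all(est <= lam[: est.size] + 1e-8)

    def test_stacked_equals_unstacked_with_shared_seed(self, small_bundle):
        prov_u = make_provider(
            [rs.scores for rs in small_bundle.reduced], mode="unstacked"
        )
        r_s = mpowit(small_bundle.provider, k=10, l=5, seed=6)
        r_u = mpowit(prov_u, k=10, l=5, seed=6)
        assert np.allclose(r_s.eigenvalues, r_u.eigenvalues, atol=1e-10)
        assert np.allclose(r_s.basis, r_u.basis, atol=1e-10)
        assert np.allclose(r_s.backproj, r_u.backproj, atol=1e-10)

    def test_dataloads_m_per_iteration(self, small_bundle):
        prov = make_provider(
            [rs.scores for rs in small_bundle.reduced], mode="unstacked"
        )
        res = mpowit(prov, k=10, l=5, seed=7, compute_backproj=False)
        M, j = prov.M, res.extra["iterations"]
        assert res.trace.extra["dataloads"]["iterations"] == j * M
        assert res.extra["dataloads"] == (j + 1) * M

    def test_orth_choice_immaterial_to_fixed_point(self, small_bundle, small_oracle):
        # QR-orthonormalized subspace iteration reaches the same eigenvalues
        _, lam = small_oracle
        prov = small_bundle.provider
        rng = np.random.default_rng(8)
        X = rng.standard_normal((prov.v, 50))
        chi = prov.apply_cov(X)
        for _ in range(30):
            X, _ = np.linalg.qr(chi)
            chi = prov.apply_cov(X)
        w = np.linalg.eigvalsh(X.T @ chi / (prov.v - 1))[::-1][:10]
        res = mpowit(prov, k=10, l=5, seed=8, compute_backproj=False)
        assert np.allclose(res.eigenvalues, w, atol=1e-8)

    def test_subspace_cap_enforced(self, small_bundle):
        with pytest.raises(ValueError, match="allow_large_subspace"):
            mpowit(small_bundle.provider, k=110, l=5)

    def test_trace_contract(self, small_bundle):
        res = mpowit(small_bundle.provider, k=10, l=5, seed=9, compute_backproj=False)
        tr = res.trace
        assert len(tr.history) == len(tr.diff_norms) + 1
        assert tr.iterations >= 2  # Lambda_0 = 0 forbids stopping at j=1
        assert tr.converged
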