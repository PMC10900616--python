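"""Forward/backward recursion contracts: emissions, initialisation,
decomposition, slicing, worker independence, table mechanics."""

import numpy as np
import pytest

import lspaint as lp


def _uniform_instance(N, L, mu=0.1, rho_val=0.05, seed=0):
    haps = lp.random_panel(N, L, seed=seed)
    cache = lp.cache_haplotypes(haps)
    rho = np.full(L, rho_val)
    rho[-1] = 1.0
    pars = lp.make_parameters(rho, mu, num_haps=N)
    return cache, pars


class TestEmission:
    def test_symmetric_kernel_match_and_mismatch(self):
        cache = lp.cache_haplotypes([[0, 0, 1]])
        theta = lp.emission_vector(cache, 0, 0, 0.1)
        assert theta[1] == pytest.approx(0.9)  # h matches
        assert theta[2] == pytest.approx(0.1)  # h mismatches

    def test_mu_half_collapses_alleles(self):
        cache = lp.cache_haplotypes([[0, 1, 0, 1]])
        theta = lp.emission_vector(cache, 0, 2, 0.5)
        assert np.allclose(theta, 0.5)

    def test_derived_allele_kernel_asymmetry(self):
        # donors: ancestral(0), derived(1); recipients both orientations
        cache = lp.cache_haplotypes([[0, 1, 0, 1]])
        mu = 0.2
        anc = lp.emission_vector(cache, 0, 2, mu, use_speidel=True)
        der = lp.emission_vector(cache, 0, 3, mu, use_speidel=True)
        # ancestral recipient: derived donors are not penalised
        assert anc[0] == pytest.approx(1 - mu)
        assert anc[1] == pytest.approx(1.0)
        # derived recipient: ancestral donors pay the mis-copy probability
        assert der[0] == pytest.approx(mu)
        assert der[1] == pytest.approx(1 - mu)


class TestForward:
    def test_init_two_haplotypes_single_donor(self):
        cache = lp.cache_haplotypes([[0, 0], [1, 0]])
        pars = lp.make_parameters(np.array([0.1, 1.0]), 0.2, num_haps=2)
        fwd = lp.initialise_forward(lp.make_forward_table(2), pars, cache)
        # recipient 0's only donor is 1 (match at variant 0): alpha = 1-mu
        assert fwd.alpha[1, 0] == pytest.approx(0.8)
        assert fwd.alpha[0, 0] == 0.0
        assert fwd.alpha_f[0] == pytest.approx(0.8)

    def test_init_three_haplotypes_hand_value(self):
        # recipient 2 carries allele 1, donors carry 0: theta=(0.1,0.1)*Pi=(.5,.5)
        cache = lp.cache_haplotypes([[0, 0, 1]])
        pars = lp.make_parameters(np.array([1.0]), 0.1, num_haps=3)
        fwd = lp.initialise_forward(lp.make_forward_table(3), pars, cache)
        assert np.allclose(fwd.alpha[:, 2], [0.05, 0.05, 0.0])

    def test_diagonal_identically_zero(self, small_instance):
        cache, pars = small_instance
        fwd = lp.forward(lp.make_forward_table(pars.num_haps), pars, cache,
                         pars.num_variants - 1)
        assert (np.diagonal(fwd.alpha) == 0).all()

    def test_off_diagonal_positive_with_uniform_pi(self):
        cache, pars = _uniform_instance(7, 15, seed=5)
        fwd = lp.initialise_forward(lp.make_forward_table(7), pars, cache)
        off = fwd.alpha[~np.eye(7, dtype=bool).reshape(7, 7)]
        assert (off > 0).all()

    def test_zero_step_is_identity(self, small_instance):
        cache, pars = small_instance
        fwd = lp.forward(lp.make_forward_table(pars.num_haps), pars, cache, 4)
        snap = fwd.alpha.copy()
        lp.forward(fwd, pars, cache, 4)
        assert np.array_equal(fwd.alpha, snap)

    def test_multi_step_equals_single_steps_bit_exact(self, small_instance):
        cache, pars = small_instance
        L, N = pars.num_variants, pars.num_haps
        one = lp.forward(lp.make_forward_table(N), pars, cache, L - 1)
        many = lp.make_forward_table(N)
        for ell in range(L):
            lp.forward(many, pars, cache, ell)
        assert np.array_equal(one.alpha, many.alpha)
        assert np.array_equal(one.alpha_f, many.alpha_f)

    def test_no_switching_closed_form(self):
        # rho == 0: alpha proportional to the running emission product x prior
        N, L = 5, 8
        haps = lp.random_panel(N, L, seed=11)
        cache = lp.cache_haplotypes(haps)
        rho = np.zeros(L)
        rho[-1] = 1.0
        pars = lp.make_parameters(rho, 0.2, num_haps=N)
        fwd = lp.forward(lp.make_forward_table(N), pars, cache, L - 1)
        for i in range(N):
            direct = np.where(haps == haps[:, [i]], 0.8, 0.2).prod(axis=0)
            direct[i] = 0.0
            direct = direct / (N - 1)
            got = fwd.alpha[:, i] / fwd.alpha[:, i].sum()
            assert np.allclose(got, direct / direct.sum(), rtol=1e-12)

    def test_cannot_move_backwards(self, small_instance):
        cache, pars = small_instance
        fwd = lp.forward(lp.make_forward_table(pars.num_haps), pars, cache, 5)
        with pytest.raises(ValueError, match="cannot move backwards"):
            lp.forward(fwd, pars, cache, 2)

    def test_parameter_hash_mismatch_rejected(self, small_instance):
        cache, pars = small_instance
        fwd = lp.forward(lp.make_forward_table(pars.num_haps), pars, cache, 3)
        other = lp.make_parameters(
            pars.rho, 0.123, "uniform", num_haps=pars.num_haps
        )
        with pytest.raises(ValueError, match="hash"):
            lp.forward(fwd, other, cache, 5)

    def test_auto_initialise_matches_explicit(self, small_instance):
        cache, pars = small_instance
        auto = lp.forward(
            lp.make_forward_table(pars.num_haps), pars, cache, 6
        )
        explicit = lp.make_forward_table(pars.num_haps)
        lp.initialise_forward(explicit, pars, cache)
        lp.forward(explicit, pars, cache, 6)
        assert np.array_equal(auto.alpha, explicit.alpha)

    def test_dimension_mismatch_rejected(self, small_instance):
        cache, pars = small_instance
        other_cache = lp.cache_haplotypes(
            lp.random_panel(pars.num_haps + 1, pars.num_variants, seed=1)
        )
        with pytest.raises(ValueError, match="N="):
            lp.forward(lp.make_forward_table(pars.num_haps + 1), pars,
                       other_cache, 0)


class TestBackward:
    def test_init_all_ones_off_diagonal(self):
        cache, pars = _uniform_instance(6, 10)
        bwd = lp.initialise_backward(lp.make_backward_table(6), pars, cache)
        off = ~np.eye(6, dtype=bool)
        assert (bwd.beta[off] == 1.0).all()
        assert (np.diagonal(bwd.beta) == 0.0).all()
        assert not bwd.beta_theta
        assert (bwd.beta_g == 1.0).all()
        assert bwd.at_variant == 9

    def test_double_initialisation_idempotent(self):
        cache, pars = _uniform_instance(4, 6)
        bwd = lp.initialise_backward(lp.make_backward_table(4), pars, cache)
        snap = bwd.beta.copy()
        lp.initialise_backward(bwd, pars, cache)
        assert np.array_equal(bwd.beta, snap)

    def test_multi_step_equals_single_steps_bit_exact(self, small_instance):
        cache, pars = small_instance
        L, N = pars.num_variants, pars.num_haps
        one = lp.backward(lp.make_backward_table(N), pars, cache, 0)
        many = lp.make_backward_table(N)
        for ell in range(L - 1, -1, -1):
            lp.backward(many, pars, cache, ell)
        assert np.array_equal(one.beta, many.beta)
        assert np.array_equal(one.beta_g, many.beta_g)

    def test_no_switching_closed_form(self):
        # rho == 0: beta_j proportional to the downstream emission product
        N, L = 4, 6
        haps = lp.random_panel(N, L, seed=21)
        cache = lp.cache_haplotypes(haps)
        rho = np.zeros(L)
        rho[-1] = 1.0
        pars = lp.make_parameters(rho, 0.3, num_haps=N)
        ell = 2
        bwd = lp.backward(lp.make_backward_table(N), pars, cache, ell)
        for i in range(N):
            down = np.where(haps[ell + 1:] == haps[ell + 1:, [i]], 0.7, 0.3)
            direct = down.prod(axis=0)
            mask = np.arange(N) != i
            got = bwd.beta[mask, i]
            ratio = got / direct[mask]
            assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_rescaled_space_round_trip(self, small_instance):
        cache, pars = small_instance
        N = pars.num_haps
        plain = lp.backward(lp.make_backward_table(N), pars, cache, 3)
        via = lp.make_backward_table(N)
        lp.backward(via, pars, cache, 7, return_rescaled=True)
        assert via.beta_theta
        lp.backward(via, pars, cache, 3)
        assert not via.beta_theta
        assert np.array_equal(plain.beta, via.beta)

    def test_rescaled_flag_conversion_in_place(self, small_instance):
        cache, pars = small_instance
        N = pars.num_haps
        bwd = lp.backward(lp.make_backward_table(N), pars, cache, 5)
        std = bwd.beta.copy()
        lp.backward(bwd, pars, cache, 5, return_rescaled=True)
        assert bwd.beta_theta and not np.array_equal(bwd.beta, std)
        lp.backward(bwd, pars, cache, 5, return_rescaled=False)
        assert np.allclose(bwd.beta, std, rtol=1e-14)

    def test_cannot_move_forwards(self, small_instance):
        cache, pars = small_instance
        bwd = lp.backward(lp.make_backward_table(pars.num_haps), pars, cache, 4)
        with pytest.raises(ValueError, match="cannot move forwards"):
            lp.backward(bwd, pars, cache, 8)


class TestSlicesAndWorkers:
    @pytest.mark.parametrize("bounds", [(0, 3), (2, 6), (5, 11), (7, 7)])
    def test_recipient_slice_bit_exact(self, bounds):
        cache, pars = _uniform_instance(12, 20, seed=31)
        a, b = bounds
        full_f = lp.forward(lp.make_forward_table(12), pars, cache, 19)
        part_f = lp.forward(lp.make_forward_table(12, a, b), pars, cache, 19)
        assert np.array_equal(full_f.alpha[:, a:b + 1], part_f.alpha)
        assert np.array_equal(full_f.alpha_f[a:b + 1], part_f.alpha_f)
        full_b = lp.backward(lp.make_backward_table(12), pars, cache, 0)
        part_b = lp.backward(lp.make_backward_table(12, a, b), pars, cache, 0)
        assert np.array_equal(full_b.beta[:, a:b + 1], part_b.beta)

    @pytest.mark.parametrize("workers", [2, 3, 8])
    def test_worker_count_independence(self, workers):
        cache, pars = _uniform_instance(10, 16, seed=41)
        base_f = lp.forward(lp.make_forward_table(10), pars, cache, 15)
        par_f = lp.forward(lp.make_forward_table(10), pars, cache, 15,
                           workers=workers)
        assert np.array_equal(base_f.alpha, par_f.alpha)
        base_b = lp.backward(lp.make_backward_table(10), pars, cache, 0)
        par_b = lp.backward(lp.make_backward_table(10), pars, cache, 0,
                            workers=workers)
        assert np.array_equal(base_b.beta, par_b.beta)


class TestTableMechanics:
    def test_copy_is_independent(self, small_instance):
        cache, pars = small_instance
        fwd = lp.forward(lp.make_forward_table(pars.num_haps), pars, cache, 2)
        dup = lp.copy_table(fwd)
        lp.forward(fwd, pars, cache, 6)
        assert dup.at_variant == 2 and fwd.at_variant == 6
        assert not np.array_equal(dup.alpha, fwd.alpha)

    def test_copy_preserves_metadata_and_uninitialised_state(self):
        t = lp.make_forward_table(5, 1, 3)
        c = lp.copy_table(t)
        assert c.at_variant is None and c.pars_hash is None
        assert (c.from_recipient, c.to_recipient) == (1, 3)

    def test_hdf5_checkpoint_round_trip(self, small_instance, tmp_path):
        cache, pars = small_instance
        N = pars.num_haps
        fwd = lp.forward(lp.make_forward_table(N), pars, cache, 5)
        bwd = lp.backward(lp.make_backward_table(N), pars, cache, 5,
                          return_rescaled=True)
        lp.save_table(fwd, tmp_path / "f.h5")
        lp.save_table(bwd, tmp_path / "b.h5")
        f2 = lp.load_table(tmp_path / "f.h5")
        b2 = lp.load_table(tmp_path / "b.h5")
        assert np.array_equal(f2.alpha, fwd.alpha)
        assert f2.pars_hash == pars.content_hash and f2.at_variant == 5
        assert np.array_equal(b2.beta, bwd.beta) and b2.beta_theta
        # a restored table keeps propagating identically
        lp.forward(f2, pars, cache, 9)
        ref = lp.forward(lp.make_forward_table(N), pars, cache, 9)
        assert np.array_equal(f2.alpha, ref.alpha)
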