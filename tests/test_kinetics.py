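"""Contact kernel, reaction propensities, closed-form acetylation and the
single-site periodic-steady-state oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import h3k27sim as h
from h3k27sim.kinetics import (
    AC, ME1, ME2, ME3, U,
    AllosteryGeometry,
    single_site_generator,
    single_site_periodic_steady_state,
    validate_kernel,
)


class TestContactKernel:
    def test_power_law_entries_and_structure(self):
        P = h.contact_kernel(200, 1.0)
        assert P[100, 101] == 1.0
        assert P[100, 110] == pytest.approx(0.1)
        assert np.all(np.diag(P) == 0)
        assert np.allclose(P, P.T)

    def test_exponent_two(self):
        P = h.contact_kernel(50, 2.0)
        assert P[0, 5] == pytest.approx(1 / 25)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            h.contact_kernel(10, 0.0)

    def test_user_kernel_validation(self):
        P = h.contact_kernel(10, 1.0)
        assert validate_kernel(P, 10) is not None
        bad = P.copy()
        bad[0, 1] = 5.0  # breaks symmetry
        with pytest.raises(ValueError, match="symmetric"):
            validate_kernel(bad, 10)


class TestPropensities:
    def _uniform_profile(self, lattice, psi_s=0.0, psi_p=0.0, psi_u=0.0):
        n = lattice.n_sites
        return h.HMEProfile(lattice, np.full(n, psi_s), np.full(n, psi_p), np.full(n, psi_u))

    def test_demethylation_rate_is_gamma_times_utx(self, lattice, params):
        prof = self._uniform_profile(lattice, psi_u=0.2)
        config = np.full(lattice.n_sites, ME2, dtype=np.int8)
        rates = h.propensities(config, prof, params)
        assert rates["demethylate"][0] == pytest.approx(1.5 * 0.2)

    def test_nucleation_only_rate(self, lattice, params):
        prof = self._uniform_profile(lattice, psi_s=0.1)
        config = np.full(lattice.n_sites, ME2, dtype=np.int8)
        rates = h.propensities(config, prof, params)  # no me3 anywhere
        assert rates["methylate"][50] == pytest.approx(0.81 * 0.1)

    def test_spreading_term_adds_kernel_weighted_contribution(self, lattice, params):
        n = lattice.n_sites
        psi_s = np.full(n, 0.1)
        i, j = 100, 110
        psi_s[j] = 0.2
        prof = h.HMEProfile(lattice, psi_s, np.zeros(n), np.zeros(n))
        config = np.full(n, ME2, dtype=np.int8)
        config[j] = ME3
        rates = h.propensities(config, prof, params)
        expected = 0.81 * 0.1 + 0.85 * 0.81 * 0.1 * 0.2
        assert rates["methylate"][i] == pytest.approx(expected)  # 0.09477

    def test_ladder_structure_no_skipping(self, lattice, params):
        """Acetylation is only reachable from u; methylation moves one level."""
        prof = self._uniform_profile(lattice, psi_s=0.3, psi_p=0.4, psi_u=0.2)
        for state, allowed in [
            (U, {"methylate", "acetylate"}),
            (AC, {"deacetylate", "turnover"}),
            (ME1, {"methylate", "demethylate", "turnover"}),
            (ME2, {"methylate", "demethylate", "turnover"}),
            (ME3, {"demethylate", "turnover"}),
        ]:
            config = np.full(lattice.n_sites, state, dtype=np.int8)
            rates = h.propensities(config, prof, params)
            active = {name for name, arr in rates.items() if arr[0] > 0}
            assert active == allowed, f"state {state}"

    def test_zero_R_kills_spreading_for_any_configuration(self, lattice):
        params = h.ModelParams(R=0.0)
        rng = np.random.default_rng(0)
        n = lattice.n_sites
        psi_s = rng.random(n)
        prof = h.HMEProfile(lattice, psi_s, np.zeros(n), np.zeros(n))
        config = rng.integers(0, 5, n).astype(np.int8)
        rates = h.propensities(config, prof, params)
        k_me = params.k_me
        for x, frm in enumerate((U, ME1, ME2)):
            mask = config == frm
            assert np.allclose(rates["methylate"][mask], k_me[x] * psi_s[mask])

    def test_total_outflow_is_sum_of_reactions(self, lattice, params):
        rng = np.random.default_rng(1)
        n = lattice.n_sites
        prof = h.HMEProfile(lattice, rng.random(n), rng.random(n), rng.random(n))
        config = rng.integers(0, 5, n).astype(np.int8)
        rates = h.propensities(config, prof, params)
        total = sum(rates.values())
        # recompute from scratch with an independent loop
        kernel = h.contact_kernel(lattice, params.lambda_exp)
        S = kernel @ (prof.psi_suz12 * (config == ME3))
        k_me, eps = params.k_me, params.eps_me
        for i in range(0, n, 17):
            s = config[i]
            expect = 0.0
            if s == U:
                expect = k_me[0] * prof.psi_suz12[i] + eps[0] * S[i] + params.k_ac * prof.psi_p300[i]
            elif s == AC:
                expect = params.gamma_ac + params.gamma_turn
            elif s in (ME1, ME2):
                x = 1 if s == ME1 else 2
                expect = (k_me[x] * prof.psi_suz12[i] + eps[x] * S[i]
                          + params.gamma_me * prof.psi_utx[i] + params.gamma_turn)
            else:
                expect = params.gamma_me * prof.psi_utx[i] + params.gamma_turn
            assert total[i] == pytest.approx(expect)

    def test_shape_mismatch_rejected(self, lattice, params):
        prof = self._uniform_profile(lattice)
        with pytest.raises(ValueError):
            h.propensities(np.zeros(7, dtype=np.int8), prof, params)


class TestClosedFormAc:
    def test_limits(self, params):
        assert h.closed_form_ac(0.0, params) == 0.0
        assert h.closed_form_ac(1e9, params) == pytest.approx(1.0, abs=1e-6)

    def test_dko_peak_value(self, params):
        # background-corrected DKO p300 peak: 0.1666 + 0.6*0.1196
        assert h.closed_form_ac(0.23836, params) == pytest.approx(0.265, abs=5e-4)

    @given(
        psi=st.floats(1e-4, 5.0),
        dpsi=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_occupancy(self, psi, dpsi):
        p = h.ModelParams()
        assert h.closed_form_ac(psi + dpsi, p) > h.closed_form_ac(psi, p)

    def test_monotonicity_in_rates(self):
        base = h.ModelParams()
        psi = 0.3
        assert h.closed_form_ac(psi, base.with_(k_ac=2.0)) > h.closed_form_ac(psi, base)
        assert h.closed_form_ac(psi, base.with_(gamma_ac=1.2)) < h.closed_form_ac(psi, base)
        assert h.closed_form_ac(psi, base.with_(gamma_turn=0.5)) < h.closed_form_ac(psi, base)
        # longer cycles dilute less, so acetylation rises with T
        assert h.closed_form_ac(psi, base.with_(T=100.0)) > h.closed_form_ac(psi, base)


class TestSingleSiteOracle:
    def test_absorbing_unmodified_state(self):
        params = h.ModelParams(gamma_turn=0.0)
        _, p_avg = single_site_periodic_steady_state(0.0, 0.0, 0.0, params)
        assert p_avg[U] == pytest.approx(1.0)

    def test_zero_generator_fixed_point_is_unmodified(self):
        params = h.ModelParams(k_me3=0, gamma_me=0, k_ac=0, gamma_ac=0, gamma_turn=0)
        Q = single_site_generator(0.5, 0.5, 0.5, params)
        assert np.allclose(Q, 0.0)
        _, p_avg = single_site_periodic_steady_state(0.5, 0.5, 0.5, params)
        # replication map alone drives everything to u
        assert p_avg[U] == pytest.approx(1.0)

    def test_probability_conservation_and_positivity(self, params):
        p_phase, p_avg = single_site_periodic_steady_state(0.3, 0.2, 0.15, params)
        assert np.allclose(p_phase.sum(axis=1), 1.0)
        assert np.all(p_phase >= -1e-12)
        assert p_avg.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("psi_p", [0.05, 0.15, 0.3, 0.7])
    def test_acetylation_only_matches_effective_rate_formula(self, psi_p):
        """Phase-averaged P(ac) vs the ln2/T effective-dilution approximation."""
        params = h.ModelParams(k_me3=0.0, gamma_me=0.0)
        _, p_avg = single_site_periodic_steady_state(0.0, psi_p, 0.0, params)
        assert p_avg[AC] == pytest.approx(h.closed_form_ac(psi_p, params), abs=0.02)


class TestAllostery:
    def test_fold_change_formula(self):
        assert h.allostery_fold_change(0.0) == 0.0
        geom = AllosteryGeometry(a=5.0, d0=5.0)
        assert h.allostery_fold_change(1.2, geom) == pytest.approx(1.2 * np.pi / 6)
        assert h.allostery_fold_change(0.85) == pytest.approx(4.74, abs=0.01)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            AllosteryGeometry(a=0.0, d0=22.0)


class TestModelParams:
    def test_defaults_and_derived_rates(self, params):
        assert params.k_me == pytest.approx([2.43, 2.43, 0.81])
        assert params.eps_me == pytest.approx([0.85 * 2.43, 0.85 * 2.43, 0.85 * 0.81])
        # spreading-to-nucleation ratio identical across methylation steps
        ratio = params.eps_me / params.k_me
        assert np.allclose(ratio, params.R)

    def test_dict_roundtrip(self, params):
        assert h.ModelParams.from_dict(params.to_dict()) == params

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            h.ModelParams(gamma_me=-0.1)
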