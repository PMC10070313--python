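import numpy as np
import pytest

from lh2exciton.exciton import (
    AugmentedHamiltonian,
    CouplingMatrix,
    CTManifold,
    SiteBasis,
    assemble_hamiltonian,
    band_summary,
    circulant_eigenvalues,
    diagonalize,
    k_labels,
    read_hamiltonian,
    rotational_strengths,
    state_dipoles,
    write_hamiltonian,
    write_states_table,
)

from conftest import (
    nearest_neighbor_ring,
    random_geometry,
    random_hamiltonian,
    single_pigment_ring,
    tangential_ring,
)


def dimer(e1=0.0, e2=0.0, v=100.0):
    return assemble_hamiltonian(
        SiteBasis(np.array([e1, e2]), ("Qy", "Qy")),
        CouplingMatrix(np.array([[0.0, v], [v, 0.0]])),
    )


class TestAssembly:
    def test_frenkel_dimer_matrix(self):
        h = dimer(v=100.0)
        np.testing.assert_array_equal(h.matrix(), [[0, 100], [100, 0]])

    def test_ct_block_pattern(self):
        ct = CTManifold(
            ct_energies=np.array([2000.0]),
            ct_couplings=np.array([[300.0], [300.0]]),
            adjacency=((0, 1),),
        )
        h = assemble_hamiltonian(dimer().sites, dimer().couplings, ct)
        expected = [[0, 100, 300], [100, 0, 300], [300, 300, 2000]]
        np.testing.assert_array_equal(h.matrix(), expected)
        # CT-CT block is zero by construction
        assert h.matrix()[2, 2] == 2000.0

    def test_ct_coupling_to_non_adjacent_site_rejected(self):
        with pytest.raises(ValueError, match="non-adjacent"):
            CTManifold(
                ct_energies=np.array([2000.0]),
                ct_couplings=np.array([[300.0], [0.0], [50.0]]),
                adjacency=((0, 1),),
            )

    def test_asymmetric_couplings_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            CouplingMatrix(np.array([[0.0, 100.0], [50.0, 0.0]]))

    def test_non_finite_entries_rejected(self):
        with pytest.raises(ValueError):
            SiteBasis(np.array([np.nan, 0.0]), ("Qy", "Qy"))


class TestDiagonalization:
    def test_symmetric_dimer_splitting(self):
        states = diagonalize(dimer(v=100.0))
        np.testing.assert_allclose([s.energy for s in states], [-100, 100], atol=1e-10)

    @pytest.mark.parametrize("delta,v", [(50.0, 100.0), (300.0, 40.0), (0.0, 166.0)])
    def test_detuned_dimer_closed_form(self, delta, v):
        states = diagonalize(dimer(0.0, delta, v))
        split = states[1].energy - states[0].energy
        assert split == pytest.approx(np.sqrt(delta**2 + 4 * v**2), abs=1e-10)

    @pytest.mark.parametrize("n", [7, 9, 14, 18, 27])
    def test_circulant_ring_matches_analytic_spectrum(self, n):
        h = nearest_neighbor_ring(n, 100.0, site_energy=12500.0)
        numeric = np.array([s.energy for s in diagonalize(h)])
        np.testing.assert_allclose(
            numeric, circulant_eigenvalues(12500.0, 100.0, n), atol=1e-8
        )

    def test_trace_and_orthonormality(self, rng):
        h = random_hamiltonian(rng, 12)
        states = diagonalize(h)
        assert sum(s.energy for s in states) == pytest.approx(
            np.trace(h.matrix()), abs=1e-6
        )
        vecs = np.array([s.coefficients for s in states])
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(12), atol=1e-10)

    def test_deterministic_gauge(self, rng):
        h = random_hamiltonian(rng, 8)
        a = diagonalize(h)
        b = diagonalize(h)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.coefficients, sb.coefficients)


class TestDipolesAndRotationalStrengths:
    def test_single_site_state_carries_site_dipole(self):
        h = assemble_hamiltonian(
            SiteBasis(np.array([12500.0]), ("Qy",)), CouplingMatrix(np.zeros((1, 1)))
        )
        ring = single_pigment_ring()
        (s,) = state_dipoles(diagonalize(h), ring)
        np.testing.assert_allclose(s.transition_dipole, ring.dipoles[0])
        assert s.dipole_strength == pytest.approx(6.3**2)

    def test_bright_pair_concentrates_dipole_strength(self):
        n = 7
        states = state_dipoles(
            diagonalize(nearest_neighbor_ring(n, 100.0)), tangential_ring(n)
        )
        states = k_labels(states, n)
        total = sum(s.dipole_strength for s in states)
        bright = sum(s.dipole_strength for s in states if s.k_label == 1)
        assert bright / total > 0.95
        # the fully symmetric state is dark: tangential dipoles cancel
        k0 = [s for s in states if s.k_label == 0]
        for s in k0:
            assert s.dipole_strength == pytest.approx(0.0, abs=1e-16)

    def test_dipole_strength_sum_rule_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            h = random_hamiltonian(rng, n)
            geom = random_geometry(rng, n)
            states = state_dipoles(diagonalize(h), geom)
            total_site = np.sum(geom.dipoles**2)
            total_exciton = sum(s.dipole_strength for s in states)
            assert total_exciton == pytest.approx(total_site, rel=1e-8)

    def test_single_pigment_has_zero_rotational_strength(self):
        h = assemble_hamiltonian(
            SiteBasis(np.array([12500.0]), ("Qy",)), CouplingMatrix(np.zeros((1, 1)))
        )
        (s,) = rotational_strengths(diagonalize(h), single_pigment_ring())
        assert s.rotational_strength == 0.0

    def test_parallel_dipoles_give_no_cd(self):
        geom = random_geometry(np.random.default_rng(1), 2)
        for p in geom.pigments:
            object.__setattr__(p, "dipole_axis", np.array([0.0, 0.0, 1.0]))
        states = rotational_strengths(diagonalize(dimer(v=80.0)), geom)
        for s in states:
            assert s.rotational_strength == pytest.approx(0.0, abs=1e-12)

    def test_conservative_cd_sum_rule_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            h = random_hamiltonian(rng, n)
            geom = random_geometry(rng, n)
            states = rotational_strengths(diagonalize(h), geom)
            scale = max(abs(s.rotational_strength / s.energy) for s in states) or 1.0
            resid = sum(s.rotational_strength / s.energy for s in states)
            assert abs(resid) / scale < 1e-8


class TestKLabels:
    def test_homogeneous_seven_ring_multiplicities(self):
        n = 7
        states = k_labels(diagonalize(nearest_neighbor_ring(n, 100.0)), n)
        labels = [s.k_label for s in states]
        assert sorted(labels) == [0, 1, 1, 2, 2, 3, 3]

    def test_ground_state_of_negative_coupling_ring_is_totally_symmetric(self):
        states = k_labels(diagonalize(nearest_neighbor_ring(9, -100.0)), 9)
        assert states[0].k_label == 0
        assert np.all(states[0].coefficients > 0)

    def test_strong_disorder_localizes_states(self, rng):
        n = 8
        e = rng.normal(0.0, 5000.0, n)
        v = np.zeros((n, n))
        for i in range(n):
            v[i, (i + 1) % n] = v[(i + 1) % n, i] = 50.0
        h = AugmentedHamiltonian(SiteBasis(e, ("Qy",) * n), CouplingMatrix(v))
        states = k_labels(diagonalize(h), n)
        mixed = sum(1 for s in states if s.k_label == "mixed")
        assert mixed > n // 2

    def test_incommensurate_symmetry_rejected(self):
        states = diagonalize(nearest_neighbor_ring(9, 100.0))
        with pytest.raises(ValueError, match="divide"):
            k_labels(states, 7)


class TestBandSummary:
    def test_single_site_summary(self):
        h = assemble_hamiltonian(
            SiteBasis(np.array([12500.0]), ("Qy",)), CouplingMatrix(np.zeros((1, 1)))
        )
        states = state_dipoles(diagonalize(h), single_pigment_ring())
        summary = band_summary(states)
        assert summary["band_width"] == 0.0
        assert summary["ipr"][0] == pytest.approx(1.0)
        assert summary["bright_energy"] == pytest.approx(12500.0)

    @pytest.mark.parametrize("n", [7, 9, 14])
    def test_band_width_matches_circulant_spectrum(self, n):
        states = diagonalize(nearest_neighbor_ring(n, 150.0))
        analytic = circulant_eigenvalues(0.0, 150.0, n)
        summary = band_summary(states)
        assert summary["band_width"] == pytest.approx(
            analytic.max() - analytic.min(), abs=1e-8
        )

    def test_uniform_delocalization_ipr(self):
        n = 10
        states = diagonalize(nearest_neighbor_ring(n, -100.0))
        # totally symmetric ground state spreads evenly over all n sites
        assert states[0].ipr == pytest.approx(n, rel=1e-10)


class TestCTEffects:
    def test_decoupled_ct_states_leave_qy_spectrum_unchanged(self):
        base = dimer(v=120.0)
        ct = CTManifold(
            ct_energies=np.array([2500.0]),
            ct_couplings=np.zeros((2, 1)),
            adjacency=((0, 1),),
        )
        augmented = assemble_hamiltonian(base.sites, base.couplings, ct)
        e_base = [s.energy for s in diagonalize(base)]
        e_aug = [s.energy for s in diagonalize(augmented)][:2]
        np.testing.assert_allclose(e_base, e_aug, atol=1e-10)

    def test_ct_above_band_redshifts_lowest_state_monotonically(self):
        lows = []
        for vct in (0.0, 100.0, 200.0, 400.0):
            ct = CTManifold(
                ct_energies=np.array([2500.0]),
                ct_couplings=np.array([[vct], [-vct]]),
                adjacency=((0, 1),),
            )
            h = assemble_hamiltonian(dimer(v=120.0).sites, dimer(v=120.0).couplings, ct)
            lows.append(diagonalize(h)[0].energy)
        assert all(b < a for a, b in zip(lows, lows[1:]))


class TestSerialization:
    def test_hamiltonian_text_round_trip(self, rng, tmp_path):
        h = random_hamiltonian(rng, 5)
        ct = CTManifold(
            ct_energies=np.array([15000.0, 15100.0]),
            ct_couplings=np.array(
                [[200.0, 0.0], [-200.0, 300.0], [0.0, -300.0], [0.0, 0.0], [0.0, 0.0]]
            ),
            adjacency=((0, 1), (1, 2)),
        )
        h = assemble_hamiltonian(h.sites, h.couplings, ct)
        path = tmp_path / "h.txt"
        write_hamiltonian(h, path)
        back = read_hamiltonian(path)
        np.testing.assert_allclose(back.matrix(), h.matrix(), rtol=1e-9)
        assert back.sites.classes == h.sites.classes
        assert back.ct.adjacency == h.ct.adjacency

    def test_states_table_columns(self, rng, tmp_path):
        import pandas as pd

        n = 7
        states = state_dipoles(
            diagonalize(nearest_neighbor_ring(n, 100.0)), tangential_ring(n)
        )
        states = rotational_strengths(states, tangential_ring(n))
        states = k_labels(states, n)
        path = tmp_path / "states.tsv"
        write_states_table(states, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "energy_cm1",
            "dipole_strength_D2",
            "rotational_strength",
            "k_label",
            "ipr",
        ]
        assert len(df) == n
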