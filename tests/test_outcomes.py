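"""Mechanical outcome measures: stiffness, apparent modulus, von Mises
averages, Pistoia failure load, and dual-tissue load sharing."""

import numpy as np
import pytest

from voxelfe import (BCSpec, DensityVolume, FailureCriterion, SolverConfig,
                     apparent_modulus, assign_dtm, assign_stm,
                     average_von_mises, build_mesh, failure_load, layer_forces,
                     load_sharing, solve, stiffness)
from voxelfe.fe_model import Model
from voxelfe.volume import CORT, TRAB
from conftest import make_prism, porous_mask

H = 0.082
TIGHT = SolverConfig(rel_tolerance=1e-12)
BC = BCSpec()


@pytest.fixture(scope="module")
def prism():
    mesh = make_prism(3, 3, 5, E=10000.0, nu=0.0)
    return mesh, solve(mesh, BC, TIGHT)


@pytest.fixture(scope="module")
def porous():
    mask = porous_mask((4, 4, 6), fill=0.65, seed=21)
    vol = DensityVolume(np.full(mask.shape, 1200.0, dtype=np.float32))
    mesh = build_mesh(mask, "STM", vol=vol)
    mesh.poisson = 0.3
    assign_stm(mesh)
    return mesh, solve(mesh, BC, TIGHT)


class TestStiffness:
    def test_prism_closed_form(self, prism):
        """nu=0 homogeneous prism: stiffness = E*A/L."""
        mesh, sol = prism
        expected = 10000.0 * (3 * H) ** 2 / (5 * H) / 1000.0
        assert stiffness(sol, mesh, BC) == pytest.approx(expected, rel=1e-9)

    def test_uses_applied_displacement_divisor(self, porous):
        mesh, sol = porous
        delta = BC.applied_displacement(mesh)
        assert stiffness(sol, mesh, BC) == pytest.approx(
            abs(sol.reaction_distal) / delta / 1000.0)

    def test_zero_displacement_rejected(self, prism):
        mesh, sol = prism
        with pytest.raises(ValueError):
            stiffness(sol, mesh, BCSpec(applied_strain=0.0))


class TestApparentModulus:
    def test_full_section_recovers_E(self, prism):
        """Full prism with the true section area returns E exactly."""
        _, sol = prism
        csa = (3 * H) ** 2
        assert apparent_modulus(sol, BC, csa) == pytest.approx(1e4, rel=1e-9)

    def test_halving_area_doubles(self, prism):
        _, sol = prism
        a = apparent_modulus(sol, BC, 1.0)
        assert apparent_modulus(sol, BC, 0.5) == pytest.approx(2 * a)

    def test_matches_reaction_arithmetic(self, porous):
        _, sol = porous
        csa = 0.05
        assert apparent_modulus(sol, BC, csa) == pytest.approx(
            abs(sol.reaction_distal) / (csa * 0.01))


class TestAverageVonMises:
    def test_uniform_prism(self, prism):
        mesh, sol = prism
        assert average_von_mises(sol, mesh) == pytest.approx(100.0, rel=1e-9)

    def test_empty_subset_rejected(self, prism):
        mesh, sol = prism
        mesh.tissue_per_element = np.full(mesh.n_elements, TRAB, np.uint8)
        try:
            with pytest.raises(ValueError, match="empty subset"):
                average_von_mises(sol, mesh, "cortical")
        finally:
            mesh.tissue_per_element = None

    def test_overall_mean_is_count_weighted_tissue_mean(self, porous):
        mesh, sol = porous
        rng = np.random.default_rng(4)
        mesh.tissue_per_element = np.where(
            rng.random(mesh.n_elements) < 0.4, CORT, TRAB).astype(np.uint8)
        n_c = (mesh.tissue_per_element == CORT).sum()
        n_t = mesh.n_elements - n_c
        combined = (n_c * average_von_mises(sol, mesh, "cortical")
                    + n_t * average_von_mises(sol, mesh, "trabecular")) \
            / mesh.n_elements
        assert average_von_mises(sol, mesh) == pytest.approx(combined)
        mesh.tissue_per_element = None


class TestFailureLoad:
    def test_prism_closed_form(self, prism):
        """Uniform eeq = 0.01 -> scale 0.7 -> failure load 0.007*E*A."""
        mesh, sol = prism
        crit = FailureCriterion()
        expected = 0.007 * 10000.0 * (3 * H) ** 2 / 1000.0
        assert failure_load(sol, mesh, crit) == pytest.approx(expected,
                                                              rel=1e-9)

    def test_stress_variant_identical_for_stm(self, prism):
        """70 MPa energy-equivalent stress with E = 10 GPa is the same
        criterion as 7000 ue strain: identical failure loads."""
        mesh, sol = prism
        f_strain = failure_load(sol, mesh, FailureCriterion(variant="strain"))
        f_stress = failure_load(sol, mesh, FailureCriterion(variant="stress"))
        assert f_stress == pytest.approx(f_strain, rel=1e-9)

    def test_matches_exhaustive_scaling_oracle(self, porous):
        """Brute force: scan load scales until the exceedance fraction first
        reaches 2 %; the analytic k-th-largest scale agrees to 1e-9."""
        mesh, sol = porous
        crit = FailureCriterion()
        got = failure_load(sol, mesh, crit)
        v = np.sort(sol.eeq_strain)[::-1]
        n = v.size
        k = int(np.ceil(crit.tissue_fraction * n))
        # smallest s with  #(s*v >= limit) >= k  is limit / v[k-1]
        s_star = crit.strain_limit / v[k - 1]
        frac_at = (s_star * v >= crit.strain_limit * (1 - 1e-12)).sum() / n
        assert frac_at >= crit.tissue_fraction
        expected = s_star * abs(sol.reaction_distal) / 1000.0
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_solve_strain(self, porous):
        """Linearity: solving at 0.5 % or 1 % strain gives the same failure
        load."""
        mesh, _ = porous
        crit = FailureCriterion()
        sol_half = solve(mesh, BCSpec(applied_strain=0.005), TIGHT)
        sol_full = solve(mesh, BCSpec(applied_strain=0.01), TIGHT)
        assert failure_load(sol_half, mesh, crit) == pytest.approx(
            failure_load(sol_full, mesh, crit), rel=1e-8)

    def test_stm_7000_equals_dtm_3500_at_double_modulus(self, porous):
        """Halving the strain limit exactly compensates doubling E (the
        dual-tissue criterion's rescaling logic)."""
        mesh, _ = porous
        assign_stm(mesh, 10000.0)
        sol10 = solve(mesh, BC, TIGHT)
        f10 = failure_load(sol10, mesh, FailureCriterion(strain_limit=7000e-6))
        assign_stm(mesh, 20000.0)
        sol20 = solve(mesh, BC, TIGHT)
        f20 = failure_load(sol20, mesh, FailureCriterion(strain_limit=3500e-6))
        assign_stm(mesh, 10000.0)
        assert f10 == pytest.approx(f20, rel=1e-8)

    def test_model_default_limits(self):
        assert FailureCriterion.for_model("STM").strain_limit == 7000e-6
        assert FailureCriterion.for_model("DTM").strain_limit == 3500e-6
        assert FailureCriterion.for_model("EBMD").strain_limit == 7000e-6


class TestLoadSharing:
    def test_all_cortical(self, prism):
        mesh, sol = prism
        mesh.tissue_per_element = np.full(mesh.n_elements, CORT, np.uint8)
        shares = load_sharing(sol, mesh)
        assert shares["cortical"]["pct_load_min"] == pytest.approx(100.0)
        assert shares["cortical"]["pct_load_max"] == pytest.approx(100.0)
        assert shares["trabecular"]["pct_load_max"] == pytest.approx(0.0)
        mesh.tissue_per_element = None

    def test_partition_sums_to_100(self, porous):
        mesh, sol = porous
        rng = np.random.default_rng(8)
        mesh.tissue_per_element = np.where(
            rng.random(mesh.n_elements) < 0.5, CORT, TRAB).astype(np.uint8)
        shares = load_sharing(sol, mesh)
        # recompute per layer and check partition
        area = mesh.edge_length ** 2
        z = mesh.elements[:, 2]
        szz = sol.element_stress[:, 2] * area
        for layer in np.unique(z):
            sel = z == layer
            total = szz[sel].sum()
            c = szz[sel & (mesh.tissue_per_element == CORT)].sum()
            t = szz[sel & (mesh.tissue_per_element == TRAB)].sum()
            assert (c + t) / total == pytest.approx(1.0, abs=1e-9)
        mesh.tissue_per_element = None

    def test_three_layer_toy_hand_summed(self):
        """3-layer column of two side-by-side bars with different moduli:
        load split follows E_a/(E_a+E_b) in every layer (hand arithmetic)."""
        mask = np.ones((2, 1, 3), dtype=bool)
        vol = DensityVolume(np.full(mask.shape, 1200.0, dtype=np.float32))
        mesh = build_mesh(mask, "STM", vol=vol)
        mesh.poisson = 0.0
        mesh.tissue_per_element = np.where(mesh.elements[:, 0] == 0, CORT,
                                           TRAB).astype(np.uint8)
        assign_dtm(mesh, 20000.0, 10000.0)
        mesh.model = Model.DTM
        sol = solve(mesh, BC, TIGHT)
        shares = load_sharing(sol, mesh)
        assert shares["cortical"]["pct_load_min"] == pytest.approx(200 / 3,
                                                                   rel=1e-9)
        assert shares["cortical"]["pct_load_max"] == pytest.approx(200 / 3,
                                                                   rel=1e-9)
        assert shares["trabecular"]["pct_load_min"] == pytest.approx(100 / 3,
                                                                     rel=1e-9)

    def test_layer_force_conserved(self, porous):
        """Total axial force is constant down the shaft."""
        mesh, sol = porous
        lf = layer_forces(sol, mesh)
        assert np.ptp(np.abs(lf)) <= 1e-6 * np.abs(lf).max()
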