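"""Fractal-metric tests: exact examples, analytic limits, oracle shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silafract import fractal
from silafract.fractal import (
    compactness,
    compute_rg,
    connected_clusters,
    detect_contacts,
    fractal_dimension,
    mass_radius_dimension,
    mean_valency,
    molecular_volume,
    rg_to_rh,
    unwrap_frame,
)
from silafract.structio import AssemblyFrame, Trajectory


def bead_frame(positions, chains=None, masses=None, box=None, resids=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return AssemblyFrame(
        positions=positions,
        chain=np.asarray(chains if chains is not None else ["A"] * n, dtype=object),
        resid=np.asarray(resids if resids is not None else np.arange(1, n + 1)),
        resname=np.asarray(["SER"] * n, dtype=object),
        mass=np.asarray(masses if masses is not None else np.ones(n)),
        bead_class=np.asarray(["peptide"] * n, dtype=object),
        box=box,
    )


class TestComputeRg:
    def test_single_bead_zero(self):
        assert compute_rg(bead_frame([[1, 2, 3]])) == 0.0

    def test_two_unit_beads(self):
        assert compute_rg(bead_frame([[0, 0, 0], [2, 0, 0]])) == pytest.approx(1.0)

    def test_cube_corners(self):
        corners = [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)]
        assert compute_rg(bead_frame(corners)) == pytest.approx(math.sqrt(3.0))

    def test_mass_weighting_moves_com(self):
        f = bead_frame([[0, 0, 0], [2, 0, 0]], masses=[3.0, 1.0])
        # com at x=0.5: rg = sqrt((3*0.25 + 1*2.25)/4) = sqrt(0.75)
        assert compute_rg(f) == pytest.approx(math.sqrt(0.75))
        assert compute_rg(f, mass_weighted=False) == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            compute_rg(bead_frame([[0, 0, 0]]), selection=["Z"])

    def test_rigid_motion_invariance(self, r5_block, rng):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=rng)
        moved = r5_block.translated([10.0, -4.0, 2.0])
        moved.positions = rot.apply(moved.positions)
        assert compute_rg(moved) == pytest.approx(compute_rg(r5_block), rel=1e-12)


class TestContacts:
    def two_chain_frame(self, separation):
        pos = [[0, 0, 0], [separation, 0, 0]]
        return bead_frame(pos, chains=["A", "B"], resids=[1, 1])

    def test_distant_chains_no_edge(self):
        g = detect_contacts(self.two_chain_frame(100.0), cutoff=4.5)
        assert g.number_of_edges() == 0

    def test_coincident_beads_one_edge(self):
        g = detect_contacts(self.two_chain_frame(0.0), cutoff=4.5)
        assert g.number_of_edges() == 1

    def test_surface_distance_criterion(self):
        # centre distance 10.4 = 4.4 + radii (3+3): inside the 4.5 cutoff
        assert detect_contacts(self.two_chain_frame(10.4)).number_of_edges() == 1
        # centre distance 10.6 = 4.6 + 6: outside
        assert detect_contacts(self.two_chain_frame(10.6)).number_of_edges() == 0

    def test_four_touching_chains_complete_graph(self):
        pos = [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]]
        f = bead_frame(pos, chains=["A", "B", "C", "D"], resids=[1, 1, 1, 1])
        g = detect_contacts(f)
        assert all(d == 3 for _, d in g.degree())
        assert mean_valency(g) == pytest.approx(3.0)

    def test_counterion_bridges_reported_not_counted(self):
        f = AssemblyFrame(
            positions=np.asarray([[0.0, 0, 0], [12.0, 0, 0], [6.0, 0, 0]]),
            chain=np.asarray(["A", "B", "A"], dtype=object),
            resid=np.asarray([1, 1, 2]),
            resname=np.asarray(["SER", "SER", "PO4"], dtype=object),
            mass=np.asarray([100.0, 100.0, 95.0]),
            bead_class=np.asarray(["peptide", "peptide", "counterion"], dtype=object),
        )
        g = detect_contacts(f, cutoff=4.5)
        assert g.number_of_edges() == 0  # peptide-peptide distance 12 > 10.5
        assert g.graph["bridges"] == [("A", "B", 1)]

    def test_minimum_image_contacts(self):
        # beads at the opposite faces of a 20 Å box touch across the boundary
        f = bead_frame([[0.5, 0, 0], [19.5, 0, 0]], chains=["A", "B"],
                       resids=[1, 1], box=[20.0, 20.0, 20.0])
        assert detect_contacts(f).number_of_edges() == 1


class TestGraphMetrics:
    def test_mean_valency_cases(self):
        import networkx as nx

        iso = nx.empty_graph(3)
        assert mean_valency(iso) == 0.0
        single = nx.Graph([("A", "B")])
        assert mean_valency(single) == 1.0
        path3 = nx.path_graph(3)
        assert mean_valency(path3) == pytest.approx(4.0 / 3.0)

    def test_pair_count_mode(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("A", "B", n_pairs=5)
        assert mean_valency(g, mode="pairs") == pytest.approx(5.0)

    def test_connected_clusters_ordering(self):
        import networkx as nx

        g = nx.Graph([("A", "B"), ("C", "D"), ("D", "E")])
        clusters = connected_clusters(g)
        assert clusters[0] == {"C", "D", "E"}
        assert len(clusters) == 2


class TestScalarMetrics:
    def test_molecular_volume(self):
        assert molecular_volume(1000.0) == pytest.approx(1210.0)
        assert molecular_volume(0.0) == 0.0
        assert molecular_volume(2000.0) == pytest.approx(2 * molecular_volume(1000.0))

    def test_compactness_example(self):
        # two 3000 Da beads at ±12 Å: Rg = 12 Å, Mw = 6000 Da
        f = bead_frame([[-12, 0, 0], [12, 0, 0]], masses=[3000.0, 3000.0])
        phi = compactness(f)
        assert phi == pytest.approx(1.21 * 6000 / ((4 / 3) * math.pi * 12**3), rel=1e-12)
        assert phi == pytest.approx(1.003, abs=5e-4)

    def test_compactness_scales_inverse_cube(self):
        f1 = bead_frame([[-6, 0, 0], [6, 0, 0]], masses=[3000.0, 3000.0])
        f2 = bead_frame([[-12, 0, 0], [12, 0, 0]], masses=[3000.0, 3000.0])
        assert compactness(f1) / compactness(f2) == pytest.approx(8.0)

    def test_compactness_zero_rg_rejected(self):
        with pytest.raises(ValueError, match="Rg"):
            compactness(bead_frame([[0, 0, 0]], masses=[100.0]))


class TestFractalDimension:
    @pytest.mark.parametrize("valency", [1.5, 2.0, 4.0, 50.0])
    def test_unity_compactness_gives_three(self, valency):
        assert fractal_dimension(1.0, valency) == 3.0

    @pytest.mark.parametrize("v", [2.0, 3.0, 4.0])
    def test_phi_equal_valency_gives_zero(self, v):
        assert fractal_dimension(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        assert fractal_dimension(2.0, 4.0) == pytest.approx(1.5)

    @given(
        phi_a=st.floats(0.01, 50.0),
        phi_b=st.floats(0.01, 50.0),
        valency=st.floats(1.1, 20.0),
    )
    @settings(max_examples=80, derandomize=True)
    def test_strictly_decreasing_in_phi(self, phi_a, phi_b, valency):
        if phi_a == phi_b:
            return
        lo, hi = sorted((phi_a, phi_b))
        assert fractal_dimension(lo, valency) > fractal_dimension(hi, valency)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            fractal_dimension(0.0, 2.0)
        with pytest.raises(ValueError):
            fractal_dimension(1.5, 1.0)


class TestRgToRh:
    @pytest.mark.parametrize("rg,rh", [(1.1, 1.0), (0.0, 0.0), (0.88, 0.8)])
    def test_conversion(self, rg, rh):
        assert rg_to_rh(rg) == pytest.approx(rh)


class TestMassRadiusDimension:
    def test_straight_line(self):
        f = bead_frame([[4.0 * k, 0, 0] for k in range(100)])
        d = mass_radius_dimension(f).dimension
        assert 0.8 <= d <= 1.4

    def test_filled_cubic_lattice(self):
        pts = [[4 * x, 4 * y, 4 * z] for x in range(7) for y in range(7) for z in range(7)]
        d = mass_radius_dimension(bead_frame(pts)).dimension
        assert 2.6 <= d <= 3.2

    def test_square_sheet(self):
        pts = [[4 * x, 4 * y, 0] for x in range(14) for y in range(14)]
        d = mass_radius_dimension(bead_frame(pts)).dimension
        assert 1.7 <= d <= 2.3

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError, match="20 beads"):
            mass_radius_dimension(bead_frame([[0, 0, 0], [1, 0, 0]]))


class TestUnwrap:
    def test_chain_across_boundary_rejoined(self):
        box = [20.0, 20.0, 20.0]
        f = bead_frame([[19.0, 0, 0], [1.0, 0, 0]], box=box, resids=[1, 2])
        out = unwrap_frame(f)
        d = np.linalg.norm(out.positions[1] - out.positions[0])
        assert d == pytest.approx(2.0)

    def test_chains_pulled_to_same_image(self):
        box = [20.0, 20.0, 20.0]
        f = AssemblyFrame(
            positions=np.asarray([[1.0, 0, 0], [19.0, 0, 0]]),
            chain=np.asarray(["A", "B"], dtype=object),
            resid=np.asarray([1, 1]),
            resname=np.asarray(["SER", "SER"], dtype=object),
            mass=np.ones(2),
            bead_class=np.asarray(["peptide", "peptide"], dtype=object),
            box=np.asarray(box),
        )
        out = unwrap_frame(f)
        assert np.linalg.norm(out.positions[1] - out.positions[0]) == pytest.approx(2.0)

    def test_no_box_is_noop(self, r5_block):
        assert unwrap_frame(r5_block) is r5_block


class TestAnalyzeTrajectory:
    def test_frozen_trajectory_zero_sd(self, small_assemblies):
        frame = small_assemblies["compact"]
        frames = []
        for t in range(4):
            import dataclasses

            f = dataclasses.replace(frame)
            f.time = float(t)
            frames.append(f)
        traj = Trajectory(frames)
        m = fractal.analyze_trajectory(traj)
        single = fractal.analyze_frame(frame)
        assert m.rg_sd == pytest.approx(0.0, abs=1e-12)
        assert m.rg == pytest.approx(single.rg)
        assert m.valency == pytest.approx(single.valency)

    def test_full_window_equals_mean_of_frames(self, small_assemblies):
        import dataclasses

        frames = []
        for t, mode in enumerate(("linear", "compact")):
            f = dataclasses.replace(small_assemblies[mode])
            f.time = float(t)
            frames.append(f)
        # different morphologies share topology (same block, same counts)
        traj = Trajectory(frames)
        m = fractal.analyze_trajectory(traj, window=None)
        per = [fractal.analyze_frame(f).rg for f in frames]
        assert m.rg == pytest.approx(np.mean(per))
        assert m.n_frames == 2

    def test_last_fraction_window(self, small_assemblies):
        import dataclasses

        frames = []
        for t in range(5):
            f = dataclasses.replace(small_assemblies["compact"])
            f.time = float(t)
            frames.append(f)
        traj = Trajectory(frames)
        m = fractal.analyze_trajectory(traj, window="last:20%")
        assert m.n_frames == 1

    def test_empty_time_window_rejected(self, small_assemblies):
        traj = Trajectory([small_assemblies["compact"]])
        with pytest.raises(ValueError, match="no frames"):
            fractal.analyze_trajectory(traj, window=(5.0, 6.0))

    def test_v_mol_identity(self, small_assemblies):
        m = fractal.analyze_frame(small_assemblies["compact"])
        assert m.v_mol == pytest.approx(m.kappa * m.mw_total, rel=1e-15)
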