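"""Contact graphs, honeycomb shells, interface typing and lattice metrics."""

import itertools

import numpy as np
import pytest

from conftest import brute_force_contacts, random_rotation
from filarch.helical import HelicalParams, build_filament
from filarch.lattice import (
    HoneycombNeighborhood,
    IncompleteShellError,
    InterfaceRecord,
    annotate_residues,
    base_layer_count,
    classify_interfaces,
    contact_graph,
    extract_honeycomb,
    minimal_arc_cover,
    rim_diameters,
)
from filarch.structures import AtomSite, FilamentAssembly, ProtomerStructure
from filarch.synthetic import (
    IFI16_PRESET,
    LatticePreset,
    ToyProtomerSpec,
    make_filament_fixture,
    make_toy_protomer,
)


class TestContactGraph:
    def test_far_apart_protomers_share_no_edge(self, toy_protomer):
        far = toy_protomer.transformed(np.eye(3), np.array([200.0, 0.0, 0.0]))
        fil = FilamentAssembly([toy_protomer, far])
        cg = contact_graph(fil)
        assert cg.graph.number_of_edges() == 0

    def test_matches_brute_force_oracle(self, toy_protomer):
        fil = build_filament(toy_protomer, IFI16_PRESET.params, 4)
        cg = contact_graph(fil)
        oracle = brute_force_contacts(fil, cg.cutoff)
        got = {(i, j): (cg.edge(i, j)["contacts"],
                        cg.edge(i, j)["min_distance"])
               for i, j in cg.graph.edges}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key][0] == oracle[key][0]
            assert got[key][1] == pytest.approx(oracle[key][1], abs=1e-9)

    def test_interior_degree_is_six(self, pyd_fixture):
        filament, _ = pyd_fixture
        cg = contact_graph(filament)
        for i in range(5, len(filament) - 5):
            assert cg.degree(i) == 6


class TestHoneycomb:
    def test_interior_shell_has_six_members(self, pyd_honeycomb):
        assert len(pyd_honeycomb.shell) == 6
        assert pyd_honeycomb.offsets == [-3, -2, -1, 1, 2, 3]

    def test_halves_partition_shell(self, pyd_honeycomb):
        halves = {r.half for r in pyd_honeycomb.shell}
        assert halves == {"top", "bottom"}
        assert sum(r.half == "top" for r in pyd_honeycomb.shell) == 3

    def test_terminal_center_rejected_with_missing_offsets(self, pyd_fixture):
        filament, _ = pyd_fixture
        with pytest.raises(IncompleteShellError, match="missing"):
            extract_honeycomb(filament, 0)

    def test_shell_invariant_to_filament_length_and_index(self, pyd_fixture):
        filament, truth = pyd_fixture
        longer, _ = make_filament_fixture(IFI16_PRESET, n=40)
        a = extract_honeycomb(filament, 15)
        b = extract_honeycomb(longer, 20)
        assert a.offsets == b.offsets
        for ra, rb in zip(sorted(a.shell, key=lambda r: r.partner_offset),
                          sorted(b.shell, key=lambda r: r.partner_offset)):
            assert ra.contact_count == rb.contact_count
            assert ra.min_distance == pytest.approx(rb.min_distance, abs=1e-9)


class TestClassifyInterfaces:
    @staticmethod
    def _neigh_with_pairs(center, pairs):
        rec = InterfaceRecord(partner_index=1, partner_offset=1, partner=center,
                              half="top", contact_count=len(pairs),
                              min_distance=3.5, residue_pairs=pairs)
        return HoneycombNeighborhood(center_index=0, center=center, shell=[rec])

    def test_helix3_dominated_contact_is_type3(self, toy_protomer):
        h3 = toy_protomer.ss_segments["h3"]
        pairs = [(r, 1) for r in range(h3[0] + 3, h3[1] - 2)]
        neigh = self._neigh_with_pairs(toy_protomer, pairs)
        classify_interfaces(neigh)
        assert neigh.shell[0].type_label == "3a:3b"
        assert neigh.shell[0].center_side == "a"

    def test_h5h6_loop_dominated_contact_is_type2(self, toy_protomer):
        loop = toy_protomer.ss_segments["loop_h5h6"]
        pairs = [(r, 1) for r in range(loop[0], loop[1] + 1)]
        neigh = self._neigh_with_pairs(toy_protomer, pairs)
        classify_interfaces(neigh)
        assert neigh.shell[0].type_label == "2a:2b"
        assert neigh.shell[0].center_side == "b"

    def test_h1h2_face_is_type1_side_a(self, toy_protomer):
        h1, h2 = toy_protomer.ss_segments["h1"], toy_protomer.ss_segments["h2"]
        pairs = [(r, 1) for r in range(h1[0] + 2, h1[1])]
        pairs += [(r, 1) for r in range(h2[0] + 2, h2[1])]
        neigh = self._neigh_with_pairs(toy_protomer, pairs)
        classify_interfaces(neigh)
        assert neigh.shell[0].type_label == "1a:1b"
        assert neigh.shell[0].center_side == "a"

    def test_balanced_contact_flagged_ambiguous(self, toy_protomer):
        h1 = toy_protomer.ss_segments["h1"]
        h3 = toy_protomer.ss_segments["h3"]
        pairs = [(h1[0] + i, 1) for i in range(4)] + [(h3[0] + i, 1) for i in range(4)]
        neigh = self._neigh_with_pairs(toy_protomer, pairs)
        classify_interfaces(neigh)
        assert neigh.shell[0].ambiguous

    def test_missing_segments_rejected(self, toy_protomer):
        bare = ProtomerStructure(atoms=toy_protomer.atoms, label="bare",
                                 sequence=toy_protomer.sequence)
        neigh = self._neigh_with_pairs(bare, [(1, 1)])
        with pytest.raises(ValueError):
            classify_interfaces(neigh)


class TestBaseLayerCount:
    def test_matches_brute_force_cover(self, ring_fixture):
        filament, _ = ring_fixture
        from filarch.lattice import _protomer_arc
        z = filament.axial_coords()
        extent = filament.protomer_axial_extent()
        cand = [i for i in range(len(filament)) if z[i] <= z.min() + extent]
        arcs = [_protomer_arc(filament[i], filament) for i in cand]

        def covers(subset):
            marks = np.zeros(3600, dtype=bool)
            for k in subset:
                s, w = arcs[k]
                idx = (np.arange(int(s * 10), int((s + w) * 10)) % 3600)
                marks[idx] = True
            return marks.all()

        brute = None
        for size in range(1, len(arcs) + 1):
            if any(covers(sub) for sub in itertools.combinations(range(len(arcs)), size)):
                brute = size
                break
        assert base_layer_count(filament) == brute

    def test_invariant_to_length_and_rigid_motion(self, ring_fixture):
        filament, _ = ring_fixture
        n0 = base_layer_count(filament)
        preset = LatticePreset("ring3", HelicalParams(40.0, 8.0, cn=3), "user")
        longer, _ = make_filament_fixture(preset, n=42)
        assert base_layer_count(longer) == n0
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        moved = filament.transformed(R, np.array([12.0, -30.0, 4.0]))
        assert base_layer_count(moved) == n0

    def test_too_short_rejected(self, toy_protomer):
        preset = HelicalParams(40.0, 8.0, cn=3)
        fil = build_filament(toy_protomer, preset, 6)
        with pytest.raises(ValueError, match="too short"):
            base_layer_count(fil)


def test_minimal_arc_cover_on_known_configuration():
    # three 150-degree arcs at 120-degree spacing: any two leave a gap
    arcs = [(0.0, 150.0), (120.0, 150.0), (240.0, 150.0)]
    assert len(minimal_arc_cover(arcs)) == 3
    # an arc union that cannot close the circle
    assert minimal_arc_cover([(0.0, 100.0), (180.0, 100.0)]) is None


class TestRimDiameters:
    def test_single_ring_of_point_atoms(self):
        r = 20.0
        atoms = []
        protos = []
        for k in range(8):
            ang = 2 * np.pi * k / 8
            pos = np.array([r * np.cos(ang), r * np.sin(ang), 0.1 * k])
            protos.append(ProtomerStructure(
                atoms=[AtomSite("C", "CA", 1, "ALA", "A", pos)], label=str(k)))
        fil = FilamentAssembly(protos, axis_origin=np.zeros(3),
                               axis_direction=np.array([0.0, 0.0, 1.0]))
        outer, inner = rim_diameters(fil)
        assert outer == pytest.approx(2 * r, abs=1e-6)
        assert inner == pytest.approx(2 * r, abs=1e-6)

    def test_rigid_motion_invariance_and_scaling(self, pyd_fixture):
        filament, _ = pyd_fixture
        outer, inner = rim_diameters(filament)
        rng = np.random.default_rng(9)
        R = random_rotation(rng)
        moved = filament.transformed(R, np.array([5.0, 6.0, -7.0]))
        o2, i2 = rim_diameters(moved)
        assert o2 == pytest.approx(outer, abs=1e-6)
        assert i2 == pytest.approx(inner, abs=1e-6)
        # uniform scaling scales both diameters linearly
        scaled_protos = []
        for p in filament.protomers:
            atoms = [AtomSite(a.element, a.name, a.residue_number, a.residue_name,
                              a.chain_id, a.position * 2.0) for a in p.atoms]
            scaled_protos.append(ProtomerStructure(atoms, p.label, p.sequence,
                                                   dict(p.ss_segments)))
        scaled = FilamentAssembly(scaled_protos,
                                  filament.axis_origin * 2.0,
                                  filament.axis_direction)
        o3, i3 = rim_diameters(scaled)
        assert o3 == pytest.approx(2 * outer, rel=1e-9)
        assert i3 == pytest.approx(2 * inner, rel=1e-9)


class TestAnnotateResidues:
    def test_matches_per_residue_distance_oracle(self, pyd_fixture):
        filament, _ = pyd_fixture
        residues = filament[0].residue_numbers
        ann = annotate_residues(filament, residues)
        # oracle: a residue is interfacial iff any of the center's atoms of
        # that residue sits within the cutoff of any shell-partner atom
        center_idx = len(filament) // 2
        center = filament[center_idx]
        partners = [filament[center_idx + d] for d in (-3, -2, -1, 1, 2, 3)]
        partner_coords = np.concatenate([p.coords() for p in partners])
        for r in residues:
            mine = np.array([a.position for a in center.heavy_atoms()
                             if a.residue_number == r])
            d = np.linalg.norm(mine[:, None] - partner_coords[None], axis=2)
            if (d < 4.5).any():
                assert ann[r], f"residue {r} should be interfacial"

    def test_non_interfacial_residue_maps_to_empty_set(self, pyd_fixture):
        filament, _ = pyd_fixture
        ann = annotate_residues(filament, filament[0].residue_numbers)
        buried = [r for r, types in ann.items() if not types]
        assert buried, "expected at least one non-interfacial residue"

    def test_unknown_residue_rejected(self, pyd_fixture):
        filament, _ = pyd_fixture
        with pytest.raises(KeyError):
            annotate_residues(filament, [9999])
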