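"""Threading, steric scoring, center swapping and monomer alignment."""

import numpy as np
import pytest

from conftest import random_rotation
from filarch.compat import (
    CLASH_THRESHOLD_A,
    InsufficientCorrespondenceError,
    align_monomers,
    compare_honeycombs,
    identity_mapping,
    score_shell,
    sequence_mapping,
    swap_center_analysis,
    thread_monomer,
)
from filarch.helical import HelicalParams
from filarch.lattice import CONTACT_CUTOFF_A, extract_honeycomb
from filarch.structures import AtomSite, FilamentAssembly, ProtomerStructure
from filarch.synthetic import (
    IFI16_PRESET,
    LatticePreset,
    ToyProtomerSpec,
    make_filament_fixture,
    make_toy_protomer,
)


@pytest.fixture(scope="module")
def self_threading(pyd_fixture, pyd_honeycomb):
    _, truth = pyd_fixture
    mapping = identity_mapping(truth.protomer)
    threaded = thread_monomer(truth.protomer, pyd_honeycomb, mapping)
    return truth.protomer, threaded, mapping


class TestThreadMonomer:
    def test_self_threading_zero_displacement(self, self_threading, pyd_honeycomb):
        monomer, threaded, _ = self_threading
        assert np.abs(threaded.coords()
                      - pyd_honeycomb.center.coords()).max() < 1e-6

    def test_low_coverage_rejected(self, pyd_honeycomb, toy_protomer):
        partial = [(r, r) for r in toy_protomer.residue_numbers[:30]]  # ~34%
        with pytest.raises(InsufficientCorrespondenceError):
            thread_monomer(toy_protomer, pyd_honeycomb, partial)

    def test_empty_mapping_rejected(self, pyd_honeycomb, toy_protomer):
        with pytest.raises(InsufficientCorrespondenceError):
            swap_center_analysis(toy_protomer, pyd_honeycomb, mapping=[])


class TestScoreShell:
    def test_native_center_is_clash_free(self, self_threading, pyd_honeycomb):
        _, threaded, mapping = self_threading
        rep = score_shell(threaded, pyd_honeycomb, "template", mapping)
        assert rep.total_clashes == 0
        assert all(v["clash_count"] == 0 for v in rep.per_interface.values())
        assert all(v["contact_count"] > 0 for v in rep.per_interface.values())

    def test_half_sums_partition_total_exactly(self, self_threading, pyd_honeycomb):
        _, threaded, mapping = self_threading
        rep = score_shell(threaded, pyd_honeycomb, "template", mapping)
        assert rep.half_sums["top"] + rep.half_sums["bottom"] == rep.total
        assert rep.total == sum(v["score"] for v in rep.per_interface.values())

    def test_clash_counts_match_brute_force(self, pyd_fixture, pyd_honeycomb):
        _, truth = pyd_fixture
        # a deliberately mis-twisted placement produces clashes to cross-check
        mistwisted, _ = make_filament_fixture(
            LatticePreset("m", HelicalParams(120.0, 5.6), "user"), n=30)
        neigh = extract_honeycomb(mistwisted, 15, classify=False)
        mapping = identity_mapping(truth.protomer)
        threaded = thread_monomer(truth.protomer, neigh, mapping)
        rep = score_shell(threaded, neigh, "template", mapping)
        tc = threaded.coords()
        for rec in neigh.shell:
            pc = rec.partner.coords()
            d = np.linalg.norm(tc[:, None] - pc[None], axis=2)
            key = f"offset{rec.partner_offset:+d}|{rec.half}"
            assert rep.per_interface[key]["clash_count"] == int(
                (d < CLASH_THRESHOLD_A).sum())
            assert rep.per_interface[key]["contact_count"] == int(
                ((d >= CLASH_THRESHOLD_A) & (d < CONTACT_CUTOFF_A)).sum())

    def test_invariant_to_global_rigid_motion(self, pyd_fixture):
        filament, truth = pyd_fixture
        mapping = identity_mapping(truth.protomer)
        rng = np.random.default_rng(17)
        R, t = random_rotation(rng), rng.uniform(-20, 20, 3)
        moved = filament.transformed(R, t)
        n1 = extract_honeycomb(filament, 15)
        n2 = extract_honeycomb(moved, 15)
        r1 = score_shell(thread_monomer(truth.protomer, n1, mapping), n1,
                         "template", mapping)
        r2 = score_shell(thread_monomer(truth.protomer, n2, mapping), n2,
                         "template", mapping)
        assert r1.total == r2.total
        assert r1.clashes_by_type() == r2.clashes_by_type()

    def test_clashes_grow_with_lattice_mismatch(self, pyd_fixture):
        """Threading into increasingly mis-twisted lattices degrades sterics."""
        _, truth = pyd_fixture
        mapping = identity_mapping(truth.protomer)
        clashes = []
        for dtwist in (0.0, 5.0, 10.0, 15.0, 20.0):
            preset = LatticePreset(
                "sweep", HelicalParams(134.6 + dtwist, 5.6), "user")
            fil, _ = make_filament_fixture(preset, n=30)
            neigh = extract_honeycomb(fil, 15, classify=False)
            threaded = thread_monomer(truth.protomer, neigh, mapping)
            rep = score_shell(threaded, neigh, "threaded", mapping)
            clashes.append(rep.total_clashes)
        assert clashes[0] == 0
        assert all(b > a for a, b in zip(clashes, clashes[1:]))

    def test_self_score_beats_cross_threaded(self, pyd_fixture):
        _, truth = pyd_fixture
        mapping = identity_mapping(truth.protomer)
        totals = {}
        for name, twist, rise in (("native", 134.6, 5.6), ("foreign", 150.0, 6.5)):
            preset = LatticePreset(name, HelicalParams(twist, rise), "user")
            fil, _ = make_filament_fixture(preset, n=30)
            neigh = extract_honeycomb(fil, 15, classify=False)
            threaded = thread_monomer(truth.protomer, neigh, mapping)
            totals[name] = score_shell(threaded, neigh, "threaded", mapping).total
        assert totals["native"] < totals["foreign"]


class TestSwapCenter:
    def test_native_center_scores_best(self, pyd_honeycomb, pyd_fixture):
        _, truth = pyd_fixture
        native = truth.protomer
        scores = {}
        scores["native"] = swap_center_analysis(
            native, pyd_honeycomb, identity_mapping(native)).total
        # homologs with a swollen envelope cannot sit in the native cavity
        for seed, scale in ((3, 1.15), (5, 1.25)):
            dims = tuple(d * scale for d in ToyProtomerSpec().bundle_dimensions)
            other = make_toy_protomer(ToyProtomerSpec(seed=seed,
                                                      bundle_dimensions=dims))
            rep = swap_center_analysis(other, pyd_honeycomb,
                                       identity_mapping(other))
            assert rep.total_clashes > 0
            scores[f"seed{seed}"] = rep.total
        assert scores["native"] == min(scores.values())


class TestCompareHoneycombs:
    def test_self_comparison_is_zero(self, pyd_honeycomb, pyd_fixture):
        _, truth = pyd_fixture
        df = compare_honeycombs(pyd_honeycomb, pyd_honeycomb,
                                identity_mapping(truth.protomer))
        assert len(df) == 6
        assert np.allclose(df["centroid_displacement_A"], 0, atol=1e-6)
        assert np.allclose(df["orientation_diff_deg"], 0, atol=1e-4)

    def test_different_lattice_shows_large_deviations(self, pyd_honeycomb,
                                                      pyd_fixture):
        _, truth = pyd_fixture
        foreign, _ = make_filament_fixture(
            LatticePreset("f", HelicalParams(110.0, 7.0), "user"), n=30)
        nf = extract_honeycomb(foreign, 15, classify=False)
        df = compare_honeycombs(pyd_honeycomb, nf, identity_mapping(truth.protomer))
        matched = df.dropna(subset=["centroid_displacement_A"])
        assert (matched["centroid_displacement_A"] > 3.0).any()


class TestAlignMonomers:
    def test_self_alignment_is_exact(self, toy_protomer):
        rmsd, _, frac = align_monomers(toy_protomer, toy_protomer,
                                       identity_mapping(toy_protomer))
        assert rmsd < 1e-6
        assert frac == 1.0

    def test_trim_discards_displaced_loop(self, toy_protomer):
        # displace one loop far from the core; trimming should recover a
        # small core RMSD and report the discarded fraction
        lo, hi = toy_protomer.ss_segments["loop_h2h3"]
        moved_atoms = []
        for a in toy_protomer.atoms:
            pos = a.position + (np.array([9.0, 0, 0]) if lo <= a.residue_number <= hi
                                else np.zeros(3))
            moved_atoms.append(AtomSite(a.element, a.name, a.residue_number,
                                        a.residue_name, a.chain_id, pos))
        moved = ProtomerStructure(moved_atoms, "moved", toy_protomer.sequence,
                                  dict(toy_protomer.ss_segments))
        mapping = identity_mapping(toy_protomer)
        rmsd_full, _, _ = align_monomers(toy_protomer, moved, mapping)
        rmsd_trim, _, frac = align_monomers(toy_protomer, moved, mapping, trim=True)
        assert rmsd_trim < 0.1 < rmsd_full
        assert frac < 1.0

    def test_too_few_pairs_rejected(self, toy_protomer):
        with pytest.raises(InsufficientCorrespondenceError):
            align_monomers(toy_protomer, toy_protomer,
                           identity_mapping(toy_protomer)[:10])

    def test_sequence_mapping_of_homologs_is_identity(self):
        a = make_toy_protomer(ToyProtomerSpec(seed=1))
        b = make_toy_protomer(ToyProtomerSpec(seed=2))
        pairs = sequence_mapping(a, b)
        assert pairs == [(r, r) for r in a.residue_numbers]
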