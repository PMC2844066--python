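"""Shrake–Rupley SASA and radial exposure classification."""

import math

import numpy as np
import pytest

import biotite.structure as struc

from mtepitope.exposure import (
    ExposureThresholds,
    SasaParameters,
    classify_residue,
    compute_sasa,
    epitope_exposure,
    exposure_table,
    mean_wall_radius,
    reference_sasa,
    residue_sasa,
    screen_residue_type,
    sphere_points,
    _verdict,
)
from mtepitope.lattice import LatticeParameters, build_lattice, build_protofilament, orient_dimer
from mtepitope.sequences import ProteinSequence, SequenceRegion
from mtepitope.synthetic import make_coarse_dimer


def _atoms(coords, element="C", res_ids=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.asarray(res_ids) if res_ids is not None else np.arange(1, n + 1)
    arr.res_name = np.full(n, "GLY")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, element)
    return arr


def _two_sphere_analytic(r1, r2, d):
    """Accessible area of two intersecting spheres (radii include probe)."""
    if d >= r1 + r2:
        return 4 * math.pi * (r1 ** 2 + r2 ** 2)
    area = 0.0
    for ra, rb in ((r1, r2), (r2, r1)):
        # spherical cap removed from sphere a by sphere b
        h = ra - (d ** 2 + ra ** 2 - rb ** 2) / (2 * d)
        area += 4 * math.pi * ra ** 2 - 2 * math.pi * ra * h
    return area


class TestSasa:
    def test_isolated_atom_closed_form(self):
        params = SasaParameters()
        area = compute_sasa(_atoms([[0, 0, 0]]), params)[0]
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=1e-12)

    def test_enclosed_atom_zero(self):
        # surround one atom with a tight shell of neighbors
        shell = 3.1 * sphere_points(60)
        atoms = _atoms(np.vstack([[0, 0, 0], shell]))
        area = compute_sasa(atoms)[0]
        assert area == 0.0

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_analytic_within_2_percent(self, d):
        params = SasaParameters(n_points=960)
        atoms = _atoms([[0, 0, 0], [d, 0, 0]])
        areas = compute_sasa(atoms, params)
        expected = _two_sphere_analytic(3.1, 3.1, d)
        assert areas.sum() == pytest.approx(expected, rel=0.02)

    def test_sampling_convergence(self):
        atoms = _atoms([[0, 0, 0], [2.8, 0, 0]])
        expected = _two_sphere_analytic(3.1, 3.1, 2.8)
        errors = []
        for n in (96, 3840):
            areas = compute_sasa(atoms, SasaParameters(n_points=n))
            errors.append(abs(areas.sum() - expected) / expected)
        assert errors[-1] < errors[0]

    def test_agrees_with_biotite(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-6, 6, size=(25, 3))
        atoms = _atoms(coords)
        mine = compute_sasa(atoms, SasaParameters(n_points=1000))
        theirs = struc.sasa(atoms, probe_radius=1.4, point_number=1000,
                            vdw_radii="Single")
        assert np.abs(mine - theirs).sum() / theirs.sum() < 0.03

    def test_subset_restriction(self):
        atoms = _atoms([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        mask = np.array([False, True, False])
        areas = compute_sasa(atoms, subset=mask)
        assert np.isnan(areas[0]) and np.isnan(areas[2])
        full = compute_sasa(atoms)
        assert areas[1] == pytest.approx(full[1])

    def test_unknown_element_rejected(self):
        atoms = _atoms([[0, 0, 0]], element="Zz")
        with pytest.raises(ValueError, match="radius"):
            compute_sasa(atoms)

    def test_residue_aggregation(self):
        atoms = _atoms([[0, 0, 0], [20, 0, 0], [40, 0, 0]], res_ids=[1, 1, 2])
        per_res = residue_sasa(atoms, compute_sasa(atoms))
        lone = 4 * math.pi * 3.1 ** 2
        assert per_res[(0, 0, "A", 1)] == pytest.approx(2 * lone, rel=1e-9)
        assert per_res[(0, 0, "A", 2)] == pytest.approx(lone, rel=1e-9)

    def test_coarse_reference_is_isolated_sphere(self):
        atoms = _atoms([[0, 0, 0]], element="X")
        ref = reference_sasa(atoms, SasaParameters())
        assert ref == pytest.approx(4 * math.pi * 4.4 ** 2)

    def test_gxg_reference_for_all_atom(self):
        atoms = _atoms([[0, 0, 0], [1.5, 0, 0]])
        assert reference_sasa(atoms, SasaParameters()) == 104.0  # GLY


class TestClassification:
    def test_buried_regardless_of_radius(self):
        assert classify_residue(0.0, 200.0, 110.0) == "buried"
        assert classify_residue(0.05, 50.0, 110.0) == "buried"

    def test_radial_classes(self):
        t = ExposureThresholds()
        assert classify_residue(0.8, 130.0, 110.0, t) == "outer"
        assert classify_residue(0.8, 90.0, 110.0, t) == "lumen"
        assert classify_residue(0.8, 112.0, 110.0, t) == "lateral"

    def test_partition_exhaustive_and_monotone_in_delta(self):
        r_mid = 110.0
        for rel in (0.05, 0.5, 1.0):
            for r in np.linspace(80, 140, 61):
                classes = []
                for delta in np.linspace(0.5, 25, 50):
                    t = ExposureThresholds(delta=delta)
                    classes.append(classify_residue(rel, float(r), r_mid, t))
                assert all(c in ("outer", "lumen", "lateral", "buried")
                           for c in classes)
                # growing delta converts outer/lumen to lateral, never
                # outer directly to lumen
                for a, b in zip(classes, classes[1:]):
                    assert (a, b) not in (("outer", "lumen"), ("lumen", "outer"))

    def test_verdict_majority_and_ties(self):
        from mtepitope.exposure import ResidueExposure

        def res(klass):
            return ResidueExposure(0, 0, "B", 1, "GLY", 10.0, 0.5, 100.0, klass)

        counts, verdict = _verdict([res("outer")] * 3 + [res("buried")] * 2)
        assert verdict == "outer" and counts["buried"] == 2
        _, verdict = _verdict([res("outer"), res("lumen")])
        assert verdict == "mixed"
        _, verdict = _verdict([res("buried")])
        assert verdict == "buried"


@pytest.fixture(scope="module")
def planted_lattice():
    planted = {("beta", r): "outer" for r in range(61, 71)}
    planted.update({("beta", r): "lumen" for r in range(5, 15)})
    planted.update({("beta", r): "outer" for r in (40, 42, 44)})
    planted.update({("beta", r): "lumen" for r in (81, 83)})
    dimer, truth = make_coarse_dimer(100, planted=planted, seed=12)
    oriented, _ = orient_dimer(dimer)
    params = LatticeParameters()
    lattice = build_lattice(build_protofilament(oriented, 3), params)
    return lattice, truth


class TestEpitopeExposure:
    def test_planted_outer_epitope(self, planted_lattice):
        lattice, _ = planted_lattice
        report = epitope_exposure(lattice, SequenceRegion(61, 70))
        assert report.verdict == "outer"
        assert report.counts["outer"] == 10
        assert not report.partial

    def test_planted_lumen_epitope(self, planted_lattice):
        lattice, _ = planted_lattice
        report = epitope_exposure(lattice, SequenceRegion(5, 14))
        assert report.verdict == "lumen"
        assert report.counts["lumen"] == 10

    def test_planted_radial_margin(self, planted_lattice):
        """Planted residues sit well beyond the ±δ band around the wall."""
        lattice, truth = planted_lattice
        r_mid = mean_wall_radius(lattice)
        report = epitope_exposure(lattice, SequenceRegion(61, 70))
        for e in report.residues:
            assert e.radius > r_mid + 10.0
        report = epitope_exposure(lattice, SequenceRegion(5, 14))
        for e in report.residues:
            assert e.radius < r_mid - 10.0

    def test_lattice_burial_never_exceeds_isolated(self, planted_lattice):
        """Assembly can only bury residues relative to the free dimer."""
        lattice, _ = planted_lattice
        res_ids = list(range(1, 101))
        realized = lattice.realize()
        from mtepitope.exposure import interior_copy

        copy = interior_copy(lattice)
        chain = lattice.dimer.beta_chain
        mask = ((realized.copy_pf == copy.protofilament)
                & (realized.copy_dimer == copy.dimer)
                & (realized.chain_id == chain))
        in_lattice = residue_sasa(realized, compute_sasa(realized, subset=mask))
        # isolated dimer in the same frame, so the test-point directions
        # relative to the molecule are identical and burial is exact
        copy_mask = ((realized.copy_pf == copy.protofilament)
                     & (realized.copy_dimer == copy.dimer))
        solo = realized[copy_mask]
        solo_mask = solo.chain_id == chain
        isolated = residue_sasa(solo, compute_sasa(solo, subset=solo_mask))
        for rid in res_ids:
            a = in_lattice[(copy.protofilament, copy.dimer, chain, rid)]
            b = isolated[(copy.protofilament, copy.dimer, chain, rid)]
            assert a <= b + 1e-6

    def test_exposure_table_format(self, planted_lattice):
        lattice, _ = planted_lattice
        report = epitope_exposure(lattice, SequenceRegion(61, 70))
        table = exposure_table(report)
        lines = table.strip().splitlines()
        assert lines[0].startswith("chain\tres_id")
        assert len(lines) == 11


class TestResidueTypeScreen:
    def test_planted_tyrosines(self):
        beta = ProteinSequence(
            "b", "".join("Y" if i + 1 in (10, 20, 30, 50, 60) else "A"
                         for i in range(100)))
        planted = {("beta", 10): "outer", ("beta", 20): "outer",
                   ("beta", 30): "outer", ("beta", 50): "lumen",
                   ("beta", 60): "lumen"}
        dimer, _ = make_coarse_dimer(100, planted=planted, seed=3, beta_seq=beta)
        oriented, _ = orient_dimer(dimer)
        lattice = build_lattice(build_protofilament(oriented, 3),
                                LatticeParameters())
        report = screen_residue_type(lattice, beta, "Y")
        outer = sorted(e.res_id for e in report.residues if e.klass == "outer")
        assert outer == [10, 20, 30]
        lumen = sorted(e.res_id for e in report.residues if e.klass == "lumen")
        assert lumen == [50, 60]

    def test_no_tyrosines_empty_report(self, planted_lattice):
        lattice, _ = planted_lattice
        parent = ProteinSequence("p", "A" * 100)
        report = screen_residue_type(lattice, parent, "Y")
        assert report.residues == []

    def test_unresolved_tail_inherits_anchor_class(self):
        # parent longer than the structured monomer: C-terminal tyrosines
        # have no coordinates and inherit the last resolved residue's class
        beta = ProteinSequence(
            "b", "".join("Y" if i + 1 in (95, 105, 110) else "A"
                         for i in range(110)))
        planted = {("beta", 95): "outer"}
        dimer, _ = make_coarse_dimer(100, planted=planted, seed=4, beta_seq=beta)
        oriented, _ = orient_dimer(dimer)
        lattice = build_lattice(build_protofilament(oriented, 3),
                                LatticeParameters())
        report = screen_residue_type(lattice, beta, "Y")
        assert report.partial
        by_id = {e.res_id: e for e in report.residues}
        assert by_id[95].klass == "outer" and by_id[95].flags == ""
        for rid in (105, 110):
            assert by_id[rid].flags == "tail-inferred"
            assert by_id[rid].klass == "outer"

    def test_partial_epitope_report_flagged(self):
        dimer, _ = make_coarse_dimer(100, planted={("beta", 98): "outer"},
                                     seed=5)
        oriented, _ = orient_dimer(dimer)
        lattice = build_lattice(build_protofilament(oriented, 3),
                                LatticeParameters())
        report = epitope_exposure(lattice, SequenceRegion(96, 105))
        assert report.partial
        inferred = [e for e in report.residues if e.flags == "tail-inferred"]
        assert {e.res_id for e in inferred} == set(range(101, 106))
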