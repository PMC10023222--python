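"""Binding-site definition, degree of buriedness, and categorization."""

import numpy as np
import pytest

from enzymespace.binding_site import (
    SCAN_DIRECTIONS,
    BindingSite,
    CategoryParams,
    DOBGridParams,
    categorize_site,
    degree_of_buriedness,
    map_site_to_template,
    site_from_ligand,
)
from enzymespace.structure import Atom, Residue
from enzymespace.synth import make_pocket_model, make_template_assembly, _pseudo_chain, _lattice_box
from enzymespace.structure import StructureModel

from oracles import ray_march_dob


def _ligand(coord, number=900):
    return Residue(name="LIG", number=number, chain_id="L", hetero=True,
                   atoms=[Atom("C1", "C", np.asarray(coord, float))], score=0.0)


class TestSiteFromLigand:
    def test_single_nearby_residue(self):
        chain = _pseudo_chain(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        model = StructureModel(chains=[chain])
        lig = _ligand([3.0, 0, 0])
        model.ligands.append(lig)
        site = site_from_ligand(model, lig)
        assert site.residues == (("A", 1),)
        assert site.provenance == "ligand-proximity"

    def test_detached_ligand_is_an_error(self):
        chain = _pseudo_chain(np.array([[0.0, 0, 0]]))
        model = StructureModel(chains=[chain])
        lig = _ligand([20.0, 0, 0])
        with pytest.raises(ValueError, match="cutoff"):
            site_from_ligand(model, lig, cutoff=4.5)

    def test_pocket_lining_residues_match_brute_force(self, pocket_fixtures):
        model, lig, site = pocket_fixtures["cleft"]
        lig_pts = lig.heavy_coords()
        expected = []
        for res in model.residues():
            d = min(np.linalg.norm(p - q) for p in res.heavy_coords() for q in lig_pts)
            if d <= 4.6:
                expected.append((res.chain_id, res.number))
        assert sorted(site.residues) == sorted(expected)


class TestDegreeOfBuriedness:
    def test_enclosed_probe_point_scores_seven(self):
        # a single solvent point inside a closed atom shell
        shell = 4.0 * _fibonacci(150)
        model = StructureModel(chains=[_pseudo_chain(shell)])
        counts = ray_march_dob(np.zeros(3), SCAN_DIRECTIONS, shell, np.full(len(shell), 1.7))
        assert counts == 7

    def test_isolated_point_scores_zero(self):
        pts = np.array([[100.0, 100.0, 100.0]])
        dob = ray_march_dob(np.array([70.0, 70.0, 70.0]), SCAN_DIRECTIONS, pts, np.array([1.7]))
        assert dob == 0

    def test_grid_scan_matches_ray_march_oracle_on_small_cleft(self):
        # small slab with a notch; every evaluated point re-derived scalar-wise
        pts = _lattice_box(np.array([-4.0, -4.0, -3.0]), np.array([4.0, 4.0, 0.0]), 1.6)
        pts = pts[np.linalg.norm(pts - np.array([0, 0, 0.5]), axis=1) > 2.6]
        model = StructureModel(chains=[_pseudo_chain(pts)])
        lig = _ligand([0.0, 0.0, -0.5])
        model.ligands.append(lig)
        site = site_from_ligand(model, lig, cutoff=4.0)
        params = DOBGridParams(margin=3.0)
        mean, grid = degree_of_buriedness(model, site, params)
        radii = np.full(len(pts), 1.7)
        oracle = np.array(
            [ray_march_dob(p, SCAN_DIRECTIONS, pts, radii, params.scan_range) for p in grid.points]
        )
        assert np.array_equal(grid.dob, oracle)
        pocket = oracle[oracle >= 1]
        expected_mean = float(pocket.mean()) if len(pocket) else 0.0
        assert mean == pytest.approx(expected_mean)

    def test_adding_atoms_never_lowers_dob(self):
        pts = _lattice_box(np.array([-3.0, -3.0, -2.0]), np.array([3.0, 3.0, 0.0]), 1.6)
        model = StructureModel(chains=[_pseudo_chain(pts)])
        lig = _ligand([0.0, 0.0, 2.0])
        model.ligands.append(lig)
        site = site_from_ligand(model, lig, cutoff=4.0)
        params = DOBGridParams(margin=3.0)
        _, before = degree_of_buriedness(model, site, params)
        # add a roof of atoms above
        roof = _lattice_box(np.array([-3.0, -3.0, 5.0]), np.array([3.0, 3.0, 6.0]), 1.6)
        model2 = StructureModel(chains=[_pseudo_chain(np.vstack([pts, roof]))])
        model2.ligands.append(lig)
        site2 = BindingSite(residues=tuple((("A", n)) for _, n in site.residues))
        _, after = degree_of_buriedness(model2, site2, params)
        common = min(len(before.points), len(after.points))
        # same grid frame: identical candidate points
        assert np.allclose(before.points, after.points[: len(before.points)])
        assert (after.dob[: len(before.dob)] >= before.dob).all()

    def test_degenerate_grid_is_an_error(self):
        # site packed solid: no solvent points within margin
        pts = _lattice_box(np.array([-6.0] * 3), np.array([6.0] * 3), 1.2)
        model = StructureModel(chains=[_pseudo_chain(pts)])
        site = BindingSite(residues=(("A", 1 + len(pts) // 2),))
        with pytest.raises(ValueError, match="solvent"):
            degree_of_buriedness(model, site, DOBGridParams(margin=1.5))


class TestTemplateMapping:
    def test_partner_chain_near_site_flags_noncomplete(self, pocket_fixtures):
        model, _, site = pocket_fixtures["flat"]
        assembly = make_template_assembly(model, site, with_partner=True)
        mapped, flag = map_site_to_template(site, assembly)
        assert flag is True
        assert len(mapped) == len(site.residues)

    def test_single_chain_template_is_complete(self, pocket_fixtures):
        model, _, site = pocket_fixtures["flat"]
        assembly = make_template_assembly(model, site, with_partner=False)
        _, flag = map_site_to_template(site, assembly)
        assert flag is False

    def test_unaligned_site_is_an_error(self, pocket_fixtures):
        model, _, site = pocket_fixtures["flat"]
        assembly = make_template_assembly(model, site, with_partner=False)
        assembly.alignment = {}
        with pytest.raises(ValueError, match="alignment"):
            map_site_to_template(site, assembly)

    def test_partner_distance_matches_brute_force(self, pocket_fixtures):
        model, _, site = pocket_fixtures["flat"]
        assembly = make_template_assembly(model, site, with_partner=True)
        site_pts = np.vstack([r.coords() for r in site.residue_objects(model)])
        partner_pts = np.vstack([r.coords() for r in assembly.structure.chain("B").residues])
        min_d = min(np.linalg.norm(a - b) for a in site_pts for b in partner_pts)
        _, flag = map_site_to_template(site, assembly)
        assert flag == (min_d <= 5.0)


class TestCategorization:
    @pytest.mark.parametrize(
        "dob, flag, expected",
        [
            (6.5, True, "buried"),
            (6.5, False, "buried"),
            (4.0, False, "buried"),
            (2.0, True, "surface_noncomplete"),
            (2.0, False, "surface"),
            (0.0, False, "surface"),
        ],
    )
    def test_threshold_rule(self, dob, flag, expected):
        assert categorize_site(dob, flag) == expected

    def test_swap_flag_inverts_surface_subcategories(self):
        params = CategoryParams(swap_noncomplete=True)
        assert categorize_site(2.0, True, params) == "surface"
        assert categorize_site(2.0, False, params) == "surface_noncomplete"

    def test_out_of_range_dob_rejected(self):
        with pytest.raises(ValueError):
            categorize_site(7.5, False)

    def test_three_pocket_fixtures_map_to_three_categories(self, pocket_fixtures):
        got = {}
        for mode, (model, _, site) in pocket_fixtures.items():
            mean, _ = degree_of_buriedness(model, site)
            assembly = make_template_assembly(model, site, with_partner=(mode == "flat"))
            _, flag = map_site_to_template(site, assembly)
            got[mode] = categorize_site(mean, flag)
        assert got == {"enclosed": "buried", "cleft": "surface", "flat": "surface_noncomplete"}


def _fibonacci(n):
    import math

    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * k
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))
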