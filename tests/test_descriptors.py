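import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from enantiokit import (
    SterimolSpec,
    Structure,
    VburSpec,
    build_reaction_representation,
    buried_volume,
    featurize_structure,
    hardness,
    make_default_catalogue,
    sasa,
    sterimol,
)
from enantiokit.descriptors import (
    DescriptorCatalogue,
    DescriptorDef,
    angle,
    dihedral,
    distance,
    geometry_params,
    load_catalogue,
    vdw_radius,
)


class TestGeometry:
    def test_distance_three_four_five(self):
        s = Structure(["C", "C"], [[0, 0, 0], [3, 4, 0]])
        assert distance(s, 0, 1) == pytest.approx(5.0)

    def test_colinear_angle_is_180(self):
        s = Structure(["C", "C", "C"], [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert angle(s, 0, 1, 2) == pytest.approx(180.0)

    def test_planar_trans_dihedral_is_180(self):
        s = Structure(
            ["C", "C", "C", "C"], [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        )
        assert dihedral(s, 0, 1, 2, 3) == pytest.approx(180.0)

    def test_dihedral_sign_right_handed(self):
        plus = Structure(
            ["C", "C", "C", "C"], [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 1]]
        )
        minus = Structure(
            ["C", "C", "C", "C"], [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, -1]]
        )
        assert dihedral(plus, 0, 1, 2, 3) == pytest.approx(-dihedral(minus, 0, 1, 2, 3))

    def test_colinear_dihedral_raises_naming_definition(self):
        s = Structure(["C"] * 4, [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        d = DescriptorDef("tors_bad", "dihedral", (0, 1, 2, 3))
        with pytest.raises(ValueError, match="tors_bad"):
            geometry_params(s, [d])

    def test_out_of_range_index_names_definition(self):
        s = Structure(["C", "C"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IndexError, match="d_far"):
            geometry_params(s, [DescriptorDef("d_far", "distance", (0, 9))])


class TestBuriedVolume:
    def test_empty_occupancy_is_zero(self):
        s = Structure(["C"], [[0.0, 0.0, 0.0]])
        assert buried_volume(s, VburSpec(0, radius=2.0)) == 0.0

    def test_concentric_sphere_volume_ratio(self):
        # one atom at the center with scaled radius 1.0 inside a 2.0 Å sphere
        # occupies (1/2)^3 = 12.5% of it
        s = Structure(["C", "H"], [[0, 0, 0], [0, 0, 0]])
        spec = VburSpec(0, radius=2.0, scale=1.0 / vdw_radius("H"), grid_spacing=0.04)
        assert buried_volume(s, spec) == pytest.approx(12.5, abs=0.15)

    def test_rigid_motion_invariance(self, template):
        spec = VburSpec(0, radius=3.5, grid_spacing=0.1)
        v0 = buried_volume(template, spec)
        rot = Rotation.from_euler("xyz", [30, 60, -45], degrees=True)
        moved = Structure(
            list(template.elements), rot.apply(template.coords) + np.array([5.0, -1.0, 2.0])
        )
        assert buried_volume(moved, spec) == pytest.approx(v0, abs=0.3)

    def test_monotone_in_atom_radius(self):
        s = Structure(["C", "O"], [[0, 0, 0], [1.2, 0, 0]])
        lo = buried_volume(s, VburSpec(0, radius=3.0, scale=1.0, grid_spacing=0.05))
        hi = buried_volume(s, VburSpec(0, radius=3.0, scale=1.3, grid_spacing=0.05))
        assert hi > lo

    def test_matches_monte_carlo_oracle(self):
        # off-center atom: grid integration vs independent MC integration
        s = Structure(["C", "H"], [[0, 0, 0], [1.0, 0, 0]])
        scale = 1.5 / vdw_radius("H")
        spec = VburSpec(0, radius=2.0, scale=scale, grid_spacing=0.05)
        got = buried_volume(s, spec)
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(10**6, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= (rng.uniform(size=10**6) ** (1 / 3))[:, None] * 2.0
        inside = ((pts - np.array([1.0, 0, 0])) ** 2).sum(axis=1) <= 1.5**2
        assert got == pytest.approx(100 * inside.mean(), abs=0.5)


class TestSterimol:
    def test_single_substituent_convention(self):
        # one atom 1.5 Å along the axis with r_vdW 1.2 (H): L=2.7, B1=B5=1.2
        s = Structure(["C", "H"], [[0, 0, 0], [0, 0, 1.5]])
        L, B1, B5 = sterimol(s, SterimolSpec(0, 1))
        assert L == pytest.approx(1.5 + 1.2, abs=1e-6)
        assert B1 == pytest.approx(1.2, abs=1e-6)
        assert B5 == pytest.approx(1.2, abs=1e-6)

    def test_cutoff_leaves_nothing(self):
        s = Structure(["C", "H"], [[0, 0, 0], [0, 0, 5.0]])
        with pytest.raises(ValueError, match="no substituent"):
            sterimol(s, SterimolSpec(0, 1, cutoff=4.5))

    def test_b1_not_larger_than_b5_and_rigid_invariance(self, template):
        spec = SterimolSpec(0, 1)
        L0, B10, B50 = sterimol(template, spec)
        assert B10 <= B50 + 1e-12
        rot = Rotation.from_euler("zxz", [17, 33, 121], degrees=True)
        moved = Structure(
            list(template.elements), rot.apply(template.coords) + np.array([1, 2, 3])
        )
        L1, B11, B51 = sterimol(moved, spec)
        assert (L1, B11, B51) == pytest.approx((L0, B10, B50), abs=1e-6)

    def test_matches_fine_rotational_scan_oracle(self):
        # 3-atom substituent: B1/B5 against an independent 0.1° brute scan
        s = Structure(
            ["C", "C", "H", "O"],
            [[0, 0, 0], [0, 0, 1.4], [0.9, 0.2, 1.8], [-0.5, 0.8, 2.2]],
        )
        spec = SterimolSpec(0, 1)
        L, B1, B5 = sterimol(s, spec)
        base = s.coords[0]
        axis = np.array([0.0, 0.0, 1.0])
        idx = [1, 2, 3]
        pos = s.coords[idx] - base
        radii = np.array([vdw_radius(s.elements[i]) for i in idx])
        vperp = pos[:, :2]  # axis is z
        thetas = np.radians(np.arange(0, 360, 0.1))
        dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        widths = (vperp @ dirs.T + radii[:, None]).max(axis=0)
        assert B1 == pytest.approx(widths.min(), abs=1e-3)
        assert B5 == pytest.approx((np.linalg.norm(vperp, axis=1) + radii).max(), abs=1e-9)


class TestSasa:
    def test_isolated_sphere_area(self):
        s = Structure(["S"], [[0.0, 0.0, 0.0]])  # Bondi r = 1.80... use explicit radius atom
        total, per_atom = sasa(s, probe_radius=1.4)
        r = vdw_radius("S") + 1.4
        assert total == pytest.approx(4 * math.pi * r**2, rel=1e-9)

    def test_known_numeric_value_for_r15(self):
        # r_vdW 1.5 (P is 1.80; use scaled probe to hit 2.9 total radius):
        # any isolated atom with r_vdW + probe = 2.9 has area 4π(2.9)² = 105.68
        s = Structure(["H"], [[0.0, 0.0, 0.0]])  # r 1.2, probe 1.7 -> 2.9
        total, _ = sasa(s, probe_radius=1.7)
        assert round(total, 2) == round(4 * math.pi * 2.9**2, 2) == 105.68

    def test_far_separated_atoms_add(self):
        s = Structure(["C", "O"], [[0, 0, 0], [50.0, 0, 0]])
        total, per_atom = sasa(s, 1.4)
        iso = sum(4 * math.pi * (vdw_radius(e) + 1.4) ** 2 for e in ("C", "O"))
        assert total == pytest.approx(iso, rel=1e-9)
        assert per_atom[0] > 0 and per_atom[1] > 0

    def test_overlapping_pair_matches_monte_carlo(self):
        s = Structure(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        total, _ = sasa(s, 1.4, n_points=2000)
        rng = np.random.default_rng(1)
        r = vdw_radius("C") + 1.4
        mc_total = 0.0
        for center in s.coords:
            pts = rng.normal(size=(10**5, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = center + r * pts
            other = s.coords[1] if center[0] == 0 else s.coords[0]
            free = ((pts - other) ** 2).sum(axis=1) > r**2
            mc_total += free.mean() * 4 * math.pi * r**2
        assert total == pytest.approx(mc_total, rel=0.01)


class TestHardness:
    @pytest.mark.parametrize(
        "homo, lumo, eta", [(-10, -2, 8), (-5, -5, 0), (-0.30, -0.05, 0.25)]
    )
    def test_orbital_gap(self, homo, lumo, eta):
        assert hardness(homo, lumo) == pytest.approx(eta)


class TestCatalogue:
    def test_default_counts(self):
        cat = make_default_catalogue()
        assert len(cat.steric_geometric_defs) == 114
        assert len(cat.electronic_defs) == 75

    def test_default_count_validation(self):
        with pytest.raises(ValueError, match="114"):
            DescriptorCatalogue(
                [DescriptorDef("d", "distance", (0, 1))], [], is_default=True
            )

    def test_yaml_round_trip_with_one_based_atoms(self, tmp_path):
        p = tmp_path / "cat.yaml"
        p.write_text(
            "descriptors:\n"
            "  - {name: d12, kind: distance, atoms: [1, 2]}\n"
            "  - {name: vb, kind: vbur, atoms: [1], radius: 2.0}\n"
            "  - {name: homo, kind: scalar_passthrough, source: eps_homo}\n"
        )
        cat = load_catalogue(p)
        assert cat.steric_geometric_defs[0].atoms == (0, 1)  # converted to 0-based
        assert cat.steric_geometric_defs[1].radius == 2.0
        assert len(cat.electronic_defs) == 1


@pytest.fixture(scope="module")
def coarse_catalogue():
    return make_default_catalogue(grid_spacing=0.2)


@pytest.fixture(scope="module")
def module_ensemble():
    from enantiokit import SyntheticSpec, gen_conformer_ensemble, make_template_structure

    spec = SyntheticSpec(n_conformers=4, jitter_sd=0.03, seed=5)
    return gen_conformer_ensemble(make_template_structure(), spec)


class TestFeaturize:
    def test_weighted_aggregation_statistics(self):
        # two conformers with descriptor values 1 and 3 at weights 1/4 and 3/4
        from enantiokit.selectivity import R_KCAL

        d = Structure(["C", "C"], [[0, 0, 0], [1.0, 0, 0]], id="a")
        e = Structure(["C", "C"], [[0, 0, 0], [3.0, 0, 0]], id="b")
        gap = -R_KCAL * 298.15 * math.log(3.0)  # makes w = [1/4, 3/4]
        from enantiokit import ConformerEnsemble

        ens = ConformerEnsemble([d, e], np.array([0.0, gap]))
        cat = DescriptorCatalogue([DescriptorDef("d12", "distance", (0, 1))], [])
        feats = featurize_structure(ens, cat, 298.15, window=50.0)
        stats = feats.values["d12"]
        assert stats["min"] == 1.0 and stats["max"] == 3.0
        assert stats["boltz"] == pytest.approx(2.5, abs=1e-9)
        assert stats["lowE"] == 3.0  # conformer b has the lower energy

    def test_single_conformer_degenerate_statistics(self, module_ensemble, coarse_catalogue):
        one = module_ensemble.subset([0])
        feats = featurize_structure(one, coarse_catalogue)
        for stats in feats.values.values():
            assert stats["min"] == stats["max"] == stats["boltz"] == stats["lowE"]

    def test_default_catalogue_yields_756_values(self, module_ensemble, coarse_catalogue):
        feats = featurize_structure(module_ensemble, coarse_catalogue)
        assert len(feats.as_series()) == 756

    def test_min_boltz_max_ordering_and_low_temperature_limit(
        self, module_ensemble, coarse_catalogue
    ):
        feats = featurize_structure(module_ensemble, coarse_catalogue)
        for stats in feats.values.values():
            assert stats["min"] - 1e-9 <= stats["boltz"] <= stats["max"] + 1e-9
            assert stats["min"] - 1e-9 <= stats["lowE"] <= stats["max"] + 1e-9
        cold = featurize_structure(module_ensemble, coarse_catalogue, temperature=0.5)
        for stats in cold.values.values():
            assert stats["boltz"] == pytest.approx(stats["lowE"], abs=1e-6)

    def test_invariant_to_conformer_order(self, module_ensemble, coarse_catalogue):
        a = featurize_structure(module_ensemble, coarse_catalogue)
        shuffled = module_ensemble.subset([2, 0, 3, 1])
        b = featurize_structure(shuffled, coarse_catalogue)
        for name in a.values:
            for agg in ("min", "max", "boltz", "lowE"):
                assert a.values[name][agg] == pytest.approx(b.values[name][agg], abs=1e-9)

    def test_missing_property_column_reported(self, module_ensemble):
        cat = DescriptorCatalogue(
            [], [DescriptorDef("mystery", "scalar_passthrough", source="nope")]
        )
        with pytest.raises(KeyError, match="nope"):
            featurize_structure(module_ensemble, cat)


@pytest.fixture(scope="module")
def stage_features(module_ensemble, coarse_catalogue):
    feats = featurize_structure(module_ensemble, coarse_catalogue)
    return {s: feats for s in ("TSRC", "Int", "TSRE")}


class TestRepresentation:
    def test_compact_three_stage_width_1251(self, stage_features):
        rep = build_reaction_representation(stage_features, "compact", ["TSRC", "Int", "TSRE"])
        assert len(rep) == 1251

    def test_full_single_stage_width_756(self, stage_features):
        rep = build_reaction_representation(
            {"TSRC": stage_features["TSRC"]}, "full", ["TSRC"]
        )
        assert len(rep) == 756

    def test_compact_single_stage_width_417(self, stage_features):
        rep = build_reaction_representation(
            {"Int": stage_features["Int"]}, "compact", ["Int"]
        )
        assert len(rep) == 417

    def test_missing_stage_listed(self, stage_features):
        with pytest.raises(ValueError, match="TSRE"):
            build_reaction_representation(
                {"TSRC": stage_features["TSRC"]}, "compact", ["TSRC", "TSRE"]
            )
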