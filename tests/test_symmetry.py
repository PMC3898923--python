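"""Symmetry operators, expansion rules and display filtering."""

import math

import numpy as np
import pytest

from emva.fixtures import make_toy_pentamer
from emva.map_io import DensityMap
from emva.model_tools import SimplifiedEntry, SimplifiedModel
from emva.symmetry import (
    OperatorError,
    PLANE_GROUPS,
    SymmetryOperator,
    apply_operator,
    expand_2d_crystal,
    expand_helical,
    expand_virus,
    filter_instances,
    parse_biomt,
    read_operators_json,
    rotation_about_axis,
    translate_to_cell,
    write_operators_json,
)


def single_atom_model(position):
    return SimplifiedModel([SimplifiedEntry("1", "A", 1, "ALA", position)])


def random_model(rng, n=8):
    return SimplifiedModel(
        [SimplifiedEntry("1", "A", i + 1, "ALA", p) for i, p in enumerate(rng.normal(size=(n, 3)) * 5)]
    )


def random_operator(rng):
    axis = rng.normal(size=3)
    angle = rng.uniform(0, 360)
    return SymmetryOperator(rotation_about_axis(axis, angle), rng.normal(size=3) * 10)


class TestApplyOperator:
    def test_identity(self, rng):
        model = random_model(rng)
        out = apply_operator(model, SymmetryOperator.identity())
        np.testing.assert_allclose(out.positions(), model.positions())

    def test_90_degrees_about_z(self):
        op = SymmetryOperator(rotation_about_axis((0, 0, 1), 90.0))
        out = apply_operator(single_atom_model([1.0, 0.0, 0.0]), op)
        np.testing.assert_allclose(out.positions()[0], [0.0, 1.0, 0.0], atol=1e-9)

    def test_pairwise_distances_preserved(self, rng):
        model = random_model(rng, n=12)
        pos = model.positions()
        d0 = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        for _ in range(20):
            out = apply_operator(model, random_operator(rng))
            p = out.positions()
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            np.testing.assert_allclose(d, d0, atol=1e-9)

    def test_annotations_preserved(self, rng):
        model = random_model(rng)
        out = apply_operator(model, random_operator(rng))
        assert [e.res_id for e in out.entries] == [e.res_id for e in model.entries]
        assert [e.chain_id for e in out.entries] == [e.chain_id for e in model.entries]

    def test_improper_rotation_rejected(self):
        with pytest.raises(OperatorError, match="determinant"):
            SymmetryOperator(np.diag([1.0, 1.0, -1.0]))

    def test_non_orthonormal_rejected(self):
        with pytest.raises(OperatorError, match="orthonormal"):
            SymmetryOperator(np.eye(3) * 2.0)


class TestExpandVirus:
    def test_pentagon_closed_form(self):
        """C5 about z applied to (10, 0, 0) gives the regular pentagon."""
        _, ops = make_toy_pentamer()
        instances = expand_virus(single_atom_model([10.0, 0.0, 0.0]), ops)
        assert len(instances) == 5
        got = np.vstack([inst.model.positions() for inst in instances])
        expected = np.array(
            [[10 * math.cos(2 * math.pi * k / 5), 10 * math.sin(2 * math.pi * k / 5), 0.0]
             for k in range(5)]
        )
        np.testing.assert_allclose(np.sort(got, axis=0), np.sort(expected, axis=0), atol=1e-9)

    def test_fixed_point_on_axis(self):
        _, ops = make_toy_pentamer()
        instances = expand_virus(single_atom_model([0.0, 0.0, 5.0]), ops)
        for inst in instances:
            np.testing.assert_allclose(inst.model.positions()[0], [0.0, 0.0, 5.0], atol=1e-9)

    def test_wrong_operator_count(self):
        _, ops = make_toy_pentamer()
        with pytest.raises(OperatorError, match="5 operators"):
            expand_virus(single_atom_model([1, 0, 0]), ops[:4])

    def test_wrong_angles_rejected(self):
        ops = [SymmetryOperator(rotation_about_axis((0, 0, 1), 90.0 * k)) for k in range(4)]
        ops.append(SymmetryOperator.identity())
        with pytest.raises(OperatorError, match="C5"):
            expand_virus(single_atom_model([1, 0, 0]), ops)

    def test_mixed_axes_rejected(self):
        ops = [SymmetryOperator.identity()]
        ops += [SymmetryOperator(rotation_about_axis((0, 0, 1), a)) for a in (72, 144)]
        ops += [SymmetryOperator(rotation_about_axis((0, 1, 0), a)) for a in (216, 288)]
        with pytest.raises(OperatorError, match="axis"):
            expand_virus(single_atom_model([1, 0, 0]), ops)


class TestExpandHelical:
    def test_default_five_repeats(self):
        instances = expand_helical(single_atom_model([10.0, 0.0, 0.0]), rise=1.408, twist=22.03)
        assert len(instances) == 5

    def test_first_repeat_trigonometry(self):
        instances = expand_helical(single_atom_model([10.0, 0.0, 0.0]), rise=1.408, twist=22.03)
        p1 = instances.instances[1].model.positions()[0]
        theta = math.radians(22.03)
        np.testing.assert_allclose(
            p1, [10 * math.cos(theta), 10 * math.sin(theta), 1.408], atol=1e-9
        )

    def test_zero_twist_pure_translation(self):
        instances = expand_helical(single_atom_model([3.0, 4.0, 0.0]), rise=2.5, twist=0.0)
        for k, inst in enumerate(instances):
            np.testing.assert_allclose(inst.model.positions()[0], [3.0, 4.0, 2.5 * k], atol=1e-12)

    def test_inverse_composition_returns_home(self, rng):
        model = random_model(rng)
        fwd = expand_helical(model, rise=1.5, twist=30.0, n_repeats=3)
        last = fwd.instances[2].model
        back = expand_helical(last, rise=-1.5, twist=-30.0, n_repeats=3)
        np.testing.assert_allclose(back.instances[2].model.positions(), model.positions(), atol=1e-9)

    def test_full_turn_returns_to_start_azimuth(self):
        instances = expand_helical(single_atom_model([5.0, 0.0, 0.0]), rise=1.0, twist=72.0)
        p = instances.instances[4].model.positions()[0]
        theta = math.radians(4 * 72.0)
        np.testing.assert_allclose(p[:2], [5 * math.cos(theta), 5 * math.sin(theta)], atol=1e-9)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            expand_helical(single_atom_model([1, 0, 0]), rise=1.0, twist=10.0, n_repeats=0)
        with pytest.raises(ValueError):
            expand_helical(single_atom_model([1, 0, 0]), rise=0.0, twist=0.0)

    def test_rigidity_across_instances(self, rng):
        model = random_model(rng, n=6)
        pos0 = model.positions()
        d0 = np.linalg.norm(pos0[:, None] - pos0[None, :], axis=-1)
        for inst in expand_helical(model, rise=2.0, twist=36.0):
            p = inst.model.positions()
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            np.testing.assert_allclose(d, d0, atol=1e-9)


class TestExpand2dCrystal:
    CELL = np.array([[40.0, 0.0, 0.0], [0.0, 40.0, 0.0]])

    def test_p1_single_identity(self):
        instances = expand_2d_crystal(single_atom_model([5.0, 5.0, 0.0]), "p1", self.CELL)
        assert len(instances) == 1
        np.testing.assert_allclose(instances.instances[0].model.positions()[0], [5.0, 5.0, 0.0])

    def test_p2_related_by_180(self):
        instances = expand_2d_crystal(single_atom_model([5.0, 3.0, 1.0]), "p2", self.CELL)
        assert len(instances) == 2
        a, b = (inst.model.positions()[0] for inst in instances)
        # after removing the into-cell translation the copies differ by Rz(180)
        rel = b - np.array([40.0, 40.0, 0.0])
        np.testing.assert_allclose(rel, [-a[0], -a[1], a[2]], atol=1e-9)

    @pytest.mark.parametrize("symbol,order", [("p1", 1), ("p2", 2), ("p121", 2), ("p222", 4), ("p4", 4), ("p6", 6)])
    def test_group_orders(self, symbol, order):
        instances = expand_2d_crystal(single_atom_model([5.0, 3.0, 0.0]), symbol, self.CELL)
        assert len(instances) == order == len(PLANE_GROUPS[symbol])

    def test_p6_rotation_angles(self):
        instances = expand_2d_crystal(single_atom_model([5.0, 0.0, 0.0]), "p6", self.CELL)
        angles = sorted(round(inst.operator.angle_deg) for inst in instances)
        assert angles == [0, 60, 60, 120, 120, 180]  # 240/300 fold onto 120/60

    def test_copies_inside_cell(self):
        instances = expand_2d_crystal(single_atom_model([35.0, 25.0, 0.0]), "p4", self.CELL)
        for inst in instances:
            x, y, _ = inst.model.positions()[0]
            assert -1e-9 <= x < 40.0 + 1e-9
            assert -1e-9 <= y < 40.0 + 1e-9

    def test_unsupported_symbol(self):
        with pytest.raises(ValueError, match="plane group"):
            expand_2d_crystal(single_atom_model([1, 1, 0]), "p3m1", self.CELL)


class TestTranslateToCell:
    def box_map(self):
        return DensityMap(np.zeros((10, 10, 10)), voxel_size=(2.0, 2.0, 2.0))

    def to_set(self, positions):
        from emva.symmetry import Instance, InstanceSet

        return InstanceSet(
            [Instance(SymmetryOperator.identity(), single_atom_model(p)) for p in positions]
        )

    def test_inside_unchanged(self):
        out = translate_to_cell(self.to_set([[5.0, 5.0, 5.0]]), self.box_map())
        np.testing.assert_allclose(out.instances[0].model.positions()[0], [5.0, 5.0, 5.0])

    def test_one_cell_outside_shifts_exactly_one(self):
        out = translate_to_cell(self.to_set([[25.0, 5.0, 5.0]]), self.box_map())
        np.testing.assert_allclose(out.instances[0].model.positions()[0], [5.0, 5.0, 5.0])

    def test_random_offsets_end_inside(self, rng):
        dmap = self.box_map()
        positions = rng.normal(scale=200.0, size=(100, 3))
        out = translate_to_cell(self.to_set(positions), dmap)
        for inst in out:
            c = inst.model.positions().mean(axis=0)
            assert np.all(c >= np.array(dmap.origin) - 1e-9)
            assert np.all(c < np.array(dmap.origin) + np.array(dmap.extent) + 1e-9)


class TestFilterInstances:
    def blob_map(self):
        values = np.zeros((12, 12, 12))
        values[:, :, :6] = 10.0  # high density in the x < 6 half
        return DensityMap(values)

    def n_atom_instance(self, n_inside, n_total):
        from emva.symmetry import Instance, InstanceSet

        positions = [[2.0, 5.0, 5.0]] * n_inside + [[9.0, 5.0, 5.0]] * (n_total - n_inside)
        model = SimplifiedModel(
            [SimplifiedEntry("1", "A", i + 1, "ALA", p) for i, p in enumerate(positions)]
        )
        return InstanceSet([Instance(SymmetryOperator.identity(), model)])

    def test_fully_inside_displayed(self):
        out = filter_instances(self.n_atom_instance(10, 10), self.blob_map(), 5.0)
        assert out.instances[0].display

    def test_fully_outside_hidden(self):
        out = filter_instances(self.n_atom_instance(0, 10), self.blob_map(), 5.0)
        assert not out.instances[0].display

    @pytest.mark.parametrize("n_inside,shown", [(4, False), (5, True), (6, True)])
    def test_half_inside_boundary(self, n_inside, shown):
        out = filter_instances(self.n_atom_instance(n_inside, 10), self.blob_map(), 5.0)
        assert out.instances[0].display is shown


class TestOperatorIO:
    def test_biomt_roundtrip(self, tmp_path, rng):
        ops = [random_operator(rng) for _ in range(3)]
        lines = ["REMARK 350 BIOMOLECULE: 1"]
        for serial, op in enumerate(ops, start=1):
            for row in range(3):
                r = op.rotation[row]
                t = op.translation[row]
                lines.append(
                    f"REMARK 350   BIOMT{row+1} {serial:3d} {r[0]:9.6f} {r[1]:9.6f} "
                    f"{r[2]:9.6f}      {t:9.5f}"
                )
        path = tmp_path / "biomt.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        parsed = parse_biomt(path)
        assert len(parsed) == 3
        for got, want in zip(parsed, ops):
            np.testing.assert_allclose(got.rotation, want.rotation, atol=1e-6)
            np.testing.assert_allclose(got.translation, want.translation, atol=1e-4)

    def test_json_roundtrip(self, tmp_path, rng):
        ops = [random_operator(rng) for _ in range(4)]
        path = tmp_path / "ops.json"
        write_operators_json(ops, path)
        back = read_operators_json(path)
        for got, want in zip(back, ops):
            np.testing.assert_allclose(got.rotation, want.rotation, atol=1e-12)
            np.testing.assert_allclose(got.translation, want.translation, atol=1e-12)
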