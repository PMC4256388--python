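import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jointcodes as jc
from jointcodes.skeleton_io import mirror_frame


def _sequence(coords, **kw):
    kw.setdefault("activity_label", "act")
    kw.setdefault("subject_id", "subj")
    return jc.SkeletonSequence(np.asarray(coords, dtype=float), **kw)


class TestCanonicalCsv:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        seq = _sequence(rng.normal(size=(7, 4, 3)))
        path = tmp_path / "seq.csv"
        jc.write_skeleton_csv(seq, path)
        back = jc.read_skeleton_csv(path, "act", "subj")
        assert np.array_equal(back.coords, seq.coords)

    def test_rows_in_any_order(self, tmp_path):
        rows = [
            "frame,joint,x,y,z",
            "1,1,7.0,8.0,9.0",
            "0,0,1.0,2.0,3.0",
            "1,0,4.0,5.0,6.0",
            "0,1,-1.0,-2.0,-3.0",
        ]
        path = tmp_path / "seq.csv"
        path.write_text("\n".join(rows) + "\n")
        seq = jc.read_skeleton_csv(path)
        assert seq.coords.shape == (2, 2, 3)
        assert np.array_equal(seq.coords[0, 0], [1.0, 2.0, 3.0])
        assert np.array_equal(seq.coords[1, 1], [7.0, 8.0, 9.0])

    def test_frame_gap_is_structural_error(self, tmp_path):
        rows = ["0,0,1,2,3", "0,1,1,2,3", "2,0,1,2,3", "2,1,1,2,3"]
        path = tmp_path / "gap.csv"
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(jc.StructureError, match="contiguous"):
            jc.read_skeleton_csv(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,0,1.0,2.0,3.0\n0,1,1.0,oops,3.0\n")
        with pytest.raises(jc.ParseError, match=":2"):
            jc.read_skeleton_csv(path)

    def test_non_finite_coordinate_rejected(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("0,0,1.0,nan,3.0\n0,1,1.0,2.0,3.0\n")
        with pytest.raises(jc.ValidationError, match="non-finite"):
            jc.read_skeleton_csv(path)

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "missing.csv"
        path.write_text("0,0,1,2,3\n0,1,1,2,3\n1,0,1,2,3\n")
        with pytest.raises(jc.StructureError, match="missing"):
            jc.read_skeleton_csv(path)


def _write_cad60(path, frames_mm):
    """frames_mm: (T, 15, 3) positions in millimeters."""
    lines = []
    for t in range(frames_mm.shape[0]):
        tokens = [str(t + 1)]
        for j in range(11):
            tokens += ["0.1"] * 9 + ["1"]
            tokens += [repr(float(v)) for v in frames_mm[t, j]] + ["1"]
        for j in range(11, 15):
            tokens += [repr(float(v)) for v in frames_mm[t, j]] + ["1"]
        lines.append(",".join(tokens) + ",")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestDialectAdapters:
    def test_cad60_round_trip(self, tmp_path, rng):
        frames_mm = rng.uniform(-2000, 2000, size=(3, 15, 3))
        path = tmp_path / "cad.txt"
        _write_cad60(path, frames_mm)
        seq = jc.read_cad60_skeleton(path, "act", "subj")
        assert seq.coords.shape == (3, 15, 3)
        np.testing.assert_allclose(seq.coords, frames_mm / 1000.0, rtol=0, atol=1e-12)

    def test_cad60_wrong_token_count(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1,2,3\nEND\n")
        with pytest.raises(jc.ParseError, match="expected"):
            jc.read_cad60_skeleton(path)

    def test_msr_round_trip_and_dropout(self, tmp_path, rng, caplog):
        coords = rng.normal(size=(4, 20, 3))
        coords[2, 5] = 0.0  # tracker dropout in frame 2
        lines = []
        for t in range(4):
            for j in range(20):
                x, y, z = (float(v) for v in coords[t, j])
                lines.append(f"{x!r} {y!r} {z!r} 1")
        path = tmp_path / "msr.txt"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            seq = jc.read_msr_skeleton(path, "act", "subj")
        assert seq.coords.shape == (3, 20, 3)
        assert "dropped 1 frame" in caplog.text
        np.testing.assert_array_equal(seq.coords, coords[[0, 1, 3]])

    def test_msr_truncated_file(self, tmp_path):
        path = tmp_path / "trunc.txt"
        path.write_text("1.0 2.0 3.0 1\n" * 25)  # 25 rows, not multiple of 20
        with pytest.raises(jc.ParseError, match="multiple"):
            jc.read_msr_skeleton(path)

    def test_msr_bad_field_count(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1.0 2.0 3.0\n" * 20)
        with pytest.raises(jc.ParseError, match="4 fields"):
            jc.read_msr_skeleton(path)


ROLES = jc.JointRoleMap(left_arm=0, right_arm=1, left_hip=2, right_hip=3)


def _frame_with_roles(extra):
    anchor = np.array(
        [[1.0, 1.0, 0.0], [-1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, -1.0, 0.0]]
    )
    return np.vstack([anchor, np.atleast_2d(extra)])


class TestMirroring:
    def test_hand_computed_reflection(self):
        # role joints in the z=0 plane, arm midpoint (0,1,0), hip midpoint
        # (0,-1,0): the mirror plane is x=0, so (2,0,0) -> (-2,0,0).
        frame = _frame_with_roles([2.0, 0.0, 0.0])
        out = mirror_frame(frame, ROLES)
        np.testing.assert_allclose(out[4], [-2.0, 0.0, 0.0], atol=1e-12)

    def test_symmetric_configuration_maps_onto_itself(self):
        # joints on the mirror plane are fixed points; a bilaterally
        # symmetric configuration is preserved as a set (left/right swap)
        frame = _frame_with_roles([[0.0, 0.3, 0.7], [0.0, -0.9, 0.2]])
        seq = _sequence(frame[None])
        out = jc.mirror_sequence(seq, ROLES)
        np.testing.assert_allclose(out.coords[0, 4:], seq.coords[0, 4:], atol=1e-10)
        original = sorted(map(tuple, np.round(seq.coords[0], 9)))
        mirrored = sorted(map(tuple, np.round(out.coords[0], 9)))
        np.testing.assert_allclose(mirrored, original, atol=1e-10)

    def test_involution_and_isometry(self, rng):
        coords = rng.normal(size=(6, 9, 3))
        seq = _sequence(coords)
        once = jc.mirror_sequence(seq, ROLES)
        twice = jc.mirror_sequence(once, ROLES)
        np.testing.assert_allclose(twice.coords, seq.coords, atol=1e-10)
        for t in range(coords.shape[0]):
            orig = np.linalg.norm(coords[t][:, None] - coords[t][None], axis=2)
            refl = np.linalg.norm(
                once.coords[t][:, None] - once.coords[t][None], axis=2
            )
            np.testing.assert_allclose(refl, orig, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_isometry_property(self, seed):
        coords = np.random.default_rng(seed).normal(size=(1, 7, 3))
        out = mirror_frame(coords[0], ROLES)
        orig = np.linalg.norm(coords[0][:, None] - coords[0][None], axis=2)
        refl = np.linalg.norm(out[:, None] - out[None], axis=2)
        np.testing.assert_allclose(refl, orig, atol=1e-10)

    def test_coincident_midpoints_rejected(self):
        frame = np.array(
            [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
             [0.5, 0.5, 0.5]]
        )
        with pytest.raises(jc.GeometryError, match="midpoints"):
            mirror_frame(frame, ROLES)

    def test_collinear_role_joints_rejected(self):
        frame = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0], [3.0, 0.0, 0.0],
             [0.5, 0.5, 0.5]]
        )
        with pytest.raises(jc.GeometryError, match="collinear"):
            mirror_frame(frame, ROLES)


class TestValidation:
    def test_bad_shape_rejected(self):
        with pytest.raises(jc.ValidationError):
            _sequence(np.zeros((3, 4)))

    def test_single_joint_rejected(self):
        with pytest.raises(jc.ValidationError):
            _sequence(np.zeros((3, 1, 3)))

    def test_role_map_needs_distinct_indices(self):
        with pytest.raises(jc.ValidationError):
            jc.JointRoleMap(0, 0, 1, 2)
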