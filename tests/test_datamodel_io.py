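"""Domain types, TSV round trips and pooling semantics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scfs.datamodel import (
    ConditionDataset,
    CurveMetadata,
    ForceCurve,
    ForceMap,
    RuptureEvent,
    pool_condition,
)
from scfs.errors import FormatError, ValidationError
from scfs.io import read_curve, read_event_table, write_curve, write_event_table


def _small_curve(dwell_samples=4, curve_id="c0"):
    n_app, n_ret = 10, 120
    time = np.arange(n_app + dwell_samples + n_ret) / 2000.0
    z = np.concatenate(
        [np.linspace(0, 100, n_app), np.full(dwell_samples, 100.0), np.linspace(100, -500, n_ret)]
    )
    d = np.concatenate(
        [np.linspace(0, 50, n_app), np.full(dwell_samples, 50.0), np.linspace(50, -1, n_ret)]
    )
    seg = np.array(["approach"] * n_app + ["dwell"] * dwell_samples + ["retract"] * n_ret, dtype=object)
    return ForceCurve(time, z, d, seg, CurveMetadata(curve_id=curve_id))


def _event(curve_id="c0", index=10, force=30.0, klass="jump"):
    return RuptureEvent(
        curve_id=curve_id,
        index=index,
        separation_nm=float(index) * 1.5,
        step_height_d=force / 60.0,
        force_F=force,
        event_class=klass,
        loading_rate_r=600.0,
        pre_slope=-0.2,
    )


class TestCurveIO:
    @pytest.mark.parametrize("dwell", [0, 4])
    def test_round_trip_identity(self, tmp_path, dwell):
        curve = _small_curve(dwell_samples=dwell)
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.time, curve.time, rtol=1e-9)
        np.testing.assert_allclose(back.z_position, curve.z_position, rtol=1e-9)
        np.testing.assert_allclose(back.deflection, curve.deflection, rtol=1e-9)
        assert list(back.segment_labels) == list(curve.segment_labels)
        assert back.metadata == curve.metadata

    def test_two_writes_byte_identical(self, tmp_path):
        curve = _small_curve()
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_curve(curve, a)
        write_curve(curve, b)
        assert a.read_bytes() == b.read_bytes()

    def test_header_parsed_with_units(self, tmp_path):
        curve = _small_curve()
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        text = path.read_text()
        assert "# spring_constant_pN_per_nm: 60" in text
        assert read_curve(path).metadata.spring_constant_k == 60.0

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# spring_constant_pN_per_nm 60\ntime_s\tz_nm\tdeflection_nm\tsegment\n")
        with pytest.raises(FormatError, match="line 1"):
            read_curve(path)

    def test_unparseable_value_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# velocity_um_per_s: fast\ntime_s\tz_nm\tdeflection_nm\tsegment\n")
        with pytest.raises(FormatError, match="line 1"):
            read_curve(path)

    def test_missing_retract_rejected(self, tmp_path):
        curve = _small_curve()
        curve.segment_labels[:] = "approach"
        with pytest.raises(ValidationError, match="retract"):
            write_curve(curve, tmp_path / "x.tsv")

    def test_non_monotone_time_rejected(self, tmp_path):
        curve = _small_curve()
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        lines = path.read_text().splitlines()
        lines[10], lines[11] = lines[11], lines[10]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="time"):
            read_curve(path)

    @given(
        k=st.floats(1.0, 500.0),
        v=st.floats(0.1, 20.0),
        temp=st.floats(270.0, 320.0),
    )
    def test_metadata_floats_survive_round_trip(self, tmp_path_factory, k, v, temp):
        curve = _small_curve()
        curve.metadata.spring_constant_k = k
        curve.metadata.velocity_v = v
        curve.metadata.temperature = temp
        path = tmp_path_factory.mktemp("io") / "c.tsv"
        write_curve(curve, path)
        meta = read_curve(path).metadata
        assert meta.spring_constant_k == pytest.approx(k, rel=1e-9)
        assert meta.velocity_v == pytest.approx(v, rel=1e-9)
        assert meta.temperature == pytest.approx(temp, rel=1e-9)


class TestEventTable:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "e.tsv"
        write_event_table([], path)
        assert path.read_text().count("\n") == 1
        assert read_event_table(path) == []

    def test_rows_ordered_and_forces_exact(self, tmp_path):
        events = [_event("b", 5, 41.25), _event("a", 9, 17.5, "tether"), _event("a", 2, 99.0)]
        path = tmp_path / "e.tsv"
        write_event_table(events, path)
        back = read_event_table(path)
        assert [(e.curve_id, e.index) for e in back] == [("a", 2), ("a", 9), ("b", 5)]
        assert sorted(e.force_F for e in back) == sorted(e.force_F for e in events)
        for e in back:
            assert e.force_F == pytest.approx(e.step_height_d * 60.0, rel=1e-9)


class TestDomainTypes:
    def test_metadata_invariants(self):
        with pytest.raises(ValidationError):
            CurveMetadata(spring_constant_k=0).validate()
        with pytest.raises(ValidationError):
            CurveMetadata(dwell_time=-1).validate()

    def test_map_requires_shared_condition(self):
        a, b = _small_curve(curve_id="a"), _small_curve(curve_id="b")
        b.metadata.condition_label = "DF-DF"
        with pytest.raises(ValidationError, match="condition"):
            ForceMap(curves=[a, b]).validate()

    def test_event_class_restricted(self):
        with pytest.raises(ValidationError):
            _event(klass="plateau")

    def test_units_audit(self):
        """One hand-converted curve: 0.5 nm deflection at 60 pN/nm is 30 pN."""
        curve = _small_curve()
        curve.deflection = np.full_like(curve.deflection, 0.5)
        np.testing.assert_allclose(curve.force(), 30.0)
        # loading rate: 0.2 pN/nm at 3 um/s = 0.2 * 3000 nm/s = 600 pN/s
        assert 0.2 * curve.metadata.velocity_v * 1000.0 == pytest.approx(600.0)


class TestPooling:
    def test_tethers_excluded(self):
        events = [_event("c1", 5, 20.0), _event("c1", 40, 35.0), _event("c2", 7, 50.0)]
        events += [_event("c2", 60, 30.0, "tether"), _event("c3", 9, 30.0, "tether")]
        ds = pool_condition(events, "NF-NF", "none", 3.0)
        assert sorted(ds.rupture_forces) == [20.0, 35.0, 50.0]
        assert ds.n == 3
        assert ds.n_curves == 3  # tether-only curves still contributed

    def test_empty_pool_allowed(self):
        ds = pool_condition([], "NF-NF", "EGTA", 3.0)
        assert ds.n == 0 and ds.rupture_forces.size == 0

    def test_pooling_is_deterministic(self):
        events = [_event("c", i, 10.0 + i) for i in range(5)]
        a = pool_condition(events, "X", "none", 3.0)
        b = pool_condition(list(events), "X", "none", 3.0)
        np.testing.assert_array_equal(np.sort(a.rupture_forces), np.sort(b.rupture_forces))

    def test_negative_force_rejected(self):
        ds = ConditionDataset("X", "none", 3.0, np.array([-1.0]))
        with pytest.raises(ValidationError):
            ds.validate()
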