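"""Experiment XML parsing, event classification and the run loop."""

import numpy as np
import pandas as pd
import pytest

from wormstim import mechano
from wormstim.experiment import (
    EventSpec,
    ExperimentError,
    classify_events,
    parse_experiment,
    read_table,
    run,
    write_experiment,
    write_table,
)
from wormstim.geometry import pose_worm, reference_state


def write_xml(tmp_path, body, name="exp.xml", dt=0.01, t_end=2.0):
    path = tmp_path / name
    path.write_text(
        f'<experiment dt="{dt}" tEnd="{t_end}" seed="0">\n'
        '  <plate diameter="50"/>\n'
        '  <worm x="0" y="0" heading="0"/>\n'
        f"  <events>\n{body}\n  </events>\n"
        "</experiment>\n")
    return str(path)


def test_minimal_plate_tap_parses(tmp_path):
    spec = parse_experiment(write_xml(
        tmp_path, '<plateTap amplitude="100" onset="0.5" duration="0.5"/>'))
    assert len(spec.events) == 1
    assert spec.events[0].kind == "plate_tap"
    assert spec.events[0].onset == 0.5


def test_onset_beyond_t_end_rejected(tmp_path):
    with pytest.raises(ExperimentError, match="onset"):
        parse_experiment(write_xml(
            tmp_path, '<plateTap amplitude="100" onset="5" duration="0.5"/>'))


def test_unknown_element_named_in_error(tmp_path):
    with pytest.raises(ExperimentError, match="zapWorm"):
        parse_experiment(write_xml(tmp_path, '<zapWorm amplitude="1"/>'))


def test_unknown_attribute_named_in_error(tmp_path):
    with pytest.raises(ExperimentError, match="wattage"):
        parse_experiment(write_xml(
            tmp_path,
            '<plateTap amplitude="1" onset="0" duration="0.5" wattage="9"/>'))


def test_missing_required_attribute(tmp_path):
    with pytest.raises(ExperimentError, match="amplitude"):
        parse_experiment(write_xml(
            tmp_path, '<plateTap onset="0" duration="0.5"/>'))


def test_round_trip_identity(tmp_path, fixture_dir):
    for name in ["quadrants.xml", "shock.xml", "light.xml", "drop.xml",
                 "collision.xml", "proprioception.xml"]:
        spec = parse_experiment(str(fixture_dir / name))
        out = tmp_path / ("rt_" + name)
        write_experiment(spec, str(out))
        assert parse_experiment(str(out)) == spec


def test_classification_matches_partition(fixture_dir):
    spec = parse_experiment(str(fixture_dir / "shock.xml"))
    predefined, runtime = classify_events(spec)
    assert [e.kind for e in predefined] == ["electric_shock"]
    assert runtime == []

    spec = parse_experiment(str(fixture_dir / "drop.xml"))
    predefined, runtime = classify_events(spec)
    assert predefined == []
    assert [e.kind for e in runtime] == ["chem_drop"]


def test_classification_of_all_kinds():
    spec_events = [
        ("touch", True), ("plate_tap", True), ("global_temp", True),
        ("electric_shock", True), ("light_pulse", True),
        ("quadrants", False), ("osmotic_ring", False),
        ("chem_point_source", False), ("chem_drop", False),
        ("thermal_gradient", False), ("heat_point", False),
        ("proprioception", False),
    ]
    from wormstim.experiment import ExperimentSpec
    spec = ExperimentSpec(events=tuple(
        EventSpec(kind=k) for k, _ in spec_events))
    predefined, runtime = classify_events(spec)
    assert [e.kind for e in predefined] == [k for k, p in spec_events if p]
    assert [e.kind for e in runtime] == [k for k, p in spec_events if not p]

    empty_pre, empty_run = classify_events(ExperimentSpec())
    assert empty_pre == [] and empty_run == []


def test_no_events_gives_empty_table(tmp_path):
    spec = parse_experiment(write_xml(tmp_path, "", t_end=0.5))
    table = run(spec)
    assert table.empty
    assert list(table.columns) == ["t", "neuron", "modality", "channel", "value"]


def test_proprio_only_run_has_only_proprio_rows(fixture_dir):
    spec = parse_experiment(str(fixture_dir / "proprioception.xml"))
    table = run(spec)
    assert set(table.modality.unique()) == {"proprio_curvature",
                                            "proprio_stretch"}


def test_precomputed_touch_equals_direct_evaluation(tmp_path, mesh, registry):
    """The engine's precomputed-weight path reproduces, bit for bit, direct
    per-timestep evaluation of the touch pipeline."""
    spec = parse_experiment(write_xml(
        tmp_path,
        '<touch kind="gentle" u="0.3" phi="90" amplitude="10" '
        'onset="0.5" duration="1.0"/>'))
    table = run(spec, registry=registry, mesh=mesh)
    state = pose_worm(mesh, registry, reference_state())
    ev = mechano.TouchEvent(kind="gentle", amplitude=10.0, onset=0.5,
                            duration=1.0, point=(0.3, 90.0))
    sub = table[table.neuron == "ALML"].sort_values("t")
    for t, value in zip(sub.t, sub.value):
        direct = mechano.touch_stimuli(ev, state, registry,
                                       np.array([t]))["ALML"][0]
        assert value == direct


def test_shock_superposition_leaves_other_rows_unchanged(tmp_path):
    base_body = '<plateTap amplitude="50" onset="0.2" duration="0.4"/>'
    shock_body = base_body + (
        '\n<electricShock amplitude="10" frequency="10" pulseDuration="0.02"'
        ' onset="0.2" trainDuration="1.0"/>')
    t1 = run(parse_experiment(write_xml(tmp_path, base_body, name="a.xml")))
    t2 = run(parse_experiment(write_xml(tmp_path, shock_body, name="b.xml")))
    non_galvano = t2[t2.modality != "galvano"].reset_index(drop=True)
    pd.testing.assert_frame_equal(non_galvano, t1)
    assert (t2.modality == "galvano").any()


def test_write_table_sorted_and_round_trips(tmp_path, fixture_dir):
    table = run(parse_experiment(str(fixture_dir / "tap.xml")))
    path = tmp_path / "out.csv"
    write_table(table, str(path))
    again = read_table(str(path))
    key = again[["t", "neuron", "modality", "channel"]]
    assert (key.sort_values(["t", "neuron", "modality", "channel"])
            .reset_index(drop=True).equals(key.reset_index(drop=True)))
    pd.testing.assert_frame_equal(again, table)


def test_empty_table_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_table(pd.DataFrame(
        columns=["t", "neuron", "modality", "channel", "value"]), str(path))
    assert path.read_text().splitlines() == ["t,neuron,modality,channel,value"]


def test_wide_format(tmp_path, fixture_dir):
    table = run(parse_experiment(str(fixture_dir / "tap.xml")))
    path = tmp_path / "wide.csv"
    write_table(table, str(path), format="wide")
    wide = pd.read_csv(str(path))
    assert "t" in wide.columns
    assert any(col.startswith("ALML|mechano") for col in wide.columns)
    assert len(wide) == table.t.nunique()


def test_same_seed_byte_identical_csv(tmp_path, fixture_dir):
    for name in ["tap.xml", "collision.xml"]:
        spec = parse_experiment(str(fixture_dir / name))
        paths = []
        for i in range(2):
            t = run(spec)
            p = tmp_path / f"{name}.{i}.csv"
            write_table(t, str(p))
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
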