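"""Sweep machinery: consistency, order independence, interval extraction."""

import numpy as np
import pandas as pd
import pytest

from prfield import (ClassifierCriteria, ModelParams, ScanResult,
                     SimulationConfig, evaluate_point, grid_2d,
                     sensitivity_interval, sweep_current, sweep_field)

# a short horizon keeps these structural tests fast; the acceptance suite
# runs the full 7 s protocol
SHORT = SimulationConfig(duration=3500.0)


def test_singleton_grid_equals_direct_evaluation(weak_dc_params):
    res = sweep_field(weak_dc_params, [0.0], config=SHORT)
    f, regime = evaluate_point(weak_dc_params, 0.0, SHORT)
    assert len(res.table) == 1
    assert res.table["F_hz"].iloc[0] == f
    assert res.table["regime"].iloc[0] == regime


def test_duplicate_grid_points_are_identical(weak_dc_params):
    res = sweep_field(weak_dc_params, [2.0, 2.0, 2.0], config=SHORT)
    assert res.table["F_hz"].nunique() == 1
    assert res.table["regime"].nunique() == 1


def test_results_do_not_depend_on_evaluation_order(weak_dc_params):
    grid = [-2.0, 0.0, 2.0]
    fwd = sweep_field(weak_dc_params, grid, config=SHORT).table
    rev = sweep_field(weak_dc_params, grid[::-1], config=SHORT).table
    merged = fwd.merge(rev, on="Ve", suffixes=("_f", "_r"))
    assert (merged["F_hz_f"] == merged["F_hz_r"]).all()
    assert (merged["regime_f"] == merged["regime_r"]).all()


def test_grid2d_rows_match_1d_sweeps(weak_dc_params):
    ve_grid = [-2.0, 0.0, 2.0]
    grid = grid_2d(weak_dc_params, ("gc", [1.0, 2.1]), ("Ve", ve_grid),
                   config=SHORT)
    for gc in (1.0, 2.1):
        row = grid.table[grid.table["gc"] == gc]
        line = sweep_field(weak_dc_params.replace(gc=gc), ve_grid, config=SHORT).table
        assert list(row["F_hz"]) == list(line["F_hz"])
        assert list(row["regime"]) == list(line["regime"])


def test_grid2d_rejects_unknown_axes(weak_dc_params):
    with pytest.raises(ValueError):
        grid_2d(weak_dc_params, ("gNa", [10.0]), ("Ve", [0.0]), config=SHORT)
    with pytest.raises(ValueError):
        grid_2d(weak_dc_params, ("gc", []), ("Ve", [0.0]), config=SHORT)


def test_sweep_current_uses_id_axis(weak_dc_params):
    res = sweep_current(weak_dc_params, [0.0, 1.0], config=SHORT)
    assert list(res.table.columns) == ["Id", "F_hz", "regime"]
    assert len(res.table) == 2


def _fake_scan(regimes, ve=None):
    ve = np.arange(len(regimes)) if ve is None else np.asarray(ve, float)
    table = pd.DataFrame({"Ve": ve, "F_hz": 0.0, "regime": regimes})
    return ScanResult(axes=[("Ve", ve)], table=table, provenance={})


SPK, REST = "periodic_spiking", "resting"


def test_interval_is_maximal_contiguous_sensitive_run():
    scan = _fake_scan([REST, SPK, SPK, SPK, REST, SPK, REST],
                      ve=[-3, -2, -1, 0, 1, 2, 3])
    assert tuple(sensitivity_interval(scan)) == (-2.0, 0.0)


def test_interval_tie_breaks_to_smallest_lower_endpoint():
    scan = _fake_scan([SPK, SPK, REST, SPK, SPK], ve=[-2, -1, 0, 1, 2])
    assert tuple(sensitivity_interval(scan)) == (-2.0, -1.0)


def test_interval_endpoints_bracket_the_sensitive_run():
    scan = _fake_scan([REST, "depolarization_block", SPK, "fast_bursting",
                       "subthreshold_oscillation"], ve=[-2, -1, 0, 1, 2])
    lo, hi = sensitivity_interval(scan)
    assert (lo, hi) == (0.0, 1.0)
    tbl = scan.table.set_index("Ve")["regime"]
    from prfield import is_sensitive
    assert not is_sensitive(tbl[lo - 1])
    assert not is_sensitive(tbl[hi + 1])


def test_interval_empty_and_edge_runs():
    assert sensitivity_interval(_fake_scan([REST, REST])).empty
    scan = _fake_scan([SPK, SPK, SPK], ve=[5, 6, 7])
    assert tuple(sensitivity_interval(scan)) == (5.0, 7.0)


def test_interval_requires_ve_axis():
    table = pd.DataFrame({"Id": [0.0], "F_hz": [0.0], "regime": [REST]})
    scan = ScanResult(axes=[("Id", np.array([0.0]))], table=table, provenance={})
    with pytest.raises(ValueError):
        sensitivity_interval(scan)


def test_scan_csv_and_provenance(tmp_path, weak_dc_params):
    res = sweep_field(weak_dc_params, [0.0], config=SHORT,
                      criteria=ClassifierCriteria())
    res.to_csv(tmp_path / "scan.csv")
    res.write_provenance(tmp_path / "scan.json")
    back = pd.read_csv(tmp_path / "scan.csv")
    assert list(back.columns) == ["Ve", "F_hz", "regime"]
    import json
    prov = json.loads((tmp_path / "scan.json").read_text())
    assert prov["params"]["gc"] == weak_dc_params.gc
    assert prov["criteria"]["spike_threshold"] == 20.0
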