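"""Verification harness: sweeps, reports, determinism."""

import pytest

from klexact.verify import run_sweep


def test_beta_sweep_rows_and_zero_point():
    rep = run_sweep("beta", {"a": 2.0, "b": 2.0, "d": 2.0}, "c",
                    [1.0, 2.0, 3.0])
    assert len(rep.rows) == 3
    row = rep.rows[1]
    assert row.p2 == {"c": 2.0, "d": 2.0}
    assert row.closed_value == pytest.approx(0.0, abs=1e-12)
    assert rep.max_abs_diff <= 1e-8


def test_cauchy_sweep_marks_fallback_points():
    rep = run_sweep("cauchy", {"sigma": 1.0}, "r", [0.5, 1.9])
    methods = [r.method for r in rep.rows]
    assert methods[0] == "closed_series"
    assert methods[1] == "oracle_fallback"


def test_gamma_sweep_oracle_agreement():
    rep = run_sweep("gamma", {"a": 2.0, "b": 1.0, "d": 1.0}, "c",
                    [1.0, 2.0, 4.0])
    assert rep.max_abs_diff <= 1e-6


def test_inadmissible_point_recorded_not_raised():
    rep = run_sweep("beta", {"a": 2.0, "b": 2.0, "d": 2.0}, "c",
                    [-1.0, 2.0])
    assert rep.rows[0].skipped_reason is not None
    assert rep.rows[1].skipped_reason is None
    # skipped rows do not contribute to the max
    assert rep.max_abs_diff == rep.rows[1].abs_diff


def test_reports_deterministic_and_csv_well_formed():
    kwargs = (("exponential", {"a": 1.0}, "b", [1.0, 2.0, 5.0]),)
    csv1 = run_sweep(*kwargs[0]).to_csv()
    csv2 = run_sweep(*kwargs[0]).to_csv()
    assert csv1 == csv2
    lines = csv1.strip().splitlines()
    assert lines[0] == "family,sweep,param_point,closed,oracle,abs_diff,method"
    assert len(lines) == 4


def test_shared_parameter_sweep_moves_both_sides():
    rep = run_sweep("pareto_1", {"a": 2.0, "b": 3.0}, "K", [1.0, 2.0])
    for row in rep.rows:
        assert row.p1["K"] == row.p2["K"]
        assert row.abs_diff <= 1e-8
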