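"""MIRD dose schema, ICRP weighting, injection limits, method comparison."""

import numpy as np
import pandas as pd
import pytest

from petdosim import (
    F18,
    SValueTable,
    absorbed_doses,
    bladder_sensitivity,
    compare_methods,
    effective_dose,
    icrp60_scheme,
    icrp103_scheme,
    injection_limits,
)
from petdosim import reference as ref
from petdosim.dose import TissueWeightScheme, default_rules
from petdosim.pipeline import toy_svalue_table


def _table(index, columns, values):
    return SValueTable("toy", pd.DataFrame(values, index=index, columns=columns))


def test_identity_table_returns_residence_times():
    s = _table(["liver"], ["liver"], [[1.0]])
    assert absorbed_doses({"liver": 0.445}, s)["liver"] == pytest.approx(0.445)


def test_two_organ_hand_matrix_product():
    s = _table(["a", "b"], ["a", "b"], [[1.0, 0.1], [0.2, 0.5]])
    d = absorbed_doses({"a": 1.0, "b": 2.0}, s)
    assert d["a"] == pytest.approx(1.2)
    assert d["b"] == pytest.approx(1.2)


def test_zero_residence_gives_zero_dose():
    s = _table(["a", "b"], ["a", "b"], [[1.0, 0.1], [0.2, 0.5]])
    assert all(v == 0.0 for v in absorbed_doses({"a": 0.0, "b": 0.0}, s).values())


def test_absorbed_doses_linear_in_residence():
    s = _table(["a", "b"], ["a", "b"], [[1.0, 0.1], [0.2, 0.5]])
    d1 = absorbed_doses({"a": 0.4, "b": 0.1}, s)
    d2 = absorbed_doses({"a": 0.1, "b": 0.7}, s)
    mix = absorbed_doses({"a": 2 * 0.4 + 0.1, "b": 2 * 0.1 + 0.7}, s)
    for t in ("a", "b"):
        assert mix[t] == pytest.approx(2 * d1[t] + d2[t], rel=1e-12)


def test_unknown_source_is_named():
    s = _table(["a"], ["a"], [[1.0]])
    with pytest.raises(KeyError, match="pancreas"):
        absorbed_doses({"pancreas": 0.1}, s)


def test_remainder_alias_maps_to_rest_of_body_column():
    s = _table(["a"], ["a", "rest of body"], [[1.0, 0.5]])
    assert absorbed_doses({"remainder": 2.0}, s)["a"] == pytest.approx(1.0)


def test_toy_table_is_self_dose_dominant():
    s = toy_svalue_table()
    assert s.table.loc["liver", "liver"] == s.table["liver"].max()
    assert s.table.loc["urinary bladder wall", "bladder"] == s.table["bladder"].max()


@pytest.mark.parametrize("scheme_fn", [icrp103_scheme, icrp60_scheme])
def test_uniform_dose_vector_is_fixed_point(scheme_fn):
    scheme = scheme_fn()
    organs = set(ref.DOSES_TD)
    uniform = {o: 0.0123 for o in organs}
    assert effective_dose(uniform, scheme) == pytest.approx(0.0123, rel=1e-12)


@pytest.mark.parametrize(
    "scheme_fn, doses, reported, rel_tol",
    [
        (icrp103_scheme, ref.DOSES_TD, 1.88e-2, 0.10),
        (icrp103_scheme, ref.DOSES_DYNAMIC_SINGLE, 1.84e-2, 0.10),
        (icrp60_scheme, ref.DOSES_TD, 2.18e-2, 0.03),
        (icrp60_scheme, ref.DOSES_DYNAMIC_SINGLE, 2.15e-2, 0.03),
    ],
    ids=["icrp103-td", "icrp103-ds", "icrp60-td", "icrp60-ds"],
)
def test_effective_dose_recomputed_from_published_organ_doses(
    scheme_fn, doses, reported, rel_tol
):
    assert effective_dose(doses, scheme_fn()) == pytest.approx(reported, rel=rel_tol)


def test_gonad_convention_changes_effective_dose_below_one_percent():
    base = icrp103_scheme()
    testes_only = icrp103_scheme()
    testes_only.surrogate_map["gonads"] = {"testes": 1.0}
    a = effective_dose(ref.DOSES_TD, base)
    b = effective_dose(ref.DOSES_TD, testes_only)
    assert abs(a - b) / a < 0.01


def test_unresolvable_tissue_lists_missing_surrogates():
    scheme = TissueWeightScheme("x", {"colon": 1.0}, {"colon": {"uli wall": 1.0}})
    with pytest.raises(KeyError, match="uli wall"):
        effective_dose({"liver": 0.01}, scheme)


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        TissueWeightScheme("x", {"liver": 0.5})


@pytest.mark.parametrize(
    "limit_msv, dose, want_mbq",
    [(50.0, 1.54e-1, 325), (150.0, 1.54e-1, 974), (50.0, 9.67e-2, 517), (150.0, 9.67e-2, 1551)],
)
def test_organ_limits_from_published_bladder_doses(limit_msv, dose, want_mbq):
    doses = dict(ref.DOSES_TD)
    doses["urinary bladder wall"] = dose
    rows = injection_limits(doses, 1.88e-2).set_index("rule")
    scope = "us_single_organ" if limit_msv == 50.0 else "us_annual_organ"
    assert rows.loc[scope, "limit_mbq"] == want_mbq
    assert rows.loc[scope, "critical"] == "urinary bladder wall"


def test_effective_dose_limit_from_published_value():
    rows = injection_limits(ref.DOSES_TD, 1.88e-2).set_index("rule")
    assert rows.loc["eu_single_effective", "limit_mbq"] == 532


def test_limits_scale_inversely_with_dose():
    doubled = {o: 2 * v for o, v in ref.DOSES_TD.items()}
    base = injection_limits(ref.DOSES_TD, 1.88e-2).set_index("rule")["limit_mbq"]
    halved = injection_limits(doubled, 2 * 1.88e-2).set_index("rule")["limit_mbq"]
    for rule in base.index:
        assert halved[rule] == pytest.approx(base[rule] / 2, abs=1.0)


def test_zero_dose_vector_rejected():
    with pytest.raises(ValueError):
        injection_limits({o: 0.0 for o in ref.DOSES_TD}, 0.0)


def test_rules_cover_both_jurisdictions():
    names = {r.name for r in default_rules()}
    assert {"us_single_organ", "us_annual_organ", "eu_single_effective"} <= names


def test_bladder_sensitivity_grid():
    s = toy_svalue_table()
    organ_taus = {"liver": 0.445, "brain": 0.174}
    grid = bladder_sensitivity(
        organ_taus, (0.3, 0.4, 0.5), (2.0, 4.0), s,
        {"icrp103": icrp103_scheme()}, F18,
    )
    assert len(grid) == 6
    g4 = grid[grid.voiding_interval_h == 4.0].sort_values("fraction")
    # bladder-wall dose strictly increasing in the excreted fraction
    assert g4["ubw_mgy_per_mbq"].is_monotonic_increasing
    # residence linear in f: f=0.5 vs f=0.3 ratio exactly 5/3
    taus = g4.set_index("fraction")["tau_bladder_h"]
    assert taus[0.5] / taus[0.3] == pytest.approx(5.0 / 3.0, rel=1e-12)
    # shorter voiding interval reduces the bladder residence at fixed f
    g = grid.set_index(["fraction", "voiding_interval_h"])["tau_bladder_h"]
    assert g[(0.5, 2.0)] < g[(0.5, 4.0)]


def test_identical_vectors_correlate_perfectly():
    r, table = compare_methods(ref.DOSES_TD, ref.DOSES_TD)
    assert r == pytest.approx(1.0)
    assert np.allclose(table["percent_deviation"], 0.0)


def test_published_method_comparison():
    r, table = compare_methods(ref.DOSES_TD, ref.DOSES_DYNAMIC_SINGLE)
    assert r == pytest.approx(0.9666, abs=5e-4)
    brain = table.set_index("organ").loc["brain", "percent_deviation"]
    assert brain == pytest.approx(72.0, abs=0.5)


def test_comparison_requires_three_shared_organs():
    with pytest.raises(ValueError):
        compare_methods({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
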