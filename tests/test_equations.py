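"""Prediction equations, ideal body weight, and modality correction."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vo2compare.equations import (
    EquationDomainError,
    apply_mode_correction,
    ideal_body_weight,
    predict_all,
    predict_vo2,
)
from vo2compare.registry import (
    CANONICAL_IDS,
    RegistryError,
    default_registry,
    load_equation_registry,
    write_registry,
)
from vo2compare.subjects import Subject


@pytest.mark.parametrize(
    "sex, height, expected",
    [
        ("male", 170.18, 73.74),
        ("male", 180.0, 81.5),
        ("female", 160.0, 61.2),
    ],
)
def test_ideal_body_weight(sex, height, expected):
    assert ideal_body_weight(sex, height) == pytest.approx(expected, abs=0.005)


def test_ideal_body_weight_rejects_nonpositive_result():
    with pytest.raises(EquationDomainError, match="70"):
        ideal_body_weight("male", 70.0)


def test_wasserman_native_cycle_value(registry, case_subject):
    """Weight × (50.72 − 0.372·age) for the 37-year-old 127-kg man."""
    pred = predict_vo2(registry["wasserman"], case_subject)
    assert pred.native_value == pytest.approx(4693.6, abs=0.5)


def test_friend_native_treadmill_value(registry, case_subject):
    """Imperial-units registry equation: 24.45 mL/kg/min × 127.006 kg."""
    pred = predict_vo2(registry["friend"], case_subject)
    assert pred.native_value == pytest.approx(3105.3, abs=0.5)


@pytest.mark.parametrize("sex, height", [("male", 176.5), ("female", 163.0)])
def test_hansen_equals_wasserman_at_ideal_weight(registry, sex, height):
    """The over/underweight branches collapse when weight equals ideal."""
    ibw = ideal_body_weight(sex, height)
    subj = Subject(
        id="x", age=50, sex=sex, height=height, weight=ibw, mode="cycle",
        measured_vo2=2000.0,
    )
    hansen = predict_vo2(registry["hansen"], subj).native_value
    wasserman = predict_vo2(registry["wasserman"], subj).native_value
    assert hansen == pytest.approx(wasserman, rel=1e-12)


def test_hansen_continuous_across_branch_point(registry):
    """Prediction is continuous in weight at the ideal-weight kink."""
    ibw = ideal_body_weight("male", 176.5)
    values = []
    for w in (ibw - 1e-6, ibw, ibw + 1e-6):
        subj = Subject(
            id="x", age=50, sex="male", height=176.5, weight=w, mode="cycle",
            measured_vo2=2000.0,
        )
        values.append(predict_vo2(registry["hansen"], subj).native_value)
    assert values[0] == pytest.approx(values[1], abs=1e-3)
    assert values[2] == pytest.approx(values[1], abs=1e-3)


class TestModeCorrection:
    def test_cycle_equation_on_treadmill_test(self):
        corrected, factor = apply_mode_correction(4693.6, "cycle", "treadmill")
        assert factor == 1.11
        assert corrected == pytest.approx(5209.9, abs=0.05)

    def test_matching_modes_identity(self):
        corrected, factor = apply_mode_correction(1234.5, "treadmill", "treadmill")
        assert (corrected, factor) == (1234.5, 1.0)

    def test_treadmill_equation_on_cycle_test(self):
        corrected, factor = apply_mode_correction(1000.0, "treadmill", "cycle")
        assert factor == 0.89
        assert corrected == pytest.approx(890.0)

    def test_rejects_nonpositive_value(self):
        with pytest.raises(EquationDomainError):
            apply_mode_correction(0.0, "cycle", "treadmill")


def test_predict_all_six_entries_and_factors(registry, case_subject):
    preds = predict_all(registry, case_subject)
    assert tuple(preds) == CANONICAL_IDS
    assert preds["wasserman"].corrected_value == pytest.approx(5209.9, abs=0.05)
    assert all(p.correction_applied in (1.0, 1.11, 0.89) for p in preds.values())
    # modality-specific equations are never corrected
    assert preds["friend"].correction_applied == 1.0
    assert preds["hansen"].correction_applied == 1.0


def test_predict_all_deterministic(registry, case_subject):
    a = predict_all(registry, case_subject)
    b = predict_all(registry, case_subject)
    assert a == b


def test_predict_all_missing_equation_raises(registry, case_subject):
    partial = {k: v for k, v in registry.items() if k != "neder"}
    with pytest.raises(RegistryError, match="neder"):
        predict_all(partial, case_subject)


def test_mode_dependence_is_only_the_correction_factor(registry, make_subject):
    """For non-modality-specific equations the treadmill and cycle results
    differ exactly by the ×1.11 / ×0.89 factors."""
    tread = predict_all(registry, make_subject(mode="treadmill"))
    cycle = predict_all(registry, make_subject(mode="cycle"))
    for eq_id in ("wasserman", "jones", "neder"):  # cycle-native
        assert tread[eq_id].corrected_value == pytest.approx(
            cycle[eq_id].corrected_value * 1.11, rel=1e-12
        )
    assert cycle["bruce"].corrected_value == pytest.approx(
        tread["bruce"].corrected_value * 0.89, rel=1e-12
    )


# Realistic joint domain: weight tied to height through BMI 18-38. The
# FRIEND linear form predicts negative values for extreme (short, very
# heavy) combinations outside this region, which the evaluator rejects
# with a domain error rather than returning a negative prediction.
@st.composite
def _subjects(draw):
    height = draw(st.floats(150, 195))
    bmi = draw(st.floats(18, 38))
    return Subject(
        id="h",
        age=draw(st.floats(20, 67)),
        sex=draw(st.sampled_from(["male", "female"])),
        height=height,
        weight=bmi * (height / 100.0) ** 2,
        mode=draw(st.sampled_from(["treadmill", "cycle"])),
        measured_vo2=2000.0,
    )


_subject_strategy = _subjects()


@settings(deadline=None, max_examples=60)
@given(subject=_subject_strategy)
def test_predictions_positive_and_finite(subject):
    registry = default_registry()
    for pred in predict_all(registry, subject).values():
        assert pred.corrected_value > 0
        assert pred.corrected_value < 1e5


@settings(deadline=None, max_examples=40)
@given(
    subject=_subject_strategy,
    younger=st.floats(20, 60),
    delta=st.floats(0.5, 7),
)
def test_all_equations_non_increasing_in_age(subject, younger, delta):
    registry = default_registry()
    young = dataclasses.replace(subject, age=younger)
    old = dataclasses.replace(subject, age=min(younger + delta, 67))
    py = predict_all(registry, young)
    po = predict_all(registry, old)
    for eq_id in CANONICAL_IDS:
        assert po[eq_id].corrected_value <= py[eq_id].corrected_value + 1e-9
    # FRIEND is strictly decreasing (negative age coefficient)
    assert po["friend"].corrected_value < py["friend"].corrected_value


class TestRegistryIO:
    def test_default_registry_has_expected_modality_structure(self, registry):
        assert set(registry) == set(CANONICAL_IDS)
        assert set(registry["friend"].native_modes) == {"treadmill", "cycle"}
        assert set(registry["hansen"].native_modes) == {"treadmill", "cycle"}
        for eq_id in ("wasserman", "bruce", "jones", "neder"):
            assert len(registry[eq_id].native_modes) == 1

    def test_round_trip_predictions_identical(self, registry, tmp_path, make_subject):
        path = tmp_path / "registry.yaml"
        write_registry(registry, path)
        reloaded = load_equation_registry(path)
        subjects = [make_subject(id=f"s{i}", age=30 + i, weight=70 + 3 * i) for i in range(5)]
        for subj in subjects:
            a = predict_all(registry, subj)
            b = predict_all(reloaded, subj)
            for eq_id in CANONICAL_IDS:
                assert a[eq_id].corrected_value == b[eq_id].corrected_value

    def test_partial_override_changes_only_that_equation(self, registry, tmp_path, make_subject):
        path = tmp_path / "override.yaml"
        path.write_text(
            "bruce:\n"
            "  form: per_kg_linear\n"
            "  native_modes: [treadmill]\n"
            "  coefficients:\n"
            "    male: {intercept: 60.0, age: -0.5}\n"
            "    female: {intercept: 45.0, age: -0.4}\n"
        )
        merged = load_equation_registry(path)
        subj = make_subject()
        base = predict_all(registry, subj)
        new = predict_all(merged, subj)
        assert new["bruce"].corrected_value != base["bruce"].corrected_value
        for eq_id in CANONICAL_IDS:
            if eq_id != "bruce":
                assert new[eq_id].corrected_value == base[eq_id].corrected_value

    def test_unknown_units_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "bruce:\n"
            "  form: per_kg_linear\n"
            "  native_modes: [treadmill]\n"
            "  weight_units: stone\n"
            "  coefficients: {male: {intercept: 60.0}}\n"
        )
        with pytest.raises(RegistryError, match="stone"):
            load_equation_registry(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.yaml"
        block = (
            "  form: per_kg_linear\n"
            "  native_modes: [treadmill]\n"
            "  coefficients: {male: {intercept: 60.0}}\n"
        )
        path.write_text(f"bruce:\n{block}bruce:\n{block}")
        with pytest.raises(RegistryError, match="duplicate"):
            load_equation_registry(path)

    def test_out_of_source_age_range_warns_not_fails(self, registry):
        subj = Subject(
            id="young", age=24, sex="male", height=175.0, weight=80.0,
            mode="cycle", measured_vo2=2500.0,
        )
        pred = predict_vo2(registry["wasserman"], subj)  # source range 34-74
        assert pred.native_value > 0
        assert any("source range" in w for w in pred.warnings)
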