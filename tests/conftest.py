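import pytest

from vo2compare import default_params, default_registry, simulate_cohort, subjects_from_frame
from vo2compare.subjects import Subject, worked_case_subject


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def case_subject():
    """The 37-year-old male treadmill case (67 in, 280 lb, 3560 mL/min)."""
    return worked_case_subject()


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic 60-subject cohort used by structural pipeline tests."""
    frame = simulate_cohort(default_params(n=60, seed=11))
    return subjects_from_frame(frame)


@pytest.fixture()
def make_subject():
    def _make(**kwargs):
        defaults = dict(
            id="s1",
            age=44,
            sex="male",
            height=175.3,
            weight=95.9,
            mode="treadmill",
            measured_vo2=2380.0,
        )
        defaults.update(kwargs)
        return Subject(**defaults)

    return _make
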