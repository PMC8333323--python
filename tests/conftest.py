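import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def marginal_counts():
    from gmdhscreen.fixtures import load_marginal_counts

    return load_marginal_counts("all")


@pytest.fixture(scope="session")
def performance_table():
    from gmdhscreen.fixtures import load_performance_table

    return load_performance_table()


@pytest.fixture
def record_factory():
    """Build a complete questionnaire record with overridable fields."""
    from gmdhscreen.schema import QuestionnaireRecord

    def make(**overrides):
        base = dict(
            subject_id="s1",
            q1="never", q2="never", q3="never", q4="never", q5="never",
            q6="no", q7="never",
            age_years=12, sleep_hours=9.0, screen_hours=2.0,
            weight_kg=40.0, height_cm=150.0, waist_cm=60.0,
            birth_weight_g=3200.0, family_size=4, n_close_friends=3,
            life_satisfaction=8, breakfast_days_per_week=7,
            body_image_5="about_right", sex="boy", residence="urban",
            smoker="no", salty_snack="weekly", sweetened_beverage="weekly",
            fast_food="seldom_never", mother_education="diploma",
            milk_type="mother_milk", diet_plan="no", fh_sudden_death="no",
            fh_cancer="no", bmi_category="healthy", srh="good",
            ses="moderate", physical_activity="moderate",
        )
        base.update(overrides)
        return QuestionnaireRecord(**base)

    return make


@pytest.fixture
def item_frame_factory():
    """DataFrame of the seven items from per-subject level tuples."""

    def make(rows):
        return pd.DataFrame(
            rows, columns=["q1", "q2", "q3", "q4", "q5", "q6", "q7"]
        )

    return make
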