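import numpy as np
import pytest

from strokemap.behavior import BatteryTable, PromaxPCA, deficit_transform, zscore_columns
from strokemap.synthetic import SimulationConfig, generate_cohort, make_atlas


def as_battery_table(cfg: SimulationConfig, battery_df) -> BatteryTable:
    return BatteryTable(
        subject_ids=list(battery_df["subject_id"]),
        subtest_names=cfg.subtest_names,
        scores=battery_df[cfg.subtest_names].to_numpy(float),
        maxima=cfg.subtest_maxima,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort (60 subjects, 20x24x20 grid) shared by unit tests."""
    cfg = SimulationConfig(grid_shape=(20, 24, 20), n_subjects=60, seed=3)
    cohort, battery, truth = generate_cohort(cfg)
    return cfg, cohort, battery, truth


@pytest.fixture(scope="session")
def toy_atlas():
    return make_atlas((12, 14, 12))


@pytest.fixture(scope="session")
def study_assets():
    """Full study-condition cohort (n=200, 40x48x40, noise 0.1) + fitted reduction."""
    cfg = SimulationConfig(seed=1)
    cohort, battery, truth = generate_cohort(cfg)
    bt = as_battery_table(cfg, battery)
    dm = zscore_columns(deficit_transform(bt))
    model = PromaxPCA(n_components=3).fit(dm.values)
    return {
        "cfg": cfg,
        "cohort": cohort,
        "battery": battery,
        "truth": truth,
        "deficit_matrix": dm,
        "model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
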