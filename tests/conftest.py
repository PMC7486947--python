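import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beringmse import opmodel as om
from beringmse import policy as pol
from beringmse import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """The full synthetic study fixture (seed 0)."""
    return syn.make_study_fixture()


@pytest.fixture(scope="session")
def toy():
    return syn.make_toy_worked_example()


@pytest.fixture(scope="session")
def refpoints(study):
    """Unfished B0 and the two-phase F_target solve on the study fixture."""
    pers = study.forcing["persistence"]
    _, b0 = om.project_unfished(
        study.species_cfgs, study.pred_cfg, study.true_recruitment, pers
    )
    f_target = pol.solve_F_target(
        study.species_cfgs,
        study.pred_cfg,
        study.true_recruitment,
        pers,
        b0,
        joint_species=("pollock", "pcod"),
        fixed_species="arrowtooth",
        fixed_species_hist_f=syn.ARROWTOOTH_HIST_F,
    )
    return b0, f_target


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def truncate_series(series, n_years):
    """First n_years of a climate series, for short-horizon tests."""
    from beringmse.forcing import ClimateIndexSeries

    return ClimateIndexSeries(
        series.scenario_id,
        series.years[:n_years],
        {k: v[:n_years] for k, v in series.indices.items()},
    )
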