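import pytest

from vmrlearn import synth, task


@pytest.fixture(scope="session")
def schedule():
    return task.TaskSchedule()


@pytest.fixture(scope="session")
def noiseless_go_epochs():
    """Noiseless go-cue epoch sets with planted ERD of 0/50/80%.

    Generated at 500 Hz to keep the suite fast; the analysis windows and
    1-Hz resolution are unchanged.
    """
    out = {}
    for planted in (0.0, 50.0, 80.0):
        gt = synth.GroundTruth(
            alpha_erd_pct={"late_adapt": planted},
            beta_erd_pct={"late_adapt": planted},
            frn_uv={"late_adapt": -3.0},
        )
        out[planted] = synth.generate_go_epochs(
            gt, "late_adapt", n_trials=20, noise_sd_uv=0.0, seed=7, srate=500.0
        )
    return out


@pytest.fixture(scope="session")
def noiseless_fb_epochs():
    """Noiseless feedback epoch sets with planted FRN of 0 and -3 uV."""
    out = {}
    labels = ["success"] * 10 + ["failure"] * 10
    for planted in (0.0, -3.0):
        gt = synth.GroundTruth(
            alpha_erd_pct={"late_adapt": 50.0},
            beta_erd_pct={"late_adapt": 50.0},
            frn_uv={"late_adapt": planted},
        )
        out[planted] = synth.generate_feedback_epochs(
            gt, "late_adapt", labels, noise_sd_uv=0.0, seed=7, srate=500.0
        )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    return task.simulate_cohort(n_per_group=4, seed=11)
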