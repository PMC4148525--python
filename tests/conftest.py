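import numpy as np
import pandas as pd
import pytest

from valuechoice import prospect, synthetic


@pytest.fixture(scope="session")
def schedule():
    """Default-sized task schedule (3 x 70 trials, blocks of 10)."""
    return synthetic.generate_schedule(seed=1)


@pytest.fixture(scope="session")
def small_schedule():
    """Compact schedule (3 x 10 trials) for cheap unit tests."""
    return synthetic.generate_schedule(n_per_condition=10, seed=2)


@pytest.fixture(scope="session")
def agent_params():
    return prospect.ProspectParams(alpha=0.9, gamma=0.8, tau=0.1)


@pytest.fixture(scope="session")
def dataset(schedule, agent_params):
    """Simulated softmax chooser on the default schedule."""
    return synthetic.simulate_agent(schedule, agent_params, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_schedule, agent_params):
    return synthetic.simulate_agent(small_schedule, agent_params, seed=4)


def make_trials(rows):
    """Hand-rolled minimal choice dataset from (ml, pl, mr, pr, choice) tuples."""
    n = len(rows)
    df = pd.DataFrame(
        rows, columns=["magnitude_left", "probability_left",
                       "magnitude_right", "probability_right", "choice"]
    )
    df["condition"] = "middle"
    df["block_index"] = 0
    df["trial_index"] = np.arange(n)
    df["is_nobrainer"] = False
    df["display_mode"] = "magnitude_as_bar"
    df["stimulus_onset_s"] = 10.0 + 20.0 * np.arange(n)
    df["planned_outcome_delay_s"] = 4.0
    df["planned_iti_s"] = 4.0
    df["reaction_time_s"] = np.where(df["choice"].isin(["left", "right"]), 1.0, np.nan)
    df["outcome_left"] = False
    df["outcome_right"] = True
    ev_l = df["magnitude_left"] * df["probability_left"]
    ev_r = df["magnitude_right"] * df["probability_right"]
    left = df["choice"] == "left"
    df["chosen_value"] = np.where(left, ev_l, ev_r)
    df["unchosen_value"] = np.where(left, ev_r, ev_l)
    df.loc[~df["choice"].isin(["left", "right"]), ["chosen_value", "unchosen_value"]] = np.nan
    return df
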