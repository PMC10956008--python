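import numpy as np
import pytest

from sfnowcast import lstm, synthetic, windowing
from sfnowcast.windowing import WindowSample


@pytest.fixture(scope="session")
def informative_scenario():
    """One-state default informative world, generated once per session."""
    cfg = synthetic.ScenarioConfig(states=["AA"], seed=1)
    panels, truths = synthetic.generate_scenario(cfg)
    return cfg, panels["AA"], truths["AA"]


@pytest.fixture(scope="session")
def informative_panel(informative_scenario):
    return informative_scenario[1]


@pytest.fixture(scope="session")
def four_state_scenario():
    cfg = synthetic.ScenarioConfig(seed=7)
    panels, truths = synthetic.generate_scenario(cfg)
    return cfg, panels, truths


def linear_target_samples(n=20, w=2, n_features=1, coef=3.0, scale=0.1, seed=42):
    """Deterministic tiny dataset: target = coef * (sum of features)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        f = rng.uniform(0, scale, size=(w, n_features))
        out.append(WindowSample(features=f, target_week=(2016, (k % 52) + 1),
                                target=coef * float(f.sum()),
                                feature_names=[f"x{i}" for i in range(n_features)]))
    return out


@pytest.fixture(scope="session")
def trained_all_sources(informative_panel):
    """all_sources model trained once and shared by read-only tests."""
    samples = lstm.build_feature_set(informative_panel, lstm.get_combination("all_sources"))
    train, val, test = windowing.split_windows(samples)
    model = lstm.fit_nowcaster(lstm.NowcastConfig(seed=3), train, val)
    return model, train, val, test
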