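import pytest

from groomstats import EffectConfig, GroupConfig, generate_group, simulate_study


@pytest.fixture(scope="session")
def full_study():
    """A 17-female, two-season study at the default observation design."""
    cfg = GroupConfig(seed=1)
    roster, truth = generate_group(cfg)
    events, scans, sessions = simulate_study(roster, truth, EffectConfig(), cfg)
    return {
        "config": cfg,
        "roster": roster,
        "truth": truth,
        "events": events,
        "scans": scans,
        "sessions": sessions,
    }


@pytest.fixture(scope="session")
def small_study():
    """A fast 8-female, one-season study for I/O and unit tests."""
    cfg = GroupConfig(
        n_females=8,
        matriline_sizes=[3, 3, 2],
        seasons=1,
        focal_hours_per_female=10.0,
        seed=7,
    )
    roster, truth = generate_group(cfg)
    events, scans, sessions = simulate_study(roster, truth, EffectConfig(), cfg)
    return {
        "config": cfg,
        "roster": roster,
        "truth": truth,
        "events": events,
        "scans": scans,
        "sessions": sessions,
    }
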