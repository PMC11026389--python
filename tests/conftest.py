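import numpy as np
import pytest

from perceptography import Campaign, CampaignConfig, ImageSpace, percept_alignment


@pytest.fixture(scope="session")
def image_space():
    return ImageSpace()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def run_replicate(master_seed: int, **overrides) -> Campaign:
    cfg = CampaignConfig(master_seed=master_seed, **overrides)
    camp = Campaign(cfg).run()
    camp.compact()
    return camp


def winner_alignment(camp: Campaign) -> float | None:
    """Cosine between the winner's percept change and the hidden template."""
    if camp.winner is None:
        return None
    seed_id = camp.store.seed_of[camp.winner]
    return percept_alignment(
        camp.observer,
        camp.site,
        camp.store.raster(seed_id),
        camp.store.raster(camp.winner),
    )


def session_miss_rate(camp: Campaign) -> float:
    stim = [r for r in camp.records if r.stimulated and r.outcome != "aborted"]
    return sum(r.outcome == "miss" for r in stim) / len(stim)


@pytest.fixture(scope="session")
def campaign_replicates():
    """Ten replicate campaigns at the default (3 mW) study conditions."""
    return [run_replicate(seed) for seed in range(1, 11)]


@pytest.fixture(scope="session")
def low_intensity_replicates():
    """The same ten campaigns re-run at 1 mW (matched seeds and sites)."""
    return [run_replicate(seed, intensity_mw=1.0) for seed in range(1, 11)]
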