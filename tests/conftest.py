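import warnings

import numpy as np
import pytest

from placeseq import AnalysisConfig, TuningModel, compute_rate_map, day_average_map
from placeseq.synthetic import make_day, preset

warnings.filterwarnings("ignore", category=UserWarning)


def build_day_maps(session, cfg):
    maps = {}
    for u in session.place_cell_units():
        ms = [compute_rate_map(u, session.position, ep, cfg,
                               session_label=ep.label)
              for ep in session.epochs("run")]
        maps[u.unit_id] = day_average_map(ms, cfg)
    return maps


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig(rng_seed=11)


@pytest.fixture(scope="session")
def wt_bundle(cfg):
    """A wild-type-like synthetic day (short epochs) with day maps and a
    tuning model; shared across tests that only read from it."""
    session = make_day(preset("wt", seed=11), run_duration_s=60,
                       rest_duration_s=60)
    maps = build_day_maps(session, cfg)
    model = TuningModel.from_day_maps(maps, cfg)
    return session, maps, model


@pytest.fixture(scope="session")
def precession_bundle(cfg):
    """A phase-precession-mode day (no scripted sweep), ~10 laps per run."""
    from placeseq.synthetic import GroundTruth

    session = make_day(GroundTruth(rng_seed=3), run_duration_s=92.5,
                       rest_duration_s=5)
    maps = build_day_maps(session, cfg)
    return session, maps
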