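import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import emspop
from emspop import calling

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

#: RH window/step scaled to the 2 Mb simulated genome (the field-scale
#: defaults assume a ~100 Mb capture space).
SIM_RH_WINDOW = 30_000
SIM_RH_STEP = 15_000


@pytest.fixture(scope="session")
def default_sim():
    """One simulated population under default study-like conditions."""
    cfg = emspop.SimConfig(seed=1)
    truth, obs, reference = emspop.simulate_population(cfg)
    return cfg, truth, obs, reference


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    """Full post-processing pipeline run on the default population."""
    _, _, obs, _ = default_sim
    return emspop.run_pipeline(
        obs, rh_window_bp=SIM_RH_WINDOW, rh_step_bp=SIM_RH_STEP
    )


def make_calls(
    n_ems=0,
    n_nonems=0,
    n_transversion=0,
    het_fraction=1.0,
    line_id="L0001",
    start_pos=1000,
    max_tier=3,
    seed=0,
):
    """Small classified call frame with a controlled class/zygosity mix."""
    rng = np.random.default_rng(seed)
    changes = (
        [("G", "A")] * n_ems + [("A", "G")] * n_nonems + [("G", "C")] * n_transversion
    )
    n = len(changes)
    zyg = np.where(rng.random(n) < het_fraction, "het", "hom")
    frame = pd.DataFrame(
        {
            "line_id": line_id,
            "contig": "sim1",
            "pos": np.arange(start_pos, start_pos + n),
            "ref": [c[0] for c in changes],
            "alt": [c[1] for c in changes],
            "alt_depth": 10,
            "wt_depth": np.where(zyg == "het", 10, 0),
        }
    )
    frame = calling.classify_frame(frame)
    frame["zygosity"] = zyg
    frame["provisional_zygosity"] = zyg
    frame["max_tier"] = max_tier
    return frame
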