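import numpy as np
import pytest

import phantomcoupling as pc


@pytest.fixture(scope="session")
def leadfield16():
    return pc.toy_leadfield(n_sources=16)


@pytest.fixture(scope="session")
def operator16(leadfield16):
    return pc.build_sloreta_operator(leadfield16)


def simulate_subject_roi(
    mod_depth: float,
    seed: int,
    duration_s: float = 180.0,
    snr_db: float = 60.0,
    leadfield=None,
    operator=None,
    roi_indices=(0, 1),
):
    """Full forward+inverse path to the planted-coupling ROI time series:
    simulate planted sources, project to 19 sensors, invert, normalize
    per-sample power, extract the ROI spanning the theta carrier and the
    modulated gamma source (a region where both rhythms coexist, so the
    theta component's sign is pinned by the theta source's own
    reconstruction rather than by geometry-dependent leakage)."""
    cfg = pc.CouplingConfig(
        mod_depth=mod_depth,
        snr_db=snr_db,
        duration_s=duration_s,
        rate_hz=128.0,
        seed=seed,
    )
    lf = leadfield if leadfield is not None else pc.toy_leadfield(cfg.n_sources)
    op = operator if operator is not None else pc.build_sloreta_operator(lf)
    sim = pc.simulate_subject_sources(cfg)
    rec = pc.project_to_sensors(sim, lf, cfg.snr_db, seed=cfg.seed + 1)
    # nesting runs on raw standardized currents: the per-sample power
    # normalization applies a common time-varying gain to both bands and
    # would itself induce a small spurious theta-envelope coupling
    sc = pc.apply_inverse(op, rec)
    return pc.roi_timeseries(sc, pc.ROIDefinition("nesting_roi", tuple(roi_indices)))
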