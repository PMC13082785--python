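import numpy as np
import pytest

from shhtrack.tracks import Cohort, Track


def make_track(
    cell_id="c0",
    t=None,
    response=None,
    fate_ch=None,
    sat=None,
    fate="unknown",
    region="",
    lmdv=None,
    ap=None,
    z=None,
):
    """Small helper for hand-built tracks."""
    t = np.asarray(t if t is not None else 10.0 + 0.1 * np.arange(10), dtype=float)
    n = t.size
    response = np.asarray(response if response is not None else np.ones(n), dtype=float)
    intensity = {"response": response}
    sat_frac = {"response": np.asarray(sat if sat is not None else np.zeros(n), dtype=float)}
    if fate_ch is not None:
        intensity["fate"] = np.asarray(fate_ch, dtype=float)
        sat_frac["fate"] = np.zeros(n)
    return Track(
        cell_id=cell_id,
        t=t,
        pos_lmdv=np.asarray(lmdv if lmdv is not None else np.zeros(n), dtype=float),
        pos_ap=np.asarray(ap if ap is not None else np.zeros(n), dtype=float),
        pos_z=np.asarray(z if z is not None else np.zeros(n), dtype=float),
        intensity=intensity,
        sat_frac=sat_frac,
        fate=fate,
        region=region,
    )


@pytest.fixture
def small_cohort():
    tracks = [
        make_track("a", response=np.linspace(1, 5, 10), fate="LFP"),
        make_track("b", response=np.linspace(0.5, 2, 10), fate="pMN"),
    ]
    return Cohort(tracks)


@pytest.fixture(scope="session")
def anterior_zero_noise():
    """Zero-noise anterior cohort with ground truth (shared across tests)."""
    from shhtrack.simulate import anterior_like, generate_cohort, zero_noise

    return generate_cohort(zero_noise(anterior_like()), seed=7)
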