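import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import cropwater as cw

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

SEASON_START = dt.date(2022, 5, 25)
SEASON_END = dt.date(2022, 11, 5)


def season_dates():
    n = (SEASON_END - SEASON_START).days + 1
    return [SEASON_START + dt.timedelta(days=i) for i in range(n)]


def make_profile(name="chia", **overrides):
    kwargs = dict(
        name=name,
        season_start=SEASON_START,
        season_end=SEASON_END,
        et_base=2.0,
        et_peak_amplitude=2.6,
        wue_base=2.3,
    )
    kwargs.update(overrides)
    return cw.CropProfile(**kwargs)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, gap-free two-crop scene: pipeline output must be exact."""
    chia = make_profile("chia", pixel_noise_sd=0.0, missing_day_rate=0.0)
    alfalfa = make_profile(
        "alfalfa", et_base=2.6, et_peak_amplitude=3.2, wue_base=2.0,
        pixel_noise_sd=0.0, missing_day_rate=0.0,
    )
    return cw.generate_site_season(
        [chia, alfalfa], cw.RasterGrid(11, 11), season_dates(), seed=0
    )


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene with revisit gaps, all four study crops."""
    profiles = cw.default_profiles()
    return cw.generate_site_season(profiles, cw.RasterGrid(11, 11), season_dates(), seed=1)


@pytest.fixture(scope="session")
def noisy_flux(noisy_scene):
    return cw.scene_to_flux(noisy_scene)
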