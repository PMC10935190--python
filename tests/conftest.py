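"""Shared fixtures: synthetic campaigns at two scales.

The small campaign keeps per-module tests fast; the full-scale campaign
(610 + 330 ears, three instruments, three replicate scans) reproduces the
design of the two-season field study and backs the end-to-end checks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

import silagescan as ss
from silagescan.spectra import from_frame

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def campaign_to_sets(spectra_df, ref_df):
    """Split simulator output into (SpectraSet, reference frame indexed by ear)."""
    s = from_frame(spectra_df)
    ref = ref_df.set_index("ear_id")
    return s, ref


@pytest.fixture(scope="session")
def small_campaign():
    """Two scaled-down seasons (80 + 50 ears), three default instruments."""
    seasons = [
        replace(ss.season_preset(2021), n_plants=80),
        replace(ss.season_preset(2022), n_plants=50),
    ]
    spectra, ref = ss.simulate_campaign(seasons, ss.default_profiles(), seed=7)
    return campaign_to_sets(spectra, ref)


@pytest.fixture(scope="session")
def full_campaign():
    """The full two-season design: 610 calibration + 330 validation ears."""
    seasons = [ss.season_preset(2021), ss.season_preset(2022)]
    spectra, ref = ss.simulate_campaign(seasons, ss.default_profiles(), seed=20210827)
    return campaign_to_sets(spectra, ref)


def split_seasons(s, ref):
    """(calibration SpectraSet, validation SpectraSet) by season label."""
    cal_ears = set(ref.index[ref.season == "2021"])
    mask = s.keys["ear_id"].isin(cal_ears).to_numpy()
    return s.select(mask), s.select(~mask)
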