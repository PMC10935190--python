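"""Synthetic NIR ear-scan campaigns.

Generates paired (whole-plant moisture, ear moisture, multi-instrument
reflectance spectra) datasets with the statistical structure of a two-season
standing-corn survey: whole-plant moisture (WP, %w.b.) drawn from a truncated
normal, ear moisture (EM, %w.b.) tied to WP through the quadratic
EM = 0.028·WP² − 2.24·WP + 78.3 plus biological scatter, oven references
perturbed by the laboratory error (SEL), and absorbance spectra built from
water and dry-matter Gaussian bands so that absorbance is affine in moisture
fraction when all noise terms are off.

Each simulated spectrometer carries its own signature (wavelength shift, gain,
baseline offset, noise), large enough to induce the cross-instrument bias a
calibration-transfer experiment is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .chain import ear_from_wholeplant

__all__ = [
    "InstrumentProfile",
    "SeasonConfig",
    "GaussianBand",
    "SpectralSceneConfig",
    "make_wavelength_grid",
    "sample_season",
    "render_spectrum",
    "simulate_campaign",
    "default_profiles",
    "season_preset",
    "DEFAULT_SCENE",
]

REFLECTANCE_FLOOR = 1e-6


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class InstrumentProfile:
    """Signature of one simulated handheld spectrometer.

    wavelength_shift is in nm (the instrument reports band positions offset by
    this amount), gain multiplies absorbance, baseline_offset adds to it, and
    noise_sd is the per-scan absorbance noise.

    em_response_gain/em_response_offset distort the moisture the instrument's
    optics effectively sample (em_eff = gain·em + offset, %w.b.): collection
    geometry differences make one unit see systematically wetter or drier
    ear volumes than another.  Unlike photometric gain or a wavelength shift —
    both largely removed by derivative pretreatment and swamped by per-sample
    scatter — this distortion is collinear with the moisture signal, so it
    survives preprocessing and produces the cross-instrument prediction bias
    a transfer experiment exposes.
    """

    instrument_id: int
    wavelength_shift: float = 0.0
    gain: float = 1.0
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    em_response_gain: float = 1.0
    em_response_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.em_response_gain <= 0:
            raise ConfigError("gains must be > 0")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SeasonConfig:
    """One season's sampling design and reference-method error structure.

    Moisture units are %w.b. throughout.  ``em_residual_sd`` is the biological
    scatter of ear moisture about the quadratic EM–WP curve; ``sel`` is the
    oven reference error; ``scan_moisture_sd`` is the mismatch between the
    moisture the optical scan encodes (ear surface) and the whole-ear oven
    value, which sets the noise floor of any spectral calibration.
    """

    n_plants: int
    wp_mean: float
    wp_sd: float
    wp_min: float
    wp_max: float
    em_residual_sd: float = 3.2
    sel: float = 0.35
    scan_moisture_sd: float = 2.8
    n_replicates: int = 3
    label: str = ""

    def __post_init__(self) -> None:
        if not self.wp_min < self.wp_max:
            raise ConfigError("wp_min must be < wp_max")
        if min(self.wp_sd, self.em_residual_sd, self.sel, self.scan_moisture_sd) < 0:
            raise ConfigError("all SDs must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_plants < 1:
            raise ConfigError("n_plants must be >= 1")


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigError("band width must be > 0")


@dataclass(frozen=True)
class SpectralSceneConfig:
    """Physical scene the simulator renders.

    Absorbance = baseline + (em/100)·Σ water bands + (1−em/100)·Σ dry bands,
    then per-sample multiplicative/additive scatter and the instrument
    signature are applied.
    """

    water_bands: tuple[GaussianBand, ...] = (
        GaussianBand(1450.0, 60.0, 0.6),
        GaussianBand(1950.0, 80.0, 1.0),
    )
    dry_bands: tuple[GaussianBand, ...] = (
        GaussianBand(1730.0, 50.0, 0.25),
        GaussianBand(2100.0, 70.0, 0.35),
        GaussianBand(2270.0, 60.0, 0.30),
    )
    baseline_intercept: float = 0.25
    baseline_slope_per_nm: float = 5e-5
    scatter_multiplicative_sd: float = 0.05
    scatter_additive_sd: float = 0.02


DEFAULT_SCENE = SpectralSceneConfig()


def make_wavelength_grid(
    start_nm: float, end_nm: float, step_start: float, step_end: float
) -> np.ndarray:
    """Wavelength grid whose step grows linearly with wavelength.

    The local step at wavelength λ is
    ``step_start + (step_end − step_start)·(λ − start)/(end − start)``;
    the grid is built by stepping from ``start_nm`` until ``end_nm`` would be
    exceeded.  With (1350, 2550, 2.5, 8.8) this yields the 241-point grid of a
    scanning interferometer whose resolution degrades toward long wavelengths
    (average step 5 nm).
    """
    if step_start <= 0 or step_end <= 0:
        raise ConfigError("steps must be positive")
    if step_start > step_end:
        raise ConfigError("step_start must be <= step_end")
    if start_nm >= end_nm:
        raise ConfigError("start_nm must be < end_nm")
    span = end_nm - start_nm
    pts = [float(start_nm)]
    lam = float(start_nm)
    while True:
        step = step_start + (step_end - step_start) * (lam - start_nm) / span
        lam += step
        if lam > end_nm + 1e-9:
            break
        pts.append(lam)
    return np.asarray(pts)


def season_preset(year: int | str) -> SeasonConfig:
    """Built-in season presets emulating a two-year field survey.

    2021: 610 ears, EM ≈ mean 49 / SD 9.6 / range ~26–75.
    2022: 330 ears, WP range 55–81, EM ≈ mean 55 / SD 10.

    WP means/SDs are derived by inverting the EM–WP quadratic at the target EM
    statistics, correcting for curvature (a2·σ²) and truncation.
    """
    key = str(year)
    if key == "2021":
        return SeasonConfig(
            n_plants=610, wp_mean=62.5, wp_sd=6.9, wp_min=42.0, wp_max=85.0,
            label="2021",
        )
    if key == "2022":
        return SeasonConfig(
            n_plants=330, wp_mean=67.2, wp_sd=6.1, wp_min=55.0, wp_max=81.0,
            label="2022",
        )
    raise ConfigError(f"unknown season preset {year!r}")


def default_profiles() -> tuple[InstrumentProfile, ...]:
    """Three same-model instruments.

    Instrument 3 is the outlier: besides a wavelength shift (+3 nm) and
    photometric gain (1.03), its optics under-respond to moisture
    (em_response_gain 0.96) with a wet offset (+4.5 %w.b.), so
    single-instrument calibrations involving it transfer with a visible bias
    and a depressed slope; instrument 2 carries a mild dry offset.
    """
    return (
        InstrumentProfile(1, 0.0, 1.0, 0.0, 0.004),
        InstrumentProfile(2, 0.4, 0.995, 0.002, 0.004,
                          em_response_gain=1.0, em_response_offset=-1.5),
        InstrumentProfile(3, 3.0, 1.03, 0.01, 0.004,
                          em_response_gain=0.96, em_response_offset=4.5),
    )


def sample_season(cfg: SeasonConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one season of plants.

    Returns a frame with columns ``plant_id, wp_true, em_true, em_scan,
    em_oven, wp_oven``.  ``em_scan`` is the moisture value the spectrum will
    encode (em_true + scan mismatch); the oven columns carry the laboratory
    reference error.
    """
    a = (cfg.wp_min - cfg.wp_mean) / cfg.wp_sd if cfg.wp_sd > 0 else -np.inf
    b = (cfg.wp_max - cfg.wp_mean) / cfg.wp_sd if cfg.wp_sd > 0 else np.inf
    if cfg.wp_sd > 0:
        wp = truncnorm.rvs(
            a, b, loc=cfg.wp_mean, scale=cfg.wp_sd, size=cfg.n_plants,
            random_state=rng,
        )
    else:
        wp = np.full(cfg.n_plants, cfg.wp_mean)
    em_true = ear_from_wholeplant(wp) + rng.normal(0.0, cfg.em_residual_sd, cfg.n_plants)
    em_scan = em_true + rng.normal(0.0, cfg.scan_moisture_sd, cfg.n_plants)
    em_oven = em_true + rng.normal(0.0, cfg.sel, cfg.n_plants)
    wp_oven = wp + rng.normal(0.0, cfg.sel, cfg.n_plants)
    return pd.DataFrame(
        {
            "plant_id": np.arange(1, cfg.n_plants + 1),
            "wp_true": wp,
            "em_true": em_true,
            "em_scan": em_scan,
            "em_oven": em_oven,
            "wp_oven": wp_oven,
        }
    )


def _band_sum(grid: np.ndarray, bands: tuple[GaussianBand, ...]) -> np.ndarray:
    out = np.zeros_like(grid, dtype=float)
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((grid - b.center_nm) / b.width_nm) ** 2)
    return out


def clean_absorbance(
    em: float, scene: SpectralSceneConfig, profile: InstrumentProfile, grid: np.ndarray
) -> np.ndarray:
    """Noise-free absorbance as seen by ``profile`` for ear moisture ``em``.

    The instrument's wavelength shift is applied analytically (the bands are
    evaluated at λ − shift), so no interpolation artefacts enter.
    """
    lam = grid - profile.wavelength_shift
    base = scene.baseline_intercept + scene.baseline_slope_per_nm * (lam - grid[0])
    w = _band_sum(lam, scene.water_bands)
    d = _band_sum(lam, scene.dry_bands)
    em_eff = profile.em_response_gain * em + profile.em_response_offset
    f = em_eff / 100.0
    return profile.gain * (base + f * w + (1.0 - f) * d) + profile.baseline_offset


def render_spectrum(
    em: float,
    scene: SpectralSceneConfig,
    profile: InstrumentProfile,
    grid: np.ndarray,
    rng: np.random.Generator | None = None,
    scatter: bool = True,
) -> np.ndarray:
    """Render one reflectance spectrum for ear moisture ``em`` (%w.b.).

    Returns reflectance R = 10^(−A) in (0, 1], with per-sample multiplicative
    and additive scatter (if ``scatter``), instrument noise, and the
    instrument signature applied.  Deterministic when ``rng`` is None.
    """
    if not 0.0 < em < 100.0:
        raise ValueError(f"ear moisture must be in (0, 100) %w.b., got {em}")
    a = clean_absorbance(em, scene, profile, grid)
    if rng is not None:
        if scatter:
            mult = 1.0 + rng.normal(0.0, scene.scatter_multiplicative_sd)
            add = rng.normal(0.0, scene.scatter_additive_sd)
            a = mult * a + add
        if profile.noise_sd > 0:
            a = a + rng.normal(0.0, profile.noise_sd, grid.size)
    a = np.maximum(a, 0.0)  # reflectance must not exceed 1
    r = np.power(10.0, -a)
    return np.maximum(r, REFLECTANCE_FLOOR)


def simulate_campaign(
    season_cfgs: list[SeasonConfig] | tuple[SeasonConfig, ...],
    profiles: list[InstrumentProfile] | tuple[InstrumentProfile, ...],
    scene: SpectralSceneConfig = DEFAULT_SCENE,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full multi-season, multi-instrument scanning campaign.

    Emits one scan row per (ear, instrument, replicate).  Replicate scans of
    one ear on one instrument share the sample's scatter realization and
    differ only by instrument noise (the ear is re-presented, not re-grown).

    Returns ``(spectra, reference)``:

    * ``spectra`` — columns ``ear_id, instrument_id, replicate`` then one
      reflectance column per wavelength (header = nm with one decimal);
    * ``reference`` — ``ear_id, ear_moisture_wb, wholeplant_moisture_wb,
      season`` (oven values, i.e. what a laboratory would report).
    """
    if len(season_cfgs) < 1 or len(profiles) < 1:
        raise ConfigError("need at least one season and one instrument profile")
    ids = [p.instrument_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicate instrument ids: {ids}")
    if grid is None:
        grid = make_wavelength_grid(1350.0, 2550.0, 2.5, 8.8)
    rng = np.random.default_rng(seed)

    spec_rows: list[np.ndarray] = []
    keys: list[tuple[int, int, int]] = []
    ref_rows: list[dict] = []
    ear_offset = 0
    for cfg in season_cfgs:
        plants = sample_season(cfg, rng)
        for row in plants.itertuples(index=False):
            ear_id = ear_offset + int(row.plant_id)
            ref_rows.append(
                {
                    "ear_id": ear_id,
                    "ear_moisture_wb": row.em_oven,
                    "wholeplant_moisture_wb": row.wp_oven,
                    "season": cfg.label or "season1",
                }
            )
            em_scan = float(np.clip(row.em_scan, 1.0, 99.0))
            for prof in profiles:
                base = clean_absorbance(em_scan, scene, prof, grid)
                mult = 1.0 + rng.normal(0.0, scene.scatter_multiplicative_sd)
                add = rng.normal(0.0, scene.scatter_additive_sd)
                sample_a = mult * base + add
                for rep in range(1, cfg.n_replicates + 1):
                    a = sample_a + rng.normal(0.0, prof.noise_sd, grid.size)
                    r = np.maximum(np.power(10.0, -np.maximum(a, 0.0)), REFLECTANCE_FLOOR)
                    spec_rows.append(r)
                    keys.append((ear_id, prof.instrument_id, rep))
        ear_offset += cfg.n_plants

    wl_cols = [f"{w:.1f}" for w in grid]
    spectra = pd.DataFrame(spec_rows, columns=wl_cols)
    spectra.insert(0, "replicate", [k[2] for k in keys])
    spectra.insert(0, "instrument_id", [k[1] for k in keys])
    spectra.insert(0, "ear_id", [k[0] for k in keys])
    reference = pd.DataFrame(ref_rows)
    return spectra, reference
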