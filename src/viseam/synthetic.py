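"""Seeded synthetic pixel fixtures for testing and benchmarking.

Each pixel carries a gap-free phenology "truth" VI curve, an LAI series tied
to the truth through the saturating exponential VI = c - exp(a*LAI + b), a
contaminated observation series with MODIS-style quality codes, and a
reflectance series that reproduces the observations through the NDVI/EVI
formulas. This is a declared simulation: the double-logistic seasonal shape
and the contamination distributions are field-standard stand-ins, not claims
about MODIS statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .series import (
    EVI,
    NDVI,
    QA_CLOUD,
    QA_SNOW,
    SENTINEL,
    STEPS_PER_YEAR,
    LAISeries,
    QASeries,
    ReflectanceSeries,
    SeriesError,
    VISeries,
)

# default LAI<->VI couplings per stratum: VI = c - exp(a*LAI + b).
# The saturated coupling keeps LAI above 5 at moderate VI so the
# sample-builder's constrained-refit branch is exercised.
LAI_VI_STANDARD = (-0.6, -0.2, 0.95)
LAI_VI_SATURATED = (-0.35, 0.1, 0.95)


@dataclass
class PhenologyParams:
    """Double-logistic seasonal curve parameters (one growing season/year)."""

    base_vi: float = 0.15
    peak_vi: float = 0.85
    green_up_doy: float = 120.0
    senescence_doy: float = 280.0
    transition_steepness: float = 0.08  # per-day logistic rate
    inter_annual_jitter: float = 0.02  # sd of per-year peak amplitude jitter

    def __post_init__(self):
        if not (-0.2 < self.base_vi < self.peak_vi <= 1.0):
            raise SeriesError("require -0.2 < base_vi < peak_vi <= 1.0")


@dataclass
class ContaminationParams:
    """Cloud/snow/missing contamination model for one pixel."""

    cloud_fraction: float = 0.4
    cloud_run_length_mean: float = 3.0  # steps; geometric run lengths
    cloud_bias: float = -0.3  # mean negative VI bias under cloud (NDVI)
    cloud_noise_sd: float = 0.08
    evi_noise_sd: float = 0.1  # two-sided noise for EVI cloud steps
    snow_season: tuple[float, float] | None = None  # (start_doy, end_doy), wraps
    snow_vi_level: float = -0.05
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("cloud_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SeriesError(f"{name} must lie in [0,1]")


@dataclass
class SyntheticPixel:
    """One simulated pixel: truth, contaminated observation, LAI, reflectance."""

    truth_vi: VISeries
    observed_vi: VISeries
    lai: LAISeries
    reflectance: ReflectanceSeries
    qa: QASeries
    latitude: float
    index_kind: str
    params: dict = field(default_factory=dict)


def _doy_grid(n_years: int) -> np.ndarray:
    step = np.arange(n_years * STEPS_PER_YEAR)
    return 1.0 + 8.0 * (step % STEPS_PER_YEAR)


def invert_lai_vi(vi: np.ndarray, coeffs=LAI_VI_STANDARD) -> np.ndarray:
    """LAI such that c - exp(a*LAI + b) equals the given VI, clipped to [0,10]."""
    a, b, c = coeffs
    vi = np.minimum(np.asarray(vi, dtype=float), c - 1e-6)
    lai = (np.log(c - vi) - b) / a
    return np.clip(lai, 0.0, 10.0)


def generate_truth(
    p: PhenologyParams,
    n_years: int = 2,
    seed: int = 0,
    lai_coeffs=LAI_VI_STANDARD,
    index_kind: str = NDVI,
) -> tuple[VISeries, LAISeries]:
    """Gap-free double-logistic truth VI plus the LAI series implied by the
    saturating exponential coupling, 46 steps per year."""
    if n_years < 1:
        raise SeriesError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    doy = _doy_grid(n_years)
    k = p.transition_steepness
    season = 1.0 / (1.0 + np.exp(-k * (doy - p.green_up_doy))) - 1.0 / (
        1.0 + np.exp(-k * (doy - p.senescence_doy))
    )
    amp = p.peak_vi - p.base_vi
    jit = rng.normal(0.0, p.inter_annual_jitter, size=n_years) if p.inter_annual_jitter > 0 else np.zeros(n_years)
    per_step_amp = amp + np.repeat(jit, STEPS_PER_YEAR)
    vi = p.base_vi + np.clip(per_step_amp, 0.0, None) * season
    vi = np.clip(vi, -0.19, 1.0)
    lai = invert_lai_vi(vi, lai_coeffs)
    return VISeries(values=vi, index_kind=index_kind), LAISeries(values=lai)


def _snow_mask(c: ContaminationParams, n: int) -> np.ndarray:
    d0, d1 = c.snow_season
    doy = _doy_grid(n // STEPS_PER_YEAR)
    if d0 > d1:  # season wraps the year boundary
        return (doy >= d0) | (doy <= d1)
    return (doy >= d0) & (doy <= d1)


def apply_snow_to_truth(truth: VISeries, c: ContaminationParams) -> VISeries:
    """Depress the truth curve to the snow level inside the snow season.

    Long-lasting snow cover is a property of the surface, not an
    observation artefact: the true VI really is low, and a good
    reconstruction must retain it.
    """
    if c.snow_season is None:
        return truth
    mask = _snow_mask(c, len(truth))
    v = truth.values.copy()
    v[mask] = np.minimum(v[mask], c.snow_vi_level)
    return truth.with_values(v)


def contaminate(
    truth: VISeries, c: ContaminationParams
) -> tuple[VISeries, QASeries]:
    """Apply cloud runs, snow troughs and missing steps to a gap-free truth.

    NDVI cloud steps get a negative bias plus noise (qa=2); EVI cloud steps
    get two-sided zero-mean noise (qa=2); snow-season steps are depressed to
    near ``snow_vi_level`` (qa=3); ``missing_fraction`` of steps become the
    sentinel. All draws are seeded.
    """
    if not truth.is_valid.all():
        raise SeriesError("contaminate expects a gap-free truth series")
    rng = np.random.default_rng(c.seed)
    n = len(truth)
    obs = truth.values.copy()
    qa = np.zeros(n, dtype=np.int64)

    # geometric-length cloud runs until ~cloud_fraction of steps covered
    cloudy = np.zeros(n, dtype=bool)
    target = int(round(c.cloud_fraction * n))
    guard = 0
    while cloudy.sum() < target and guard < 20 * n:
        guard += 1
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / max(c.cloud_run_length_mean, 1.0)))
        cloudy[start : start + length] = True
    # trim overshoot so the realised fraction tracks the requested one
    excess = int(cloudy.sum()) - target
    if excess > 0:
        on = np.flatnonzero(cloudy)
        cloudy[rng.choice(on, size=excess, replace=False)] = False

    if truth.index_kind == NDVI:
        noise = rng.normal(c.cloud_bias, c.cloud_noise_sd, size=n)
        noise = np.minimum(noise, -0.01)  # clouds never brighten NDVI
        hi = 0.95
    else:
        noise = rng.normal(0.0, c.evi_noise_sd, size=n)
        hi = 0.9  # keep EVI inside the reflectance-invertible range
    obs[cloudy] = np.clip(obs[cloudy] + noise[cloudy], -0.19, hi)
    qa[cloudy] = QA_CLOUD

    if c.snow_season is not None:
        # snow genuinely covers the surface: the truth passed in is expected
        # to carry the trough already (see apply_snow_to_truth); observation
        # noise is small because snow reflectance is stable
        in_season = _snow_mask(c, n)
        snow_noise = rng.normal(0.0, 0.03, size=n)
        obs[in_season] = np.clip(
            truth.values[in_season] + snow_noise[in_season], -0.19, 0.95)
        qa[in_season] = QA_SNOW

    if c.missing_fraction > 0:
        n_miss = int(round(c.missing_fraction * n))
        miss = rng.choice(n, size=n_miss, replace=False)
        obs[miss] = SENTINEL
        qa[miss] = QA_CLOUD

    return truth.with_values(obs), QASeries(codes=qa)


def reflectance_from_vi(
    observed: VISeries, qa: QASeries | None = None, seed: int = 0
) -> ReflectanceSeries:
    """Per-step (red, nir, blue) whose NDVI/EVI reproduces the observation.

    NDVI: red+nir is drawn around 0.4 and the pair solved from the index.
    EVI: red/blue fixed at typical vegetated-surface values and NIR solved
    from the index formula. Sentinel steps get ``valid=False``. All
    reflectance stays inside [0, 1].
    """
    rng = np.random.default_rng(seed)
    v = observed.values
    n = v.size
    ok = observed.is_valid
    if observed.index_kind == NDVI:
        s = rng.uniform(0.3, 0.5, size=n)  # nir+red total brightness
        nir = s * (1.0 + v) / 2.0
        red = s * (1.0 - v) / 2.0
        blue = np.clip(0.5 * red + rng.normal(0.0, 0.005, size=n), 0.0, 1.0)
    else:
        # red absorption deepens with canopy density; the ramp also keeps
        # the solved NIR inside [0, 1] across the full valid EVI range
        red = 0.13 - 0.07 * np.clip(v, 0.0, 1.0)
        blue = red * 5.0 / 12.0
        den_terms = 6.0 * red - 7.5 * blue + 1.0
        if np.any(v[ok] >= 2.4):
            raise SeriesError("EVI outside invertible range")
        nir = (v * den_terms + 2.5 * red) / (2.5 - v)
    if np.any(nir[ok] < 0) or np.any(nir[ok] > 1):
        raise SeriesError("VI outside invertible range for the reflectance model")
    red = np.where(ok, red, 0.0)
    nir = np.where(ok, nir, 0.0)
    blue = np.where(ok, blue, 0.0)
    return ReflectanceSeries(red=red, nir=nir, blue=blue, valid=ok.copy())


# ---------------------------------------------------------------------------
# stratified benchmark corpus

#: stratum name -> (weight, latitude range, has snow season, lai coupling)
STRATA = {
    "tropical": (0.30, (-10.0, 10.0), False, LAI_VI_STANDARD),
    "temperate": (0.40, (35.0, 55.0), False, LAI_VI_STANDARD),
    "boreal": (0.20, (55.0, 65.0), True, LAI_VI_STANDARD),
    "saturated": (0.10, (-5.0, 5.0), False, LAI_VI_SATURATED),
}


def _draw_phenology(rng: np.random.Generator, stratum: str) -> PhenologyParams:
    if stratum in ("tropical", "saturated"):
        # saturated stratum: base VI high enough that the LAI coupling keeps
        # min LAI above 5 across both years
        base = rng.uniform(0.55, 0.7) if stratum == "tropical" else rng.uniform(0.79, 0.84)
        peak = rng.uniform(base + 0.05, min(base + 0.25, 0.92))
        return PhenologyParams(
            base_vi=base, peak_vi=peak,
            green_up_doy=rng.uniform(60, 140), senescence_doy=rng.uniform(240, 320),
            transition_steepness=rng.uniform(0.02, 0.05),
            inter_annual_jitter=0.02,
        )
    base = rng.uniform(0.08, 0.25)
    peak = rng.uniform(0.6, 0.9)
    return PhenologyParams(
        base_vi=base, peak_vi=peak,
        green_up_doy=rng.uniform(100, 150), senescence_doy=rng.uniform(250, 300),
        transition_steepness=rng.uniform(0.05, 0.12),
        inter_annual_jitter=0.02,
    )


def _draw_contamination(rng: np.random.Generator, stratum: str,
                        cloud_fraction: float, seed: int) -> ContaminationParams:
    long_runs = stratum in ("tropical", "saturated")
    return ContaminationParams(
        cloud_fraction=cloud_fraction,
        cloud_run_length_mean=rng.uniform(4.0, 8.0) if long_runs else rng.uniform(1.5, 4.0),
        cloud_bias=rng.uniform(-0.4, -0.2),
        snow_season=(rng.uniform(320, 340), rng.uniform(40, 70)) if stratum == "boreal" else None,
        missing_fraction=0.05,
        seed=seed,
    )


def make_benchmark(
    n_pixels: int,
    index_kind: str = NDVI,
    cloud_fraction: float = 0.4,
    n_years: int = 2,
    seed: int = 0,
) -> list[SyntheticPixel]:
    """Stratified corpus: tropical (long cloud runs), temperate, boreal
    (winter snow troughs), and a high-LAI saturation stratum. Fully seeded."""
    if n_pixels < 1:
        raise SeriesError("n_pixels must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(STRATA)
    weights = np.array([STRATA[s][0] for s in names])
    counts = np.floor(weights * n_pixels).astype(int)
    if n_pixels >= len(names):
        counts = np.maximum(counts, 1)
    while counts.sum() > n_pixels:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_pixels:
        counts[np.argmin(counts - weights * n_pixels)] += 1

    pixels: list[SyntheticPixel] = []
    for stratum, count in zip(names, counts):
        _, (lat0, lat1), _, lai_coeffs = STRATA[stratum]
        for _ in range(count):
            sub = int(rng.integers(0, 2**31 - 1))
            prng = np.random.default_rng(sub)
            phen = _draw_phenology(prng, stratum)
            truth, lai = generate_truth(
                phen, n_years=n_years, seed=int(prng.integers(0, 2**31 - 1)),
                lai_coeffs=lai_coeffs, index_kind=index_kind,
            )
            cont = _draw_contamination(
                prng, stratum, cloud_fraction, seed=int(prng.integers(0, 2**31 - 1))
            )
            truth = apply_snow_to_truth(truth, cont)
            observed, qa = contaminate(truth, cont)
            refl = reflectance_from_vi(
                observed, qa, seed=int(prng.integers(0, 2**31 - 1))
            )
            pixels.append(SyntheticPixel(
                truth_vi=truth, observed_vi=observed, lai=lai, reflectance=refl,
                qa=qa, latitude=float(prng.uniform(lat0, lat1)),
                index_kind=index_kind,
                params={"stratum": stratum, "seed": sub,
                        "phenology": asdict(phen), "lai_coeffs": tuple(lai_coeffs)},
            ))
    return pixels
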