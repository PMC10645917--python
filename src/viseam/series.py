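"""Per-pixel time-series containers and vegetation-index computation.

All series live on a fixed 8-day composite grid with 46 steps per year.
Invalid vegetation-index observations are marked with the sentinel value
-0.2, the fill convention of the MODIS VI products; every routine in this
package treats that value (and only that value) as "missing".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: number of 8-day composites per year
STEPS_PER_YEAR = 46
#: fill value marking an invalid VI observation
SENTINEL = -0.2
#: solar zenith angle (degrees) above which an observation is discarded
SZA_LIMIT_DEG = 85.0
#: physical reflectance bounds accepted on input (MODIS allows slight
#: negatives from atmospheric correction and super-unity values)
REFLECTANCE_MIN = -0.01
REFLECTANCE_MAX = 1.6

VI_MIN = -0.2
VI_MAX = 1.0

NDVI = "NDVI"
EVI = "EVI"

#: summaryQA codes
QA_BEST = 0
QA_USEFUL = 1
QA_CLOUD = 2
QA_SNOW = 3


class SeriesError(ValueError):
    """Structural problem with a series (length, range, degenerate input)."""


class UnusableSeriesError(SeriesError):
    """Series has too few valid observations to be processed."""


def _as_f64(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 1:
        raise SeriesError(f"expected 1-D vector, got shape {a.shape}")
    return a


def _check_grid_length(n: int) -> None:
    if n <= 0 or n % STEPS_PER_YEAR != 0:
        raise SeriesError(
            f"series length must be a positive multiple of {STEPS_PER_YEAR}, got {n}"
        )


@dataclass
class ReflectanceSeries:
    """Aligned red/NIR/blue surface reflectance on the 8-day grid.

    ``blue`` and ``sza_deg`` are optional; a step with any required band
    missing (NaN) is forced to ``valid=False``.
    """

    red: np.ndarray
    nir: np.ndarray
    blue: np.ndarray | None = None
    sza_deg: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.red = _as_f64(self.red)
        self.nir = _as_f64(self.nir)
        n = self.red.size
        _check_grid_length(n)
        if self.nir.size != n:
            raise SeriesError("red and nir lengths differ")
        if self.blue is not None:
            self.blue = _as_f64(self.blue)
            if self.blue.size != n:
                raise SeriesError("blue length differs from red/nir")
        if self.sza_deg is not None:
            self.sza_deg = _as_f64(self.sza_deg)
            if self.sza_deg.size != n:
                raise SeriesError("sza_deg length differs from red/nir")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise SeriesError("valid length differs from red/nir")
        for name, band in (("red", self.red), ("nir", self.nir), ("blue", self.blue)):
            if band is None:
                continue
            finite = np.isfinite(band)
            if np.any(band[finite] > REFLECTANCE_MAX):
                raise SeriesError(f"{name} reflectance above {REFLECTANCE_MAX}")
            # NaN in a required band invalidates the step
            self.valid &= finite if name != "blue" else True
        if self.blue is not None:
            # blue may be flagged absent per step without failing validation;
            # EVI computation will invalidate those steps
            pass

    def __len__(self) -> int:
        return self.red.size


@dataclass
class VISeries:
    """One vegetation-index vector on the 8-day grid.

    Invalid steps hold exactly :data:`SENTINEL`; all finite values lie in
    ``[-0.2, 1.0]``.
    """

    values: np.ndarray
    index_kind: str = NDVI
    epoch: tuple[int, int] = (2014, 1)  # (start year, start day-of-year)
    step_days: int = 8

    def __post_init__(self):
        self.values = _as_f64(self.values)
        _check_grid_length(self.values.size)
        if self.index_kind not in (NDVI, EVI):
            raise SeriesError(f"unknown index kind {self.index_kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise SeriesError("VI values must be finite (use the -0.2 sentinel)")
        if np.any(self.values < VI_MIN - 1e-12) or np.any(self.values > VI_MAX + 1e-12):
            raise SeriesError("VI values outside [-0.2, 1.0]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def is_valid(self) -> np.ndarray:
        """Boolean mask of non-sentinel steps."""
        return self.values != SENTINEL

    def with_values(self, values: np.ndarray) -> "VISeries":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass
class QASeries:
    """Per-step summaryQA codes: 0/1 best/useful, 2 cloud, 3 snow-ice."""

    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise SeriesError("qa codes must be 1-D")
        if np.any((self.codes < 0) | (self.codes > 3)):
            raise SeriesError("qa codes must be in {0,1,2,3}")

    def __len__(self) -> int:
        return self.codes.size


@dataclass
class LAISeries:
    """Leaf-area-index vector on the same grid as its paired VISeries.

    The LAI input is assumed gap-free (the GLASS product is seamless), so no
    sentinel convention applies here.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = _as_f64(self.values)
        if np.any(~np.isfinite(self.values)):
            raise SeriesError("LAI must be finite and gap-free")
        if np.any(self.values < 0) or np.any(self.values > 10):
            raise SeriesError("LAI outside [0, 10]")

    def __len__(self) -> int:
        return self.values.size


def _invalid_mask(
    r: ReflectanceSeries, bands: list[np.ndarray], strict_and: bool
) -> np.ndarray:
    """Steps to invalidate: missing/invalid input, negative reflectance,
    or extreme solar zenith angle.

    ``strict_and`` switches the negative-reflectance / zenith rule from the
    default "either condition invalidates" to "both must hold".
    """
    n = len(r)
    neg = np.zeros(n, dtype=bool)
    for b in bands:
        neg |= ~np.isfinite(b) | (b < 0)
    if r.sza_deg is not None:
        high_sza = r.sza_deg > SZA_LIMIT_DEG
    else:
        high_sza = np.zeros(n, dtype=bool)
    if strict_and:
        bad = neg & high_sza
        # missing bands always invalidate regardless of mode
        for b in bands:
            bad |= ~np.isfinite(b)
    else:
        bad = neg | high_sza
    return bad | ~r.valid


def compute_ndvi(r: ReflectanceSeries, *, strict_and: bool = False) -> VISeries:
    """NDVI = (NIR - RED) / (NIR + RED), clipped to [-0.2, 1.0].

    Steps with negative reflectance, solar zenith angle above 85 deg, a zero
    denominator, or ``valid=False`` are set to the -0.2 sentinel.
    """
    bad = _invalid_mask(r, [r.red, r.nir], strict_and)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = r.nir + r.red
        v = np.where(den != 0, (r.nir - r.red) / np.where(den != 0, den, 1.0), np.nan)
    bad |= ~np.isfinite(v)
    v = np.clip(v, VI_MIN, VI_MAX)
    v[bad] = SENTINEL
    return VISeries(values=v, index_kind=NDVI)


def compute_evi(r: ReflectanceSeries, *, strict_and: bool = False) -> VISeries:
    """EVI = 2.5 (NIR - RED) / (NIR + 6 RED - 7.5 BLUE + 1), clipped.

    Same invalidation rules as :func:`compute_ndvi`, plus a missing blue band
    or a zero denominator sentinels the step.
    """
    if r.blue is None:
        raise SeriesError("EVI requires the blue band")
    bad = _invalid_mask(r, [r.red, r.nir, r.blue], strict_and)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = r.nir + 6.0 * r.red - 7.5 * r.blue + 1.0
        v = np.where(den != 0, 2.5 * (r.nir - r.red) / np.where(den != 0, den, 1.0), np.nan)
    bad |= ~np.isfinite(v)
    v = np.clip(v, VI_MIN, VI_MAX)
    v[bad] = SENTINEL
    return VISeries(values=v, index_kind=EVI)


def mask_from_qa(vi: VISeries, qa: QASeries, keep: set[int] = frozenset({0, 1})) -> VISeries:
    """Sentinel every step whose quality code is not in ``keep``."""
    if len(qa) != len(vi):
        raise SeriesError("QA length differs from VI length")
    keep = set(keep)
    if not keep <= {0, 1, 2, 3}:
        raise SeriesError("keep codes must be subset of {0,1,2,3}")
    out = vi.values.copy()
    drop = ~np.isin(qa.codes, sorted(keep))
    out[drop] = SENTINEL
    return vi.with_values(out)


def fill_sentinels(values: np.ndarray) -> np.ndarray:
    """Linear interpolation across sentinel runs, constant at the ends."""
    v = np.asarray(values, dtype=np.float64)
    ok = v != SENTINEL
    if not ok.any():
        raise UnusableSeriesError("all steps are sentinel")
    idx = np.arange(v.size)
    return np.interp(idx, idx[ok], v[ok])


# ---------------------------------------------------------------------------
# columnar text I/O

_COLUMNS = ["year", "doy", "red", "nir", "blue", "sza", "qa"]

_HEADER = (
    "# per-pixel 8-day reflectance series\n"
    "# reflectance unitless in [-0.01, 1.6]; VI sentinel -0.2; qa: 0/1 good, 2 cloud, 3 snow\n"
)


def write_series_table(path, r: ReflectanceSeries, qa: QASeries | None = None,
                       epoch: tuple[int, int] = (2014, 1)) -> None:
    """Write a reflectance series (and optional QA) as delimited text."""
    n = len(r)
    year0, _ = epoch
    step = np.arange(n)
    df = pd.DataFrame({
        "year": year0 + step // STEPS_PER_YEAR,
        "doy": 1 + 8 * (step % STEPS_PER_YEAR),
        "red": r.red,
        "nir": r.nir,
        "blue": r.blue if r.blue is not None else np.nan,
        "sza": r.sza_deg if r.sza_deg is not None else np.nan,
        "qa": qa.codes if qa is not None else -1,
    })
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False)


def read_series_table(path) -> tuple[ReflectanceSeries, QASeries | None]:
    """Read a series written by :func:`write_series_table`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SeriesError(f"series table missing columns {missing}")
    blue = df["blue"].to_numpy()
    sza = df["sza"].to_numpy()
    r = ReflectanceSeries(
        red=df["red"].to_numpy(),
        nir=df["nir"].to_numpy(),
        blue=None if np.all(np.isnan(blue)) else blue,
        sza_deg=None if np.all(np.isnan(sza)) else sza,
    )
    qa_codes = df["qa"].to_numpy()
    qa = None if np.all(qa_codes < 0) else QASeries(codes=qa_codes)
    return r, qa


def save_bands(path, **bands: np.ndarray) -> None:
    """Self-describing array container keyed by band name (npz)."""
    np.savez(path, **bands)


def load_bands(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}
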