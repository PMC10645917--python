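"""Construction of high-quality VI training targets.

Contaminated VI observations are turned into gap-free "truth-like" targets
in four steps: (1) an upper-envelope Savitzky-Golay pre-clean that flags
outliers against the smooth fit, (2) a saturating exponential fit of VI
against LAI (VI = c - exp(a*LAI + b)) evaluated back onto the LAI series,
(3) an upper-envelope interpolation of the cleaned observations merged with
the LAI fit by an elementwise maximum, and (4) a snow/ice blend that
re-introduces genuinely low winter values, followed by a final smoothing
pass. Two special cases are handled: densely vegetated pixels where LAI
saturates (min LAI > 5 over two years triggers a constrained two-stage
refit) and high-latitude pixels with long snow cover (the blend of step 4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .series import (
    EVI,
    NDVI,
    SENTINEL,
    LAISeries,
    QASeries,
    SeriesError,
    UnusableSeriesError,
    VISeries,
    VI_MAX,
    VI_MIN,
    fill_sentinels,
)


class FitError(RuntimeError):
    """LAI-VI fit failed (degenerate input or no convergence)."""


@dataclass
class SGConfig:
    """Savitzky-Golay upper-envelope filter settings.

    ``half_width`` 12 and ``iterations`` 2 follow the TIMESAT-style
    configuration (window half-width = steps per year / 4). The outlier
    ``deviation_threshold`` is 0.4 for NDVI and 0.2 for EVI. With the
    window fixed at 25 steps (~200 days) a quadratic cannot track seasonal
    green-up/senescence at 8-day sampling, so the default polynomial order
    is 6; lower orders remain available for TIMESAT-style behaviour.
    """

    half_width: int = 12
    iterations: int = 2
    poly_order: int = 6
    deviation_threshold: float = 0.4
    high_side_cut: float | None = None  # EVI high-value pre-clean

    def __post_init__(self):
        if self.half_width < self.poly_order + 1:
            raise SeriesError("half_width must be >= poly_order + 1")
        if self.iterations < 1:
            raise SeriesError("iterations must be >= 1")
        if self.deviation_threshold <= 0:
            raise SeriesError("deviation_threshold must be positive")

    @classmethod
    def for_kind(cls, index_kind: str) -> "SGConfig":
        if index_kind == EVI:
            return cls(deviation_threshold=0.2, high_side_cut=0.2)
        return cls(deviation_threshold=0.4)


@dataclass
class LaiViFit:
    """Parameters of VI = c - exp(a*LAI + b) plus fit diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    n_used: int
    constrained: bool = False

    def __post_init__(self):
        if self.n_used < 3:
            raise FitError("fit must use at least 3 pairs")
        if self.rss < 0:
            raise FitError("negative residual sum of squares")


@dataclass
class SampleRecord:
    """One training sample: raw observation, LAI, and the gap-free target."""

    raw_vi: VISeries
    lai: LAISeries
    target_vi: VISeries
    provenance: str  # standard | saturation-refit | snow-blend
    reflectance: object | None = None  # optional paired ReflectanceSeries


def sg_smooth(values: np.ndarray, half_width: int, poly_order: int) -> np.ndarray:
    """Moving-window polynomial least-squares fit (gap-free input).

    Interior points take the value of the centred window fit; the first and
    last half-windows take the values of the polynomial fitted to the first
    and last full window. The basis uses an abscissa scaled to [-1, 1], so
    every point agrees with the exact least-squares solution to machine
    precision even at higher polynomial orders (where the usual convolution
    coefficients lose ~1e-10 of accuracy to ill conditioning).
    """
    values = np.asarray(values, dtype=np.float64)
    window = 2 * half_width + 1
    n = values.size
    if n < window:
        raise SeriesError(f"series shorter than SG window ({n} < {window})")
    t = np.arange(-half_width, half_width + 1, dtype=np.float64) / half_width
    A = np.vander(t, poly_order + 1, increasing=True)
    gram = np.linalg.solve(A.T @ A, A.T)  # (order+1, window)
    out = np.empty(n)
    # interior: centred-window fit evaluated at the centre (row 0 of gram)
    out[half_width : n - half_width] = np.correlate(values, gram[0], mode="valid")
    # edges: polynomial fitted to the first/last full window
    head = A @ (gram @ values[:window])
    tail = A @ (gram @ values[n - window :])
    out[:half_width] = head[:half_width]
    out[n - half_width :] = tail[half_width + 1 :]
    return out


def sg_envelope_filter(vi: VISeries, cfg: SGConfig | None = None) -> VISeries:
    """Upper-envelope Savitzky-Golay smoothing.

    Sentinels are filled by linear interpolation, then the SG fit is
    iterated: points falling below the current fit are replaced by the
    fitted value before refitting, so the curve climbs toward the upper
    envelope of the series.
    """
    cfg = cfg or SGConfig.for_kind(vi.index_kind)
    y = fill_sentinels(vi.values)  # raises on all-sentinel input
    s = sg_smooth(y, cfg.half_width, cfg.poly_order)
    for _ in range(cfg.iterations):
        y = np.where(y < s, s, y)
        s = sg_smooth(y, cfg.half_width, cfg.poly_order)
    return vi.with_values(np.clip(s, VI_MIN, VI_MAX))


def flag_outliers(vi: VISeries, smooth: VISeries, threshold: float) -> VISeries:
    """Sentinel steps deviating from the smooth fit by more than ``threshold``
    (strict inequality: boundary equality keeps the point)."""
    if len(vi) != len(smooth):
        raise SeriesError("length mismatch between series and smooth fit")
    out = vi.values.copy()
    dev = np.abs(vi.values - smooth.values)
    out[vi.is_valid & (dev > threshold)] = SENTINEL
    return vi.with_values(out)


def _model(theta: np.ndarray, lai: np.ndarray) -> np.ndarray:
    a, b, c = theta
    return c - np.exp(a * lai + b)


def _jac(theta: np.ndarray, lai: np.ndarray) -> np.ndarray:
    a, b, _ = theta
    e = np.exp(a * lai + b)
    return np.column_stack([-lai * e, -e, np.ones_like(lai)])


def _solve_fit(lai, vi, theta0, bounds) -> tuple[np.ndarray, float]:
    res = least_squares(lambda th: _model(th, lai) - vi, theta0,
                        jac=lambda th: _jac(th, lai), bounds=bounds,
                        method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13,
                        max_nfev=20000)
    if not res.success:
        raise FitError(f"LAI-VI fit did not converge: {res.message}")
    return res.x, float(np.sum(res.fun**2))


def _grid_init(L: np.ndarray, V: np.ndarray, sign: float = -1.0) -> np.ndarray:
    """Initial (a, b, c): scan c, linearise log(c - V) against LAI."""
    best, best_sse = None, np.inf
    for c in np.linspace(V.max() + 0.02, 1.25, 12):
        resid = np.log(np.maximum(c - V, 1e-6))
        slope, intercept = np.polyfit(L, resid, 1)
        if sign < 0:
            slope = min(slope, -1e-3)
        else:
            slope = max(slope, 1e-3)
        sse = float(np.sum((_model((slope, intercept, c), L) - V) ** 2))
        if sse < best_sse:
            best, best_sse = np.array([slope, intercept, c]), sse
    return best


def fit_lai_vi(vi: VISeries, lai: LAISeries, constrain: bool = False,
               constrain_sign: float = 1.0, upper_refit: bool = True) -> LaiViFit:
    """Least-squares fit of VI = c - exp(a*LAI + b) over non-sentinel pairs.

    The standard fit is sign-unconstrained and initialised with a < 0 (the
    saturating-growth orientation). Because residual contamination biases
    VI low while high values are the trustworthy ones, the fit is by
    default repeated using only the pairs lying above the first fitted
    curve (``upper_refit``), so the curve tracks the upper envelope of the
    LAI-VI relation; on noiseless data the refit is a no-op. With
    ``constrain`` set (the high-LAI saturation case), the sign of ``a`` is
    additionally bounded by ``constrain_sign`` in both stages.
    """
    if len(vi) != len(lai):
        raise SeriesError("VI and LAI lengths differ")
    ok = vi.is_valid
    L, V = lai.values[ok], vi.values[ok]
    if L.size < 3:
        raise FitError(f"need >= 3 valid (LAI, VI) pairs, have {L.size}")
    if np.ptp(L) < 1e-12:
        raise FitError("degenerate LAI series (zero variance)")
    # numeric box keeping the fit identifiable: c is the saturating VI
    # asymptote, so it cannot meaningfully exceed the VI range (without a
    # cap the a->0, c->inf direction is flat and the solver drifts)
    A, B_, C_LO, C_HI = 20.0, 20.0, -0.5, 1.25
    if not constrain:
        bounds = (np.array([-A, -B_, C_LO]), np.array([A, B_, C_HI]))
        theta0 = _grid_init(L, V, sign=-1.0)
    elif constrain_sign >= 0:
        bounds = (np.array([0.0, -B_, C_LO]), np.array([A, B_, C_HI]))
        theta0 = _grid_init(L, V, sign=1.0)
    else:
        bounds = (np.array([-A, -B_, C_LO]), np.array([0.0, B_, C_HI]))
        theta0 = _grid_init(L, V, sign=-1.0)
    theta1, rss1 = _solve_fit(L, V, theta0, bounds)
    above = V > _model(theta1, L)
    if upper_refit and above.sum() >= 3 and np.ptp(L[above]) > 1e-12:
        theta2, rss = _solve_fit(L[above], V[above], theta1, bounds)
        return LaiViFit(a=float(theta2[0]), b=float(theta2[1]), c=float(theta2[2]),
                        rss=rss, n_used=int(above.sum()), constrained=constrain)
    return LaiViFit(a=float(theta1[0]), b=float(theta1[1]), c=float(theta1[2]),
                    rss=rss1, n_used=int(L.size), constrained=constrain)


def apply_fit(fit: LaiViFit, lai: LAISeries, index_kind: str = NDVI) -> VISeries:
    """Evaluate the fitted curve on an LAI series, clipped to [-0.2, 1]."""
    v = fit.c - np.exp(fit.a * lai.values + fit.b)
    return VISeries(values=np.clip(v, VI_MIN, VI_MAX), index_kind=index_kind)


def upper_envelope_interpolate(vi: VISeries) -> VISeries:
    """Replace strict local minima by linear interpolation between their
    flanking envelope points.

    A non-sentinel step is an envelope point unless it lies strictly below
    both its nearest valid neighbours; the first and last valid steps are
    envelope points by convention. Sentinel steps are never envelope points
    and are interpolated as well; the output is gap-free.
    """
    if len(vi) < 3:
        raise SeriesError("need at least 3 steps")
    v = vi.values
    ok_idx = np.flatnonzero(vi.is_valid)
    if ok_idx.size < 2:
        raise UnusableSeriesError("fewer than 2 envelope points")
    vals = v[ok_idx]
    env = np.ones(ok_idx.size, dtype=bool)
    interior = slice(1, -1)
    env[interior] = (vals[1:-1] >= vals[:-2]) | (vals[1:-1] >= vals[2:])
    anchor_idx = ok_idx[env]
    out = np.interp(np.arange(v.size), anchor_idx, v[anchor_idx])
    return vi.with_values(out)


def synthesize(fitting: VISeries, env: VISeries) -> VISeries:
    """Elementwise maximum of the LAI-fit series and the envelope series."""
    if len(fitting) != len(env):
        raise SeriesError("length mismatch")
    if not (fitting.is_valid.all() and env.is_valid.all()):
        raise SeriesError("synthesize requires gap-free inputs")
    return fitting.with_values(np.maximum(fitting.values, env.values))


def snow_blend(ori: VISeries, syn: VISeries, sg_of_ori: VISeries) -> VISeries:
    """Blend the synthetic series back toward low original values where the
    smoothed original drops below 0.2 (persistent snow/ice cover).

    out = w*syn + (1-w)*ori with w = clip((ori + 0.2)/0.4, 0, 1); elsewhere
    out = syn. The 0.2/0.4 constants are the empirical snow-region blend
    coefficients.
    """
    if not (len(ori) == len(syn) == len(sg_of_ori)):
        raise SeriesError("length mismatch")
    w = np.clip((ori.values + 0.2) / 0.4, 0.0, 1.0)
    blended = w * syn.values + (1.0 - w) * ori.values
    out = np.where(sg_of_ori.values < 0.2, blended, syn.values)
    return syn.with_values(out)


def build_target(raw_vi: VISeries, lai: LAISeries,
                 cfg: SGConfig | None = None,
                 qa: "QASeries | None" = None) -> SampleRecord:
    """Run the full four-step chain on one pixel and return a gap-free target.

    The snow/ice blend of step 4 retains genuinely low winter values, so it
    must only run on pixels actually covered by snow for long periods: when
    ``qa`` is supplied, the blend requires snow/ice-coded steps (code 3) in
    addition to the smoothed-original trigger; without ``qa`` the trigger
    alone decides. A pixel failing any stage raises (it is rejected, never
    passed through).
    """
    cfg = cfg or SGConfig.for_kind(raw_vi.index_kind)
    if len(raw_vi) != len(lai):
        raise SeriesError("VI and LAI lengths differ")

    work = raw_vi
    # EVI carries high-value noise as well; pre-clean the high side against
    # the smooth fit before the symmetric outlier pass
    if raw_vi.index_kind == EVI and cfg.high_side_cut is not None:
        pre_smooth = sg_envelope_filter(work, cfg)
        out = work.values.copy()
        out[work.is_valid & (work.values - pre_smooth.values > cfg.high_side_cut)] = SENTINEL
        work = work.with_values(out)

    # step 1: SG pre-clean + outlier flagging
    smooth = sg_envelope_filter(work, cfg)
    flagged = flag_outliers(work, smooth, cfg.deviation_threshold)

    # step 2: LAI fitting (constrained when LAI never leaves saturation)
    constrain = bool(np.min(lai.values) > 5.0)
    fit = fit_lai_vi(flagged, lai, constrain=constrain)
    fitting = apply_fit(fit, lai, index_kind=raw_vi.index_kind)

    # step 3: upper envelope of the cleaned observations, then synthesis
    env = upper_envelope_interpolate(flagged)
    syn = synthesize(fitting, env)

    # step 4: snow blend where the smoothed original is low, then a final
    # plain SG smoothing pass (the envelope iterations exist to reject low
    # outliers, which steps 1-3 have already removed)
    sg_of_ori = sg_envelope_filter(raw_vi, cfg)
    snow_pixel = True if qa is None else bool(np.any(qa.codes == 3))
    blended = snow_pixel and bool(np.any(sg_of_ori.values < 0.2))
    if blended:
        ori_filled = raw_vi.with_values(fill_sentinels(raw_vi.values))
        syn = snow_blend(ori_filled, syn, sg_of_ori)
    # clip strictly above the fill value: a target step equal to -0.2 would
    # read back as missing
    target = syn.with_values(
        np.clip(sg_smooth(syn.values, cfg.half_width, cfg.poly_order),
                VI_MIN + 1e-6, VI_MAX))

    provenance = ("saturation-refit" if constrain
                  else "snow-blend" if blended else "standard")
    return SampleRecord(raw_vi=raw_vi, lai=lai, target_vi=target,
                        provenance=provenance)


# ---------------------------------------------------------------------------
# batch store

def write_sample_store(path, records: list[SampleRecord]) -> None:
    """Columnar text store: pixel_id, step, raw_vi, lai, target_vi, provenance."""
    import pandas as pd

    frames = []
    for pid, rec in enumerate(records):
        n = len(rec.raw_vi)
        frames.append(pd.DataFrame({
            "pixel_id": pid,
            "step": np.arange(n),
            "raw_vi": rec.raw_vi.values,
            "lai": rec.lai.values,
            "target_vi": rec.target_vi.values,
            "provenance": rec.provenance,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sample_store(path, index_kind: str = NDVI) -> list[SampleRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for pid, g in df.groupby("pixel_id", sort=True):
        records.append(SampleRecord(
            raw_vi=VISeries(values=g["raw_vi"].to_numpy(), index_kind=index_kind),
            lai=LAISeries(values=g["lai"].to_numpy()),
            target_vi=VISeries(values=g["target_vi"].to_numpy(), index_kind=index_kind),
            provenance=str(g["provenance"].iloc[0]),
        ))
    return records


def write_sg_config(path, configs: dict[str, SGConfig]) -> None:
    """Flat key=value config file, one section prefix per index kind."""
    with open(path, "w") as fh:
        for kind, cfg in configs.items():
            fh.write(f"{kind}.half_width={cfg.half_width}\n")
            fh.write(f"{kind}.iterations={cfg.iterations}\n")
            fh.write(f"{kind}.poly_order={cfg.poly_order}\n")
            fh.write(f"{kind}.deviation_threshold={cfg.deviation_threshold}\n")
            if cfg.high_side_cut is not None:
                fh.write(f"{kind}.high_side_cut={cfg.high_side_cut}\n")


def read_sg_config(path) -> dict[str, SGConfig]:
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("=", 1)
            kind, field_name = key.split(".", 1)
            raw.setdefault(kind, {})[field_name] = val
    out = {}
    for kind, fields in raw.items():
        out[kind] = SGConfig(
            half_width=int(fields["half_width"]),
            iterations=int(fields["iterations"]),
            poly_order=int(fields["poly_order"]),
            deviation_threshold=float(fields["deviation_threshold"]),
            high_side_cut=float(fields["high_side_cut"]) if "high_side_cut" in fields else None,
        )
    return out
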