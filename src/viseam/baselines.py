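"""Classical reference reconstructors: Savitzky-Golay and Whittaker.

These are the comparison methods, configured as in the product evaluation:
SG with half-width 12 and 2 upper-envelope iterations, Whittaker with
smoothing parameter lambda = 2 and second-order differences. The SG
baseline deliberately keeps sentinel steps at -0.2 (no interpolation), which
reproduces the known failure mode of filter baselines on fill values; the
Whittaker baseline instead zero-weights sentinels by default, with a
fill-value mode available for the harsher comparison variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .series import (
    SeriesError,
    UnusableSeriesError,
    VISeries,
    VI_MAX,
    VI_MIN,
)
from .samples import SGConfig, sg_smooth


@dataclass
class WhittakerConfig:
    """Penalised-least-squares smoother settings."""

    lam: float = 2.0
    difference_order: int = 2

    def __post_init__(self):
        if self.lam <= 0:
            raise SeriesError("lambda must be positive")
        if self.difference_order != 2:
            raise SeriesError("only second-order differences are supported")


def reconstruct_sg(vi: VISeries, cfg: SGConfig | None = None) -> VISeries:
    """Upper-envelope SG reconstruction of a possibly contaminated series.

    Sentinels are NOT interpolated first: the -0.2 fill value enters the
    moving-window fits, dragging the baseline down across long gaps exactly
    as fill values do for filter methods in practice.
    """
    cfg = cfg or SGConfig.for_kind(vi.index_kind)
    y = vi.values.copy()
    s = sg_smooth(y, cfg.half_width, cfg.poly_order)
    for _ in range(cfg.iterations):
        y = np.where(y < s, s, y)
        s = sg_smooth(y, cfg.half_width, cfg.poly_order)
    return vi.with_values(np.clip(s, VI_MIN, VI_MAX))


def whittaker_system(y: np.ndarray, w: np.ndarray, lam: float):
    """Upper-banded form of (W + lam * D2'D2) for scipy.solveh_banded."""
    n = y.size
    # D2'D2 for the (n-2) x n second-difference matrix, as 3 upper diagonals
    main = np.zeros(n)
    main[0] = main[-1] = 1.0
    main[1] = main[-2] = 5.0
    main[2:-2] = 6.0
    if n < 5:
        raise SeriesError("need at least 5 steps")
    off1 = np.full(n - 1, -4.0)
    off1[0] = off1[-1] = -2.0
    off2 = np.full(n - 2, 1.0)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * off2
    ab[1, 1:] = lam * off1
    ab[2] = lam * main + w
    return ab


def reconstruct_whittaker(vi: VISeries, cfg: WhittakerConfig | None = None,
                          fill_mode: bool = False) -> VISeries:
    """Whittaker smoothing: minimise sum w*(z-y)^2 + lam*sum (d2 z)^2.

    Weights are 1 on valid steps and 0 on sentinels; with ``fill_mode`` all
    weights are 1 and sentinels contribute their -0.2 fill value, mirroring
    the harsher baseline behaviour on fill values.
    """
    cfg = cfg or WhittakerConfig()
    y = vi.values.astype(np.float64)
    if y.size < 5:
        raise SeriesError("need at least 5 steps")
    if fill_mode:
        w = np.ones(y.size)
    else:
        w = vi.is_valid.astype(np.float64)
        if w.sum() < 3:
            raise UnusableSeriesError("fewer than 3 valid steps")
    ab = whittaker_system(y, w, cfg.lam)
    z = solveh_banded(ab, w * y, lower=False)
    return vi.with_values(np.clip(z, VI_MIN, VI_MAX))
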