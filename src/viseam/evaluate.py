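"""Evaluation metrics and the method-comparison harness.

Reconstructions are scored against quality-masked reference series with
four quantities: RMSE and R2 over good-quality reference steps, the
upper-envelope rate (fraction of reconstructed values falling below the
original observations; lower is better for NDVI since the envelope is the
target), and the distance (mean absolute deviation from the observations,
a fidelity measure).

R2 follows the product evaluation's explained-variation form
sum(result - mean)^2 / sum(obs - mean)^2 by default; the conventional
1 - SSres/SStot is reported alongside. RMSE is the standard root mean
square error; the raw summed variant (no square, no 1/n) is available
behind a flag for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import QASeries, SeriesError, VISeries


class UndefinedMetricError(ValueError):
    """No usable steps (or zero variance) for the requested metric."""


@dataclass
class EvalReport:
    """Metrics for one reconstruction method on one dataset."""

    method_name: str
    index_kind: str
    rmse: float
    r2: float
    env_rate: float
    distance: float
    n_good: int
    stratum: str = "all"
    r2_standard: float = float("nan")

    def __post_init__(self):
        if self.n_good < 1:
            raise UndefinedMetricError("report needs at least one good step")


def _good_mask(reference: VISeries, mask: QASeries | None,
               keep=(0, 1)) -> np.ndarray:
    good = reference.is_valid
    if mask is not None:
        if len(mask) != len(reference):
            raise SeriesError("mask length differs from reference")
        good &= np.isin(mask.codes, keep)
    return good


def rmse(result: VISeries, reference: VISeries, mask: QASeries | None = None,
         printed_form: bool = False) -> float:
    """Root mean square error over good reference steps.

    ``printed_form`` reproduces the raw summed variant (no square of the
    residual, no 1/n) for auditing; the default is the standard RMSE.
    """
    if len(result) != len(reference):
        raise SeriesError("length mismatch")
    good = _good_mask(reference, mask)
    if not good.any():
        raise UndefinedMetricError("no good steps for RMSE")
    d = result.values[good] - reference.values[good]
    if printed_form:
        return float(np.sqrt(np.abs(np.sum(d))))
    return float(np.sqrt(np.mean(d * d)))


def r_squared(result: VISeries, reference: VISeries,
              mask: QASeries | None = None, standard: bool = False) -> float:
    """Coefficient of determination over good reference steps.

    Default: explained-variation ratio sum(result-mean)^2/sum(ref-mean)^2
    with the mean taken over good reference values. ``standard`` switches
    to 1 - SSres/SStot, clipped below at 0.
    """
    if len(result) != len(reference):
        raise SeriesError("length mismatch")
    good = _good_mask(reference, mask)
    if not good.any():
        raise UndefinedMetricError("no good steps for R2")
    ref = reference.values[good]
    res = result.values[good]
    ybar = float(np.mean(ref))
    sstot = float(np.sum((ref - ybar) ** 2))
    if sstot <= 0:
        raise UndefinedMetricError("zero reference variance")
    if standard:
        ssres = float(np.sum((res - ref) ** 2))
        return max(0.0, 1.0 - ssres / sstot)
    return float(np.sum((res - ybar) ** 2) / sstot)


def envelope_rate(result: VISeries, observations: VISeries) -> float:
    """Fraction of non-sentinel observation steps where the reconstruction
    lies strictly below the observation (equality counts as not-lower)."""
    if len(result) != len(observations):
        raise SeriesError("length mismatch")
    ok = observations.is_valid
    if not ok.any():
        raise UndefinedMetricError("no valid observations")
    below = result.values[ok] < observations.values[ok]
    return float(np.mean(below))


def distance(result: VISeries, observations: VISeries) -> float:
    """Mean absolute deviation from the non-sentinel observations."""
    if len(result) != len(observations):
        raise SeriesError("length mismatch")
    ok = observations.is_valid
    if not ok.any():
        raise UndefinedMetricError("no valid observations")
    return float(np.mean(np.abs(result.values[ok] - observations.values[ok])))


#: default latitude strata mirroring the product evaluation's bands
DEFAULT_STRATA = {"all": None, "40N-60N": (40.0, 60.0), "10S-10N": (-10.0, 10.0)}


def compare_methods(
    methods: dict,
    dataset: list,
    references: list[VISeries],
    masks: list[QASeries] | None = None,
    observations: list[VISeries] | None = None,
    latitudes: list[float] | None = None,
    strata: dict | None = None,
    index_kind: str = "NDVI",
    max_failure_fraction: float = 0.1,
) -> list[EvalReport]:
    """Score each named reconstructor on a pixel collection.

    ``methods`` maps a name to a callable taking one dataset entry and
    returning a VISeries. Metrics pool all good steps across pixels before
    being computed (pooled RMSE equals RMSE on the concatenated step set).
    ``observations`` (for envelope rate / distance) defaults to the
    references. With ``latitudes`` given, reports are additionally
    stratified into latitude bands.
    """
    n = len(dataset)
    if n == 0:
        raise SeriesError("empty dataset")
    if len(references) != n:
        raise SeriesError("references length mismatch")
    observations = observations if observations is not None else references
    strata = strata if strata is not None else (
        DEFAULT_STRATA if latitudes is not None else {"all": None})

    reports: list[EvalReport] = []
    for name, fn in methods.items():
        results: list[VISeries | None] = []
        failures = []
        for i, entry in enumerate(dataset):
            try:
                results.append(fn(entry))
            except Exception as exc:  # noqa: BLE001 - failures are collected
                results.append(None)
                failures.append((i, repr(exc)))
        if len(failures) > max_failure_fraction * n:
            raise RuntimeError(
                f"method {name!r} failed on {len(failures)}/{n} pixels: "
                f"{failures[:5]}")
        for stratum, band in strata.items():
            idx = [i for i in range(n) if results[i] is not None]
            if band is not None:
                lo, hi = band
                idx = [i for i in idx if lo <= latitudes[i] <= hi]
            if not idx:
                continue
            res_cat, ref_cat, msk_cat, obs_cat = [], [], [], []
            for i in idx:
                res_cat.append(results[i].values)
                ref_cat.append(references[i].values)
                msk_cat.append(masks[i].codes if masks is not None
                               else np.zeros(len(references[i]), dtype=int))
                obs_cat.append(observations[i].values)
            # pool by concatenation: metrics over the union of good steps
            res_v = np.concatenate(res_cat)
            ref_v = np.concatenate(ref_cat)
            msk_v = np.concatenate(msk_cat)
            obs_v = np.concatenate(obs_cat)
            good = (ref_v != -0.2) & np.isin(msk_v, (0, 1))
            if not good.any():
                continue
            d = res_v[good] - ref_v[good]
            ybar = ref_v[good].mean()
            sstot = float(np.sum((ref_v[good] - ybar) ** 2))
            obs_ok = obs_v != -0.2
            reports.append(EvalReport(
                method_name=name,
                index_kind=index_kind,
                rmse=float(np.sqrt(np.mean(d * d))),
                r2=float(np.sum((res_v[good] - ybar) ** 2) / sstot)
                    if sstot > 0 else float("nan"),
                r2_standard=max(0.0, 1.0 - float(np.sum(d * d)) / sstot)
                    if sstot > 0 else float("nan"),
                env_rate=float(np.mean(res_v[obs_ok] < obs_v[obs_ok])),
                distance=float(np.mean(np.abs(res_v[obs_ok] - obs_v[obs_ok]))),
                n_good=int(good.sum()),
                stratum=stratum,
            ))
    return reports


def reports_to_table(reports: list[EvalReport]) -> pd.DataFrame:
    """One row per (method, index kind, stratum), metric columns."""
    return pd.DataFrame([{
        "method": r.method_name, "index": r.index_kind, "stratum": r.stratum,
        "rmse": r.rmse, "r2": r.r2, "r2_standard": r.r2_standard,
        "env_rate": r.env_rate, "distance": r.distance, "n_good": r.n_good,
    } for r in reports])


def write_report(path, reports: list[EvalReport]) -> None:
    reports_to_table(reports).to_csv(path, sep="\t", index=False)
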