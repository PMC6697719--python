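"""Per-run process quantities feeding the kinetics.

Fed-batch feeding (33 vol% total) and daily sampling continually change
the culture volume, so raw daily concentrations confound biology with
dilution.  ``dilution_correct`` decomposes each daily interval into the
known volume change and the biological change, and re-expresses every
concentration on the common (inoculation) volume basis by dividing by
the cumulative dilution factor R: a species formed at concentration c
in interval i contributes c / R_{i+1} on the common basis regardless of
later feeds, which is what makes increments of different intervals
additive and the kinetic relationship between acidic species and the
driving integral exact.

``compute_rates`` derives, per interval between consecutive samples:

* the specific growth rate  mu = ln(VCC2 / (VCC1 * r)) / dt   (r = the
  interval's feed-dilution ratio),
* the specific glucose consumption  q_gluc = consumed / (logmean VCC *
  dt), with the log-mean viable-cell integral standard for
  exponentially growing cultures; VCC stays on the cells/mL basis, so
  q_gluc carries the mixed g/L-per-(cells/mL)-per-day unit declared in
  the output metadata,
* delta_mab, the dilution-corrected newly built IgG of the interval,
  expressed both on the common basis (used by the kinetics) and on the
  interval's own volume basis (used for mass balances).

Negative corrected increments can only arise from measurement noise
and are clipped to zero with a logged warning.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import FedBatchRun

logger = logging.getLogger(__name__)

Q_GLUC_UNITS = "g/L per (cells/mL) per day"


def _logmean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = 0.5 * (a + b)
    differ = ~np.isclose(a, b, rtol=1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = (b - a) / np.log(b / a)
    out[differ] = lm[differ]
    return out


def dilution_correct(run: FedBatchRun, feed_glucose: float | None = None) -> pd.DataFrame:
    """Augment a run's records with dilution-correction factors.

    Returns the record table with, per day ``i``:

    ``r``
        dilution ratio of the interval starting at day ``i`` (volume
        after sampling divided by volume after the feed pulse); 1 where
        no feed was given, NaN for the final day.
    ``basis_factor``
        cumulative product R of all ``r`` up to (excluding) day ``i``;
        dividing a measured concentration by R expresses it on the
        common inoculation-volume basis.
    ``glucose_postfeed``
        glucose concentration right after the day's feed pulse, needed
        to split measured glucose changes into feed input and
        consumption.
    ``*_corr``
        common-basis versions of VCC and the three titers.
    """
    frame = run.to_frame()
    for col in ("volume_before_sample", "feed_added_today"):
        if frame[col].isna().any():
            raise ValidationError(f"missing volume field '{col}'")
    params = run.params
    if feed_glucose is None:
        feed_glucose = params.feed_base_glucose + params.feed_glucose_add

    v_sampled = frame["volume_before_sample"].to_numpy() - params.sample_volume
    if np.any(v_sampled <= 0):
        raise ValidationError("sampling volume exceeds culture volume")
    feed = frame["feed_added_today"].to_numpy()
    r = v_sampled / (v_sampled + feed)

    n = len(frame)
    basis = np.ones(n)
    for i in range(1, n):
        basis[i] = basis[i - 1] * r[i - 1]

    glucose = frame["glucose"].to_numpy()
    g_postfeed = glucose * r + feed_glucose * (1.0 - r)

    out = frame.copy()
    out["r"] = r
    out.loc[out.index[-1], "r"] = np.nan
    out["basis_factor"] = basis
    out["glucose_postfeed"] = g_postfeed
    out.loc[out.index[-1], "glucose_postfeed"] = np.nan
    for col in ("vcc", "titer_total", "titer_acidic", "titer_basic"):
        out[f"{col}_corr"] = out[col] / basis
    out.attrs["feed_glucose"] = feed_glucose
    out.attrs["run_id"] = run.run_id
    return out


def compute_rates(run: FedBatchRun, corrected: pd.DataFrame | None = None) -> pd.DataFrame:
    """Interval growth, glucose-consumption and IgG-production rates.

    One row per consecutive record pair, indexed by interval midpoint.
    """
    if corrected is None:
        corrected = dilution_correct(run)
    day = corrected["day"].to_numpy(dtype=float)
    dt = np.diff(day)
    if np.any(dt <= 0):
        raise ValidationError("records must be strictly time-ordered")
    vcc = corrected["vcc"].to_numpy()
    if np.any(vcc <= 0):
        raise ValidationError("non-positive viable cell concentration")
    r = corrected["r"].to_numpy()[:-1]
    vcc_start = vcc[:-1] * r  # post-feed start of each interval
    vcc_end = vcc[1:]
    mu = np.log(vcc_end / vcc_start) / dt

    g_post = corrected["glucose_postfeed"].to_numpy()[:-1]
    consumed = g_post - corrected["glucose"].to_numpy()[1:]
    cells = _logmean(vcc_start, vcc_end)
    q_gluc = consumed / (cells * dt)

    titer_corr = corrected["titer_total_corr"].to_numpy()
    delta = np.diff(titer_corr)
    n_clipped = int(np.sum(delta < 0))
    if n_clipped:
        logger.warning(
            "%s: clipped %d negative corrected IgG increment(s) to zero",
            corrected.attrs.get("run_id", "run"),
            n_clipped,
        )
    delta = np.clip(delta, 0.0, None)

    titer = corrected["titer_total"].to_numpy()
    delta_local = np.clip(titer[1:] - titer[:-1] * r, 0.0, None)
    v_interval = (
        corrected["volume_before_sample"].to_numpy()[:-1]
        - run.params.sample_volume
        + corrected["feed_added_today"].to_numpy()[:-1]
    )

    rates = pd.DataFrame(
        {
            "midpoint_day": 0.5 * (day[:-1] + day[1:]),
            "dt": dt,
            "mu": mu,
            "q_gluc": q_gluc,
            "delta_mab": delta,
            "delta_mab_local": delta_local,
            "interval_volume": v_interval,
            "n_clipped": 0,
        }
    )
    rates.attrs["q_gluc_units"] = Q_GLUC_UNITS
    rates.attrs["mu_units"] = "1/day"
    rates.attrs["delta_mab_units"] = "g/L per interval, common volume basis"
    rates.attrs["run_id"] = corrected.attrs.get("run_id", "run")
    rates.attrs["n_clipped"] = n_clipped
    return rates


def produced_mass_g(rates: pd.DataFrame) -> float:
    """Total produced IgG mass, grams, from interval increments.

    Each local-basis increment times its interval volume gives the mass
    formed in that interval; the sum must balance the generator's own
    bookkeeping on noiseless runs.
    """
    return float(
        np.sum(rates["delta_mab_local"].to_numpy() * rates["interval_volume"].to_numpy())
        / 1000.0
    )
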