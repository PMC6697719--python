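"""Second-order glycation kinetics of acidic charge-variant formation.

Acidic variants form extracellularly by glycation of newly built IgG,
an irreversible reaction that is second order overall — first order in
the newly built antibody and first order in glucose:

    newly built IgG + glucose  ->  acidic IgG

with the constraints that only part of the antibody pool is
susceptible and that an antibody not converted shortly after synthesis
never converts.  Integrating the rate law gives a linear relationship
between the acidic-variant concentration and a driving integral

    acidic(t) = k * D(t),      D(t) = ∫ [new IgG] * [glucose] dτ

so plotting acidic concentration against D(t) across samples of a run
must give a straight line through the origin with slope k, the
temperature-dependent reaction constant in
(g_acidic·L)/(g_IgG·g_glucose·day).  Pooling runs by their process
temperature and regressing per group yields one k per temperature.

Numerically, D is accumulated by the trapezoid rule on the daily
sampling grid: the newly built IgG concentration of an interval (the
dilution-corrected titer increment, on the common volume basis) is
held piecewise-constant across the interval, and glucose is linearly
interpolated between its sampled values.  The regression is forced
through the origin because the integrated rate law has no intercept;
the intercept of the unconstrained fit is reported as a diagnostic
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class KineticDataset:
    """Per-run kinetic series: D(t) and acidic concentration by day.

    ``acidic_conc`` is the dilution-corrected (common volume basis)
    concentration of acidic species, g/L; ``D_values`` are in
    (g_IgG/L)·(g_glucose/L)·day.  The run's post-shift temperature
    labels the whole run.
    """

    times: np.ndarray
    D_values: np.ndarray
    acidic_conc: np.ndarray
    temperature_group: float
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.D_values = np.asarray(self.D_values, dtype=float)
        self.acidic_conc = np.asarray(self.acidic_conc, dtype=float)
        if not (self.times.size == self.D_values.size == self.acidic_conc.size):
            raise ValidationError("kinetic series lengths differ")
        if self.times.size and abs(self.D_values[0]) > 1e-12:
            raise ValidationError("D must start at zero")
        if np.any(np.diff(self.D_values) < -1e-12):
            raise ValidationError("D must be nondecreasing")

    def restrict(self, mask: np.ndarray) -> "KineticDataset":
        """Subset the series (e.g. to days with a quantified chromatogram)."""
        ds = KineticDataset.__new__(KineticDataset)
        ds.times = self.times[mask]
        ds.D_values = self.D_values[mask]
        ds.acidic_conc = self.acidic_conc[mask]
        ds.temperature_group = self.temperature_group
        ds.run_id = self.run_id
        return ds


@dataclass
class KineticFit:
    """One temperature group's fitted reaction constant and diagnostics."""

    k: float
    r_squared: float
    n_points: int
    residual_sd: float
    intercept_diagnostic: float
    temperature_group: float | None = None
    flags: list = field(default_factory=list)


def compute_D(
    rates: pd.DataFrame,
    corrected: pd.DataFrame,
    temperature_group: float | None = None,
    run_id: str | None = None,
    rebaseline_shift: bool = True,
) -> KineticDataset:
    """Accumulate D(t) on the sampling grid of one run.

    ``rates`` and ``corrected`` must come from the same run (aligned
    days).  Per interval the contribution is ``delta_mab`` times the
    trapezoid of the sampled glucose — the exact integral of a
    piecewise-constant production concentration against a piecewise-
    linear glucose interpolant, so refining the grid between samples
    cannot change the result.

    For temperature-shifted runs the reaction constant changes mid-run,
    so acidic species formed during the shared 37 degC batch phase do
    not belong to the post-shift group's kinetics.  With
    ``rebaseline_shift`` (default) the integral's origin ``t0`` is
    moved to the shift day: the series starts there with D = 0 and the
    acidic concentration measured relative to its shift-day value,
    which is the exact piecewise inversion of the integrated rate law.
    """
    day = corrected["day"].to_numpy(dtype=float)
    mid = rates["midpoint_day"].to_numpy()
    if mid.size != day.size - 1 or not np.allclose(mid, 0.5 * (day[:-1] + day[1:])):
        raise ValidationError("rate series and run records are misaligned")
    glucose = corrected["glucose"].to_numpy(dtype=float)
    dt = rates["dt"].to_numpy()
    delta = rates["delta_mab"].to_numpy()
    g_mean = 0.5 * (glucose[:-1] + glucose[1:])
    D = np.concatenate([[0.0], np.cumsum(delta * g_mean * dt)])
    acidic = corrected["titer_acidic_corr"].to_numpy(dtype=float)

    temps = corrected["temperature"].to_numpy(dtype=float)
    if temperature_group is None:
        temperature_group = float(temps[-1])
    start = 0
    if rebaseline_shift and temps.size and temps[-1] != temps[0]:
        # last record still labelled with the initial temperature
        start = int(np.nonzero(temps == temps[0])[0][-1])
    return KineticDataset(
        times=day[start:],
        D_values=D[start:] - D[start],
        acidic_conc=acidic[start:] - acidic[start],
        temperature_group=temperature_group,
        run_id=run_id or corrected.attrs.get("run_id", "run"),
    )


def fit_k(datasets: list[KineticDataset], through_origin: bool = True) -> KineticFit:
    """Pooled regression of acidic concentration on D for one group.

    All datasets must share one temperature group; replicate runs and
    feeds are pooled.  The primary slope is the least-squares fit
    through the origin, k = sum(D*a) / sum(D^2); the unconstrained
    intercept is reported as ``intercept_diagnostic``.
    """
    if not datasets:
        raise ValidationError("no kinetic datasets to fit")
    groups = {ds.temperature_group for ds in datasets}
    if len(groups) != 1:
        raise ValidationError(f"datasets span multiple temperature groups: {groups}")
    D = np.concatenate([ds.D_values for ds in datasets])
    a = np.concatenate([ds.acidic_conc for ds in datasets])
    if D.size < 3:
        raise ValidationError("need at least 3 pooled points to fit k")

    flags = []
    ss_D = float(np.sum(D * D))
    if ss_D == 0.0:
        if np.any(np.abs(a) > 0):
            flags.append("model violated: acidic species without driving integral")
        return KineticFit(
            k=0.0,
            r_squared=0.0,
            n_points=int(D.size),
            residual_sd=float(np.std(a, ddof=1)) if D.size > 1 else 0.0,
            intercept_diagnostic=float(np.mean(a)),
            temperature_group=groups.pop(),
            flags=flags,
        )

    slope_to = float(np.sum(D * a) / ss_D)
    # unconstrained fit, diagnostic only
    coeffs = np.polyfit(D, a, 1)
    slope = slope_to if through_origin else float(coeffs[0])
    if slope < 0:
        flags.append("negative slope clipped to 0 (model violated)")
        slope = 0.0
    resid = a - slope * D
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(a**2)) if through_origin else float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return KineticFit(
        k=slope,
        r_squared=r2,
        n_points=int(D.size),
        residual_sd=float(np.sqrt(ss_res / max(D.size - 1, 1))),
        intercept_diagnostic=float(coeffs[1]),
        temperature_group=groups.pop(),
        flags=flags,
    )


def fit_by_temperature(
    study: list[KineticDataset],
    through_origin: bool = True,
    exclude_preshift: bool = False,
    shift_day: float = 4.0,
) -> dict[float, KineticFit]:
    """Partition datasets by process temperature and fit each group.

    Whole runs are labelled by their post-shift temperature; with
    ``exclude_preshift`` the samples from the shared 37 degC batch
    phase (day <= ``shift_day``) are dropped before fitting.
    """
    import logging

    groups: dict[float, list[KineticDataset]] = {}
    for ds in study:
        if exclude_preshift:
            ds = ds.restrict(ds.times > shift_day)
        groups.setdefault(ds.temperature_group, []).append(ds)
    fits = {}
    for temp in sorted(groups, reverse=True):
        members = [ds for ds in groups[temp] if ds.times.size]
        if not members:
            logging.getLogger(__name__).warning("empty temperature group %s omitted", temp)
            continue
        fits[temp] = fit_k(members, through_origin=through_origin)
    return fits


def predict_acidic(k: float, D_values) -> np.ndarray:
    """Forward model: acidic(t) = k * D(t)."""
    return k * np.asarray(D_values, dtype=float)


def fits_to_frame(fits: dict[float, KineticFit]) -> pd.DataFrame:
    """Tidy study-level result table, one row per temperature."""
    rows = [
        {
            "temperature": temp,
            "k": fit.k,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "residual_sd": fit.residual_sd,
            "intercept_diagnostic": fit.intercept_diagnostic,
            "flags": "; ".join(fit.flags),
        }
        for temp, fit in fits.items()
    ]
    return pd.DataFrame(rows)
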