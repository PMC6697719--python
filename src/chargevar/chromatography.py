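"""Charge-variant quantification from pH-gradient CEX chromatograms.

A weak cation-exchange separation with a linear pH gradient elutes IgG
charge variants in order of net surface charge: acidic species first,
then the main variant (K0, fully clipped C-terminal lysines), then the
basic lysine variants (K1, K2).  Because shallow pH gradients are
sensitive to small buffer-batch differences, absolute retention times
drift between sequences; the analysis therefore normalizes retention by
the main-variant retention time (``t_normalized = t_i / t_main``) and
integrates peak areas only within a fixed normalized window
(0.76–1.23 by default), the sum of which is the *total peak area*.

The quantification pipeline is deliberately simple and assay-faithful:

1. linear baseline correction fitted through the signal-free leading
   and trailing portions of the trace,
2. peak detection on local maxima with height/prominence thresholds,
   valley-to-valley boundaries, trapezoidal areas,
3. main-peak selection by largest area (abundance read as area),
4. retention normalization and window filtering,
5. classification relative to the main peak's own extent and
   conversion of class areas to relative percentages.

No peak-shape fitting or deconvolution is performed: areas are
integrated on the sampled grid, exactly as an integrating data system
would report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, find_peaks

from .errors import CalibrationError, NoPeaksError, ValidationError

#: default normalized-retention integration window
DEFAULT_WINDOW = (0.76, 1.23)

#: columns of a peak table
PEAK_COLUMNS = [
    "start_time",
    "apex_time",
    "end_time",
    "area",
    "height",
    "prominence",
    "normalized_apex",
    "class_label",
]


@dataclass
class Chromatogram:
    """A sampled UV absorbance trace with pH-gradient metadata.

    Parameters
    ----------
    time
        Retention time in minutes, strictly increasing, uniform step.
    absorbance
        Detector signal in mAU, same length as ``time``.
    metadata
        Free-form dict; the generator stores gradient slope (pH/min),
        start pH, flow rate and injected mass here.
    baseline_corrected
        Provenance flag set by :func:`correct_baseline`.
    flags
        Warnings accumulated while producing the trace (e.g.
        ``"baseline-only"`` for a zero-titer sample).
    """

    time: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)
    baseline_corrected: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.size != self.absorbance.size:
            raise ValidationError("time and absorbance must have equal length")
        if self.time.size < 100:
            raise ValidationError("chromatogram must have at least 100 samples")
        if np.any(~np.isfinite(self.time)) or np.any(~np.isfinite(self.absorbance)):
            raise ValidationError("chromatogram contains missing values")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValidationError("time axis must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValidationError("time axis must be uniformly sampled")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass
class ChargeDistribution:
    """Relative acidic / main / basic areas of one chromatogram.

    Percentages are on a 0–100 scale and sum to 100; areas are in
    mAU·min and sum to ``total_area`` (the total peak area inside the
    normalized integration window).
    """

    acidic_pct: float
    main_pct: float
    basic_pct: float
    total_area: float
    acidic_area: float
    main_area: float
    basic_area: float

    def __post_init__(self) -> None:
        pcts = (self.acidic_pct, self.main_pct, self.basic_pct)
        if min(pcts) < -1e-12:
            raise ValidationError("negative class percentage")
        if abs(sum(pcts) - 100.0) > 1e-9:
            raise ValidationError("class percentages must sum to 100")
        if abs(self.acidic_area + self.main_area + self.basic_area - self.total_area) > 1e-9 * max(
            1.0, self.total_area
        ):
            raise ValidationError("class areas must sum to the total area")

    def as_dict(self) -> dict:
        return {
            "acidic_pct": self.acidic_pct,
            "main_pct": self.main_pct,
            "basic_pct": self.basic_pct,
            "total_area": self.total_area,
            "acidic_area": self.acidic_area,
            "main_area": self.main_area,
            "basic_area": self.basic_area,
        }


def estimate_noise_sd(absorbance: np.ndarray) -> float:
    """Robust noise estimate from first differences.

    The median absolute deviation of successive differences is immune
    to peaks (which occupy few samples and change slowly relative to
    white noise); dividing by sqrt(2) converts a difference SD back to
    a sample SD.
    """
    diffs = np.diff(np.asarray(absorbance, dtype=float))
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return 1.4826 * mad / np.sqrt(2.0)


def correct_baseline(chrom: Chromatogram, fit_fraction: float = 0.1) -> Chromatogram:
    """Subtract a linear baseline fitted through signal-free regions.

    Direct-injection supernatant runs show a slight linear drift of a
    few tenths of a mAU over the gradient.  A straight line is fitted
    by least squares through the leading and trailing ``fit_fraction``
    of samples — regions the method leaves free of product peaks — and
    subtracted from the whole trace.
    """
    n = chrom.n_samples
    m = int(round(n * fit_fraction))
    if m < 3:
        raise ValidationError("trace too short for baseline fit regions")
    idx = np.r_[0:m, n - m : n]
    coeffs = np.polyfit(chrom.time[idx], chrom.absorbance[idx], 1)
    corrected = chrom.absorbance - np.polyval(coeffs, chrom.time)
    return replace(
        chrom,
        absorbance=corrected,
        baseline_corrected=True,
        flags=list(chrom.flags) + ["baseline-corrected"],
    )


def _empty_peak_table() -> pd.DataFrame:
    return pd.DataFrame(columns=PEAK_COLUMNS)


def detect_peaks(
    chrom: Chromatogram,
    min_height: float | None = None,
    min_prominence: float | None = None,
) -> pd.DataFrame:
    """Detect peaks and integrate valley-to-valley areas.

    Local maxima above ``min_height`` with at least ``min_prominence``
    are apexes; each peak's boundaries are the deepest valleys towards
    its neighbours (or towards the trace ends for the outermost peaks)
    and its area is the trapezoidal integral between those boundaries.
    Default thresholds derive from the robust noise estimate of the
    trace: height 5x noise SD, prominence 3x, with a small absolute
    floor so that ideal noiseless traces do not yield zero thresholds.

    Returns a peak table (one row per peak, ordered by apex) with
    ``normalized_apex`` unset and ``class_label`` ``"unassigned"``;
    an empty table is a valid result.
    """
    y = chrom.absorbance
    t = chrom.time
    noise = estimate_noise_sd(y)
    if min_height is None:
        min_height = max(5.0 * noise, 1e-6)
    if min_prominence is None:
        min_prominence = max(3.0 * noise, 1e-6)
    apexes, props = find_peaks(y, height=min_height, prominence=min_prominence)
    if apexes.size == 0:
        return _empty_peak_table()

    # shared valleys between adjacent apexes; trace ends for the outer flanks
    bounds = np.empty(apexes.size + 1, dtype=int)
    bounds[0] = int(np.argmin(y[: apexes[0] + 1]))
    bounds[-1] = apexes[-1] + int(np.argmin(y[apexes[-1] :]))
    for i in range(apexes.size - 1):
        seg = slice(apexes[i], apexes[i + 1] + 1)
        bounds[i + 1] = apexes[i] + int(np.argmin(y[seg]))

    rows = []
    for i, apex in enumerate(apexes):
        lo, hi = bounds[i], bounds[i + 1]
        rows.append(
            {
                "start_time": t[lo],
                "apex_time": t[apex],
                "end_time": t[hi],
                "area": float(np.trapezoid(y[lo : hi + 1], t[lo : hi + 1])),
                "height": float(y[apex]),
                "prominence": float(props["prominences"][i]),
                "normalized_apex": np.nan,
                "class_label": "unassigned",
            }
        )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def select_main_peak(
    peaks: pd.DataFrame, reference_positions: list[float] | None = None
) -> int:
    """Index (label) of the main peak.

    Without a reference pattern the most abundant (largest-area) peak
    is the main variant, ties resolved to the earlier apex.  That rule
    fails for heavily stressed samples where acidic species outgrow
    K0; the assay then anchors identification on the reference
    standard's normalized peak pattern, which is invariant to the
    shared buffer-batch retention shift.  Given ``reference_positions``
    (normalized retentions of the standard's peaks), each detected
    peak is tried as the normalization anchor and the candidate whose
    induced normalized pattern best matches the reference — by
    area-weighted distance to the nearest reference position — wins.
    """
    if len(peaks) == 0:
        raise NoPeaksError("no product detected: empty peak table")
    order = peaks.sort_values(["area", "apex_time"], ascending=[False, True])
    if reference_positions is None or len(peaks) == 1:
        return order.index[0]
    refs = np.asarray(sorted(reference_positions), dtype=float)
    apex = peaks["apex_time"].to_numpy(dtype=float)
    area = peaks["area"].to_numpy(dtype=float)
    best_idx, best_score = None, np.inf
    for idx in order.index:  # area-descending: ties keep the larger peak
        t_cand = peaks.loc[idx, "apex_time"]
        napex = apex / t_cand
        mismatch = np.min(np.abs(napex[:, None] - refs[None, :]), axis=1)
        score = float(np.sum(area * mismatch) / np.sum(area))
        if score < best_score - 1e-12:
            best_idx, best_score = idx, score
    return best_idx


def normalize_retention(peaks: pd.DataFrame, main_index: int | None = None) -> pd.DataFrame:
    """Divide every apex retention time by the main-variant retention time.

    The main peak is chosen by area (two-pass rule: peaks are detected
    on the raw time axis first, then the most abundant one anchors the
    normalization).  Its normalized apex is exactly 1.0.
    """
    if len(peaks) == 0:
        raise NoPeaksError("cannot normalize retention: no peaks")
    if main_index is None:
        main_index = select_main_peak(peaks)
    t_main = peaks.loc[main_index, "apex_time"]
    if t_main <= 0:
        raise ValidationError("main-peak retention time must be positive")
    out = peaks.copy()
    out["normalized_apex"] = out["apex_time"] / t_main
    out.loc[main_index, "normalized_apex"] = 1.0
    return out


def quantify_distribution(
    chrom: Chromatogram,
    min_height: float | None = None,
    min_prominence: float | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    reference_positions: list[float] | None = None,
) -> ChargeDistribution:
    """Full quantification: baseline -> detect -> normalize -> classify.

    Peaks whose normalized apex falls outside ``window`` are excluded
    from the total peak area.  Within the window, peaks eluting before
    the main peak's own left boundary are acidic, after its right
    boundary basic; the boundary-based split keeps shoulders of the
    main peak from being misclassified.
    """
    lo, hi = window
    if not (lo < 1.0 < hi):
        raise ValidationError("integration window must bracket 1.0")
    if not chrom.baseline_corrected:
        chrom = correct_baseline(chrom)
    peaks = detect_peaks(chrom, min_height=min_height, min_prominence=min_prominence)
    if len(peaks) == 0:
        raise NoPeaksError("no product detected")
    main_idx = select_main_peak(peaks, reference_positions=reference_positions)
    peaks = normalize_retention(peaks, main_idx)
    t_main = peaks.loc[main_idx, "apex_time"]
    main_lo = peaks.loc[main_idx, "start_time"] / t_main
    main_hi = peaks.loc[main_idx, "end_time"] / t_main

    acidic = main = basic = 0.0
    for idx, row in peaks.iterrows():
        napex = row["normalized_apex"]
        if not (lo <= napex <= hi):
            continue
        if idx == main_idx or main_lo <= napex <= main_hi:
            main += row["area"]
        elif napex < main_lo:
            acidic += row["area"]
        else:
            basic += row["area"]
    total = acidic + main + basic
    if total <= 0:
        raise NoPeaksError("no product detected: zero total peak area")
    return ChargeDistribution(
        acidic_pct=100.0 * acidic / total,
        main_pct=100.0 * main / total,
        basic_pct=100.0 * basic / total,
        total_area=total,
        acidic_area=acidic,
        main_area=main,
        basic_area=basic,
    )


@dataclass
class Calibration:
    """Linear area-vs-mass calibration: area = slope * mass + intercept."""

    slope: float  # mAU·min per µg
    intercept: float = 0.0  # mAU·min
    slope_ci: tuple[float, float] | None = None
    r_squared: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")


def fit_area_calibration(areas, masses) -> Calibration:
    """Least-squares calibration of total peak area against known IgG mass.

    Ordinary least squares of area on mass, as used to demonstrate that
    the total peak area of direct-injection samples responds linearly
    to the amount of IgG.  The 95% CI of the slope is carried for
    coverage checks.
    """
    import statsmodels.api as sm

    areas = np.asarray(areas, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if areas.size != masses.size or areas.size < 2:
        raise ValidationError("calibration needs >= 2 (area, mass) pairs")
    X = sm.add_constant(masses)
    fit = sm.OLS(areas, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return Calibration(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(fit.rsquared),
        n=int(areas.size),
    )


def estimate_titer_from_area(total_area: float, calibration: Calibration) -> float:
    """Inverse-linear prediction of injected IgG mass (µg) from total area."""
    return (total_area - calibration.intercept) / calibration.slope


def distribution_consistency(samples: list[ChargeDistribution]) -> pd.DataFrame:
    """Per-class mean, sample SD and CV% across replicate distributions.

    CV = SD / mean x 100 with the sample (n-1) standard deviation,
    matching the ``mean ± σ`` reporting convention for replicate
    reference-standard injections.
    """
    if len(samples) < 2:
        raise ValidationError("consistency requires at least 2 replicates")
    data = pd.DataFrame(
        {
            "acidic": [s.acidic_pct for s in samples],
            "main": [s.main_pct for s in samples],
            "basic": [s.basic_pct for s in samples],
        }
    )
    mean = data.mean()
    sd = data.std(ddof=1)
    out = pd.DataFrame(
        {"mean_pct": mean, "sd_pct": sd, "cv_pct": 100.0 * sd / mean}
    )
    out.index.name = "variant_class"
    return out


def write_chromatogram_csv(chrom: Chromatogram, path, metadata_path=None) -> None:
    """Two-column CSV (time_min, absorbance_mau); metadata to a YAML sidecar."""
    import yaml

    pd.DataFrame(
        {"time_min": chrom.time, "absorbance_mau": chrom.absorbance}
    ).to_csv(path, index=False)
    if metadata_path is not None:
        with open(metadata_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dict(chrom.metadata), fh)


def read_chromatogram_csv(path, metadata_path=None) -> Chromatogram:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.read(4096)
    if ";" in head.splitlines()[0]:
        raise ValidationError(
            f"{path}: semicolon-separated file with comma decimals detected; "
            "expected comma-separated CSV with '.' decimal"
        )
    frame = pd.read_csv(path)
    for col in ("time_min", "absorbance_mau"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    metadata = {}
    if metadata_path is not None:
        import yaml

        with open(metadata_path, "r", encoding="utf-8") as fh:
            metadata = yaml.safe_load(fh) or {}
    return Chromatogram(
        time=frame["time_min"].to_numpy(),
        absorbance=frame["absorbance_mau"].to_numpy(),
        metadata=metadata,
    )
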