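"""Synthetic fed-batch trajectories and CEX chromatograms.

This module emulates the study design the analysis modules are built
for: shake-flask CHO fed-batch cultures producing an anti-TNF-alpha
IgG1, run on a 3x3 grid of process temperatures (37 degC held, or
shifted to 34/31 degC at day 4) and glucose feed supplements (+10/+20/
+30 g/L; "Feed 1/2/3"), in duplicate, with daily 11 mL samples, pulse
feeding on days 3-13 totalling 33 vol%, and termination at 70%
viability or day 14.

The generative rules are exactly the structure the downstream analysis
assumes and inverts:

* cell growth is exponential with a temperature-switched maximum rate
  and a logistic density brake (no mechanistic metabolism);
* IgG production and glucose consumption are proportional to the
  log-mean viable cell concentration of each daily interval, with a
  single cell-specific glucose consumption rate ``q_gluc`` that is
  independent of feed and temperature;
* a fixed temperature-dependent fraction of each interval's newly
  built IgG carries unclipped C-terminal lysines (basic variants,
  an intracellular mechanism);
* acidic variants form extracellularly by glycation of *newly built*
  IgG only: the fraction of interval ``i``'s new IgG converted is
  ``min(k(T) * mean_glucose_i * dt, susceptible_fraction)``, a
  second-order rule that is first-order in each of new IgG and
  glucose.  The susceptible-pool cap encodes the constraint that an
  antibody not transformed within its own interval is never
  transformed later.  ``mean_glucose`` is the trapezoid of the sampled
  (pre-feed) glucose at the interval's endpoints, i.e. the reaction is
  defined on the daily sampling grid the analysis sees.

Chromatograms are sums of Gaussian peaks whose total area is linear in
the injected IgG mass, partitioned among acidic/K0/basic positions in
the record's proportions, with linear baseline drift, i.i.d. detector
noise and one shared retention-jitter factor per chromatogram
(buffer-batch retention shifts move all peaks together).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chromatography import Chromatogram
from .errors import ValidationError

# --------------------------------------------------------------------------
# parameters

#: reaction constants fitted in the study, (g_acidic*L)/(g_IgG*g_glucose*day)
K_PER_TEMP = {37.0: 0.09, 34.0: 0.04, 31.0: 0.03}

#: reference-standard composition (acidic, main, basic) in percent
STANDARD_COMPOSITION = (16.2, 59.2, 24.5)


def _as_temp_map(mapping: dict) -> dict[float, float]:
    return {float(k): float(v) for k, v in mapping.items()}


@dataclass
class SimulationParams:
    """Parameters of one synthetic fed-batch cultivation.

    Units: days, degC, mL, cells/mL, g/L; ``q_p`` in pg/cell/day;
    ``q_gluc`` expressed as g/L consumed per (cells/mL) per day (the
    same mixed volumetric basis specific rates are reported on);
    ``k_per_temp`` in (g_acidic*L)/(g_IgG*g_glucose*day).
    """

    temperature_schedule: tuple = ((0, 37.0),)
    feed_glucose_add: float = 10.0  # extra glucose in the feed, g/L
    feed_start_day: int = 3
    feed_end_day: int = 13
    total_feed_fraction: float = 0.33
    mu_max_per_temp: dict = field(default_factory=lambda: {37.0: 0.55, 34.0: 0.32, 31.0: 0.22})
    q_p_per_temp: dict = field(default_factory=lambda: {37.0: 15.0, 34.0: 12.0, 31.0: 8.0})
    q_gluc: float = 1.1e-7
    k_per_temp: dict = field(default_factory=lambda: dict(K_PER_TEMP))
    basic_fraction_per_temp: dict = field(
        default_factory=lambda: {37.0: 0.04, 34.0: 0.05, 31.0: 0.09}
    )
    susceptible_fraction: float = 0.95
    start_volume: float = 300.0
    sample_volume: float = 11.0
    inoculation_density: float = 2.5e5
    initial_glucose: float = 4.0
    feed_base_glucose: float = 8.0
    vcc_max_per_temp: dict = field(
        default_factory=lambda: {37.0: 1.4e7, 34.0: 8.0e6, 31.0: 5.0e6}
    )
    viability_stop: float = 0.70
    viability_midpoint_day: float = 15.5
    viability_width: float = 1.2
    max_day: int = 14
    lactate_yield: float = 0.25  # g lactate per g glucose, batch phase only
    lactate_decay: float = 0.30  # fractional daily consumption, fed phase
    titer_noise_cv: float = 0.0
    glucose_noise_cv: float = 0.0
    vcc_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_max_per_temp = _as_temp_map(self.mu_max_per_temp)
        self.q_p_per_temp = _as_temp_map(self.q_p_per_temp)
        self.k_per_temp = _as_temp_map(self.k_per_temp)
        self.basic_fraction_per_temp = _as_temp_map(self.basic_fraction_per_temp)
        self.vcc_max_per_temp = _as_temp_map(self.vcc_max_per_temp)
        self.temperature_schedule = tuple(
            (int(d), float(t)) for d, t in self.temperature_schedule
        )
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.total_feed_fraction < 1.0:
            raise ValidationError("total_feed_fraction must be in (0, 1)")
        sched = self.temperature_schedule
        if not sched or sched[0][0] != 0 or sched[0][1] != 37.0:
            raise ValidationError("temperature schedule must start at day 0 at 37 degC")
        if len(sched) > 2:
            raise ValidationError("at most one temperature shift is supported")
        if len(sched) == 2 and sched[1][0] != 4:
            raise ValidationError("the temperature shift must occur at day 4")
        for name, rates in (
            ("mu_max_per_temp", self.mu_max_per_temp),
            ("q_p_per_temp", self.q_p_per_temp),
            ("k_per_temp", self.k_per_temp),
            ("basic_fraction_per_temp", self.basic_fraction_per_temp),
        ):
            if any(v < 0 for v in rates.values()):
                raise ValidationError(f"{name} must be non-negative")
        if self.q_gluc < 0:
            raise ValidationError("q_gluc must be non-negative")
        if not 0.0 < self.susceptible_fraction <= 1.0:
            raise ValidationError("susceptible_fraction must be in (0, 1]")
        if self.start_volume <= 0 or self.sample_volume < 0:
            raise ValidationError("volumes must be positive")

    def temperature_at(self, day: float) -> float:
        """Temperature in effect for the interval starting at ``day``."""
        temp = self.temperature_schedule[0][1]
        for shift_day, shift_temp in self.temperature_schedule:
            if day >= shift_day:
                temp = shift_temp
        return temp

    @property
    def final_temperature(self) -> float:
        return self.temperature_schedule[-1][1]

    @property
    def feed_pulse_volume(self) -> float:
        """Volume of one daily feed pulse, mL.

        The total feed is planned as ``total_feed_fraction`` of the
        nominal end volume (start + feed, sampling losses excluded from
        the plan) and delivered linearly over the feed days.
        """
        n_pulses = self.feed_end_day - self.feed_start_day + 1
        if n_pulses <= 0:  # feed-free configuration (batch culture)
            return 0.0
        f = self.total_feed_fraction
        total = f / (1.0 - f) * self.start_volume
        return total / n_pulses

    def viability_at(self, day: float) -> float:
        """Logistic viability decline with a nutrient-independent midpoint."""
        z = (day - self.viability_midpoint_day) / self.viability_width
        return 1.0 / (1.0 + math.exp(z))


@dataclass
class ProcessRecord:
    """One daily offline sample of a fed-batch cultivation."""

    day: int
    vcc: float  # cells/mL
    viability: float
    titer_total: float  # g/L
    titer_acidic: float  # g/L
    titer_basic: float  # g/L
    glucose: float  # g/L
    lactate: float  # g/L
    osmolality: float  # mOsm/kg (passive reporter)
    volume_before_sample: float  # mL
    feed_added_today: float  # mL, applied after this day's sample
    temperature: float  # degC

    def __post_init__(self) -> None:
        if not 0.0 <= self.viability <= 1.0:
            raise ValidationError("viability must lie in [0, 1]")
        if self.glucose < 0:
            raise ValidationError("glucose must be non-negative")
        if self.titer_acidic + self.titer_basic > self.titer_total + 1e-9:
            raise ValidationError("variant titers exceed the total titer")
        if self.volume_before_sample <= 0:
            raise ValidationError("volume must be positive")


RECORD_COLUMNS = [
    "day",
    "vcc",
    "viability",
    "titer_total",
    "titer_acidic",
    "titer_basic",
    "glucose",
    "lactate",
    "osmolality",
    "volume_before_sample",
    "feed_added_today",
    "temperature",
]


@dataclass
class FedBatchRun:
    """Daily records of one cultivation plus its generating parameters.

    ``mu_applied`` stores the per-interval growth rate the generator
    actually applied (the logistic brake makes it time-varying); it is
    generator-side ground truth for rate-recovery checks, not part of
    the record schema.  ``mass_produced_g``/``mass_sampled_g`` support
    mass-balance audits.
    """

    records: list
    params: SimulationParams
    run_id: str = "run"
    warnings: list = field(default_factory=list)
    mu_applied: list = field(default_factory=list)
    mass_produced_g: float = 0.0
    mass_sampled_g: float = 0.0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("a run must contain at least one record")
        days = [r.day for r in self.records]
        if days != sorted(days) or days[0] != 0:
            raise ValidationError("records must be day-sorted and start at day 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=RECORD_COLUMNS)

    def write_csv(self, path, params_path=None) -> None:
        """One row per day, fixed header, UTF-8, '.' decimal."""
        self.to_frame().to_csv(path, index=False)
        if params_path is not None:
            import json

            payload = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.params).items()
            }
            payload["run_id"] = self.run_id
            with open(params_path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)


def read_fedbatch_csv(path, params_path=None, run_id: str | None = None) -> FedBatchRun:
    """Read a run CSV (with optional JSON parameter sidecar) back."""
    import json

    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    if ";" in head:
        raise ValidationError(
            f"{path}: semicolon-separated file with comma decimals detected; "
            "expected comma-separated CSV with '.' decimal"
        )
    frame = pd.read_csv(path)
    for col in RECORD_COLUMNS:
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    params = SimulationParams()
    if params_path is not None:
        with open(params_path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        sidecar_run_id = payload.pop("run_id", None)
        run_id = run_id or sidecar_run_id
        if "temperature_schedule" in payload:
            payload["temperature_schedule"] = tuple(
                tuple(x) for x in payload["temperature_schedule"]
            )
        params = SimulationParams(**payload)
    records = [
        ProcessRecord(**{k: row[k] for k in RECORD_COLUMNS})
        for _, row in frame.astype({"day": int}).iterrows()
    ]
    return FedBatchRun(records=records, params=params, run_id=run_id or "run")


def _logmean(a: float, b: float) -> float:
    if a <= 0 or b <= 0:
        raise ValidationError("viable cell concentration must stay positive")
    if abs(a - b) < 1e-12 * max(a, b):
        return 0.5 * (a + b)
    return (b - a) / math.log(b / a)


def _osmolality(glucose: float) -> float:
    # linear reporter spanning roughly 233 mOsm/kg at 1.5 g/L to 345 at 15 g/L
    return 220.0 + 8.3 * glucose


def simulate_fedbatch(params: SimulationParams, run_id: str = "run") -> FedBatchRun:
    """Simulate one cultivation from inoculation to harvest.

    Each daily interval applies, in order: sample-volume removal
    (concentration-neutral), feed addition with dilution of all
    dissolved species and cells, exponential growth, IgG production,
    glucose consumption bounded at zero, acidic conversion of the
    interval's newly built IgG, and the fixed basic fraction.  Records
    are written before that day's sample/feed, so recorded glucose is
    the pre-feed concentration.  The run is deterministic given the
    seed; with all noise CVs at zero it is reproducible bit-for-bit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    noisy = (
        params.titer_noise_cv > 0
        or params.glucose_noise_cv > 0
        or params.vcc_noise_cv > 0
    )

    volume = params.start_volume
    vcc = params.inoculation_density
    titer_total = titer_acidic = titer_basic = 0.0
    glucose = params.initial_glucose
    lactate = 0.1
    warnings: list[str] = []
    mu_applied: list[float] = []
    mass_produced = 0.0
    mass_sampled = 0.0
    records: list[ProcessRecord] = []

    def emit_record(day: int, temp: float) -> ProcessRecord:
        feed_today = (
            params.feed_pulse_volume
            if params.feed_start_day <= day <= params.feed_end_day
            else 0.0
        )
        tf = gf = vf = 1.0
        if noisy:
            tf = max(0.05, 1.0 + params.titer_noise_cv * rng.standard_normal())
            gf = max(0.05, 1.0 + params.glucose_noise_cv * rng.standard_normal())
            vf = max(0.05, 1.0 + params.vcc_noise_cv * rng.standard_normal())
        rec = ProcessRecord(
            day=day,
            vcc=vcc * vf,
            viability=params.viability_at(day),
            titer_total=titer_total * tf,
            titer_acidic=titer_acidic * tf,
            titer_basic=titer_basic * tf,
            glucose=glucose * gf,
            lactate=lactate,
            osmolality=_osmolality(glucose * gf),
            volume_before_sample=volume,
            feed_added_today=feed_today,
            temperature=temp,
        )
        records.append(rec)
        return rec

    emit_record(0, params.temperature_at(0))

    for day in range(params.max_day):
        temp = params.temperature_at(day)
        glucose_at_sample = glucose  # pre-feed, what the record reported

        # sample removal (concentration-neutral), then feed pulse
        mass_sampled += titer_total * params.sample_volume / 1000.0
        volume -= params.sample_volume
        if volume <= 0:
            raise ValidationError("sampling exhausted the culture volume")
        feed = records[-1].feed_added_today
        if feed > 0:
            feed_glucose = params.feed_base_glucose + params.feed_glucose_add
            ratio = volume / (volume + feed)
            glucose = glucose * ratio + feed_glucose * (1.0 - ratio)
            vcc *= ratio
            titer_total *= ratio
            titer_acidic *= ratio
            titer_basic *= ratio
            lactate *= ratio
            volume += feed

        # growth with logistic density brake; the attainable density is
        # temperature-dependent (temperature shift arrests proliferation)
        vcc_max = params.vcc_max_per_temp[temp]
        mu = params.mu_max_per_temp[temp] * max(0.0, 1.0 - vcc / vcc_max)
        vcc_end = vcc * math.exp(mu)
        mu_applied.append(mu)
        cells = _logmean(vcc, vcc_end)  # cells/mL, integrated over the day

        # production and consumption (pg/cell/day x cells/mL -> 1e-9 g/L)
        new_mab = params.q_p_per_temp[temp] * cells * 1e-9
        consumed = params.q_gluc * cells
        glucose_end = glucose - consumed
        if glucose_end < 0.0:
            glucose_end = 0.0
            if day < params.feed_start_day:
                flag = f"glucose exhausted on day {day} before feed start"
            else:
                flag = f"glucose exhausted on day {day}"
            if flag not in warnings:
                warnings.append(flag)

        # acidic conversion of this interval's newly built IgG, driven by
        # the trapezoid of the *sampled* glucose at the interval endpoints
        basic_frac = params.basic_fraction_per_temp[temp]
        mean_glucose = 0.5 * (glucose_at_sample + glucose_end)
        cap = min(params.susceptible_fraction, 1.0 - basic_frac)
        conv = min(params.k_per_temp[temp] * mean_glucose, cap)
        titer_acidic += conv * new_mab
        titer_basic += basic_frac * new_mab
        titer_total += new_mab
        mass_produced += new_mab * volume / 1000.0

        if day < params.feed_start_day:
            lactate += params.lactate_yield * (glucose - glucose_end)
        else:
            lactate *= 1.0 - params.lactate_decay

        vcc = vcc_end
        glucose = glucose_end

        # record temperature reflects the interval that produced it; the
        # shifted temperature first appears on the day-5 record
        rec = emit_record(day + 1, temp)
        if rec.viability < params.viability_stop:
            warnings.append(f"harvested at day {day + 1}: viability below stop")
            break

    run = FedBatchRun(
        records=records,
        params=params,
        run_id=run_id,
        warnings=warnings,
        mu_applied=mu_applied,
        mass_produced_g=mass_produced,
        mass_sampled_g=mass_sampled,
    )
    return run


# --------------------------------------------------------------------------
# chromatogram synthesis


@dataclass
class ChromatogramParams:
    """Shape and noise parameters of synthetic CEX traces.

    Peak centers are placed at fixed normalized retentions (relative to
    the main K0 peak) inside the 0.76-1.23 integration window; the K0
    retention time follows from the antibody pI and the gradient:
    ``t_main = (pI - start_pH) / gradient_slope``.
    """

    flow_rate: float = 1.0  # mL/min
    injection_volume: float = 100.0  # µL
    gradient_slope: float = 0.07  # pH/min
    start_ph: float = 7.0
    mab_pi: float = 8.6
    peak_positions_normalized: dict = field(
        default_factory=lambda: {
            "A3": 0.80,
            "A2": 0.87,
            "A1": 0.93,
            "K0": 1.00,
            "K1": 1.07,
            "K2": 1.14,
        }
    )
    acidic_split: dict = field(default_factory=lambda: {"A3": 0.2, "A2": 0.3, "A1": 0.5})
    basic_split: dict = field(default_factory=lambda: {"K1": 0.7, "K2": 0.3})
    peak_width: float = 0.20  # Gaussian sigma, min
    baseline_drift: float = 0.3  # mAU across the trace
    baseline_offset: float = 0.5  # mAU
    noise_sd: float = 0.05  # mAU
    retention_jitter_sd: float = 0.015  # relative, shared per chromatogram
    area_per_mass: float = 0.2  # mAU·min per µg IgG
    trace_end: float = 35.0  # min
    sampling_interval: float = 0.01  # min
    seed: int = 0

    def __post_init__(self) -> None:
        pos = self.peak_positions_normalized
        if "K0" not in pos or pos["K0"] != 1.0:
            raise ValidationError("peak positions must include K0 at exactly 1.0")
        for label, p in pos.items():
            if not 0.76 <= p <= 1.23:
                raise ValidationError(f"peak {label} outside the normalized window")
            if label in self.acidic_split and p >= 1.0:
                raise ValidationError("acidic peaks must elute before the main peak")
            if label in self.basic_split and p <= 1.0:
                raise ValidationError("basic peaks must elute after the main peak")
        ordered = sorted(pos.values())
        min_gap = min(b - a for a, b in zip(ordered, ordered[1:]))
        if min_gap * self.t_main < 4.0 * self.peak_width:
            raise ValidationError("peaks too wide to be valley-separated")
        if not 0.0 <= self.baseline_drift <= 2.0:
            raise ValidationError("baseline drift out of plausible range")

    @property
    def t_main(self) -> float:
        return (self.mab_pi - self.start_ph) / self.gradient_slope

    def metadata(self) -> dict:
        return {
            "flow_rate_ml_min": self.flow_rate,
            "injection_volume_ul": self.injection_volume,
            "gradient_slope_ph_min": self.gradient_slope,
            "start_ph": self.start_ph,
        }


def synthesize_chromatogram(
    record,
    cparams: ChromatogramParams,
    rng: np.random.Generator | None = None,
) -> Chromatogram:
    """Render one record's charge composition as a CEX trace.

    Total Gaussian area equals ``area_per_mass`` x injected IgG mass
    (1 g/L titer in a 100 µL injection is 100 µg), partitioned among
    the acidic/K0/basic positions in the record's proportions.  A
    single jitter factor scales every peak center; baseline drift and
    i.i.d. noise are added last.
    """
    if rng is None:
        rng = np.random.default_rng(cparams.seed)
    t = np.arange(0.0, cparams.trace_end + cparams.sampling_interval / 2, cparams.sampling_interval)
    y = cparams.baseline_offset + cparams.baseline_drift * t / cparams.trace_end
    flags: list[str] = []

    titer = float(record.titer_total)
    jitter = 1.0 + cparams.retention_jitter_sd * rng.standard_normal()
    if titer <= 0.0:
        flags.append("baseline-only")
    else:
        mass_ug = titer * cparams.injection_volume  # g/L x µL == µg
        total_area = cparams.area_per_mass * mass_ug
        frac_acidic = record.titer_acidic / titer
        frac_basic = record.titer_basic / titer
        frac_main = 1.0 - frac_acidic - frac_basic
        label_area = {"K0": frac_main * total_area}
        for label, w in cparams.acidic_split.items():
            label_area[label] = frac_acidic * total_area * w
        for label, w in cparams.basic_split.items():
            label_area[label] = frac_basic * total_area * w
        sigma = cparams.peak_width
        for label, area in label_area.items():
            if area <= 0:
                continue
            center = cparams.peak_positions_normalized[label] * cparams.t_main * jitter
            y = y + area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
                -0.5 * ((t - center) / sigma) ** 2
            )
    if cparams.noise_sd > 0:
        y = y + cparams.noise_sd * rng.standard_normal(t.size)

    meta = cparams.metadata()
    meta.update({"day": getattr(record, "day", None), "jitter_factor": jitter})
    return Chromatogram(time=t, absorbance=y, metadata=meta, flags=flags)


@dataclass
class _StandardRecord:
    """Minimal record-like carrier for reference-standard injections."""

    day: int
    titer_total: float
    titer_acidic: float
    titer_basic: float


def standard_record(
    composition: tuple[float, float, float] = STANDARD_COMPOSITION,
    titer: float = 1.0,
) -> _StandardRecord:
    """A pseudo-record holding a reference-standard composition (percent)."""
    acidic, main, basic = composition
    total = acidic + main + basic
    return _StandardRecord(
        day=0,
        titer_total=titer,
        titer_acidic=titer * acidic / total,
        titer_basic=titer * basic / total,
    )


def replicate_standards(
    n: int,
    cparams: ChromatogramParams,
    composition: tuple[float, float, float] = STANDARD_COMPOSITION,
    titer: float = 1.0,
    seed: int | None = None,
) -> list[Chromatogram]:
    """``n`` replicate injections of one reference standard.

    Each replicate draws its own retention-jitter factor and detector
    noise, and a baseline drift uniform in [0.2, 0.4] mAU — the
    between-sequence variability replicate consistency is judged
    against.
    """
    rng = np.random.default_rng(cparams.seed if seed is None else seed)
    rec = standard_record(composition, titer)
    out = []
    for _ in range(n):
        cp = replace(cparams, baseline_drift=float(rng.uniform(0.2, 0.4)))
        out.append(synthesize_chromatogram(rec, cp, rng=rng))
    return out


# --------------------------------------------------------------------------
# study-level generation


def study_design(
    master_seed: int = 0,
    temperatures: tuple = (37.0, 34.0, 31.0),
    feeds: tuple = (10.0, 20.0, 30.0),
    replicates: int = 2,
    noisy: bool = True,
    k_per_temp: dict | None = None,
    **overrides,
) -> list[SimulationParams]:
    """Parameter sets for the full temperature x feed x replicate grid.

    Per-run seeds are derived deterministically from ``master_seed``
    via :class:`numpy.random.SeedSequence`, so the same master seed
    always regenerates the identical study.  ``noisy`` applies the
    default measurement noise (5% titer CV, 3% glucose and VCC CV).
    """
    n = len(temperatures) * len(feeds) * replicates
    seeds = np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF
    if noisy:
        overrides.setdefault("titer_noise_cv", 0.05)
        overrides.setdefault("glucose_noise_cv", 0.03)
        overrides.setdefault("vcc_noise_cv", 0.03)
    design = []
    i = 0
    for temp in temperatures:
        schedule = ((0, 37.0),) if temp == 37.0 else ((0, 37.0), (4, float(temp)))
        for feed in feeds:
            for rep in range(replicates):
                kwargs = dict(overrides)
                if k_per_temp is not None:
                    kwargs["k_per_temp"] = dict(k_per_temp)
                design.append(
                    SimulationParams(
                        temperature_schedule=schedule,
                        feed_glucose_add=float(feed),
                        seed=int(seeds[i]),
                        **kwargs,
                    )
                )
                i += 1
    return design


def run_label(params: SimulationParams, rep: int | None = None) -> str:
    label = f"T{params.final_temperature:g}_F{params.feed_glucose_add:g}"
    return label if rep is None else f"{label}_r{rep}"


def generate_study(design: list[SimulationParams]) -> list[FedBatchRun]:
    """Simulate every run of a study design."""
    runs = []
    counts: dict[str, int] = {}
    for params in design:
        base = run_label(params)
        rep = counts.get(base, 0)
        counts[base] = rep + 1
        runs.append(simulate_fedbatch(params, run_id=f"{base}_r{rep}"))
    return runs
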