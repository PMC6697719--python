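"""End-to-end orchestration: study -> quantification -> rates -> kinetics.

The pipeline ties the modules together in the order the analysis runs
in the lab: obtain fed-batch runs (synthetic or from CSV), quantify
each sample's charge distribution from its chromatogram, dilution-
correct the process records, accumulate the driving integral D(t), and
fit the per-temperature reaction constants.  A single config object is
the source of truth; the effective config and its hash are embedded in
the report so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatography as cx
from . import kinetics as kin
from . import process as proc
from . import simulate as sim
from .errors import NoPeaksError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline execution.

    ``synthetic`` selects between generating the study in silico and
    reading run/chromatogram CSVs from ``input_dir``.  ``window`` is
    the normalized-retention integration window (must bracket 1.0).
    """

    synthetic: bool = True
    input_dir: str | None = None
    output_dir: str = "chargevar_out"
    master_seed: int = 0
    temperatures: tuple = (37.0, 34.0, 31.0)
    feeds: tuple = (10.0, 20.0, 30.0)
    replicates: int = 2
    noisy: bool = True
    k_per_temp: dict | None = None
    simulation_overrides: dict = field(default_factory=dict)
    chromatogram_overrides: dict = field(default_factory=dict)
    window: tuple = (0.76, 1.23)
    min_height: float | None = None
    min_prominence: float | None = None
    through_origin: bool = True
    exclude_preshift: bool = False
    use_chromatograms: bool = True
    make_plots: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < 1.0 < hi:
            raise ValidationError("integration window must satisfy lower < 1 < upper")
        if not self.synthetic and not self.input_dir:
            raise ValidationError("input_dir is required when synthetic is off")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("temperatures", "feeds", "window"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        data = asdict(self)
        for key in ("temperatures", "feeds", "window"):
            data[key] = list(data[key])
        return data

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All study-level results plus provenance."""

    config: PipelineConfig
    distributions: pd.DataFrame
    rates: pd.DataFrame
    fits: dict
    warnings: list

    @property
    def k_table(self) -> pd.DataFrame:
        return kin.fits_to_frame(self.fits)


def _study_runs(config: PipelineConfig):
    design = sim.study_design(
        master_seed=config.master_seed,
        temperatures=config.temperatures,
        feeds=config.feeds,
        replicates=config.replicates,
        noisy=config.noisy,
        k_per_temp=config.k_per_temp,
        **config.simulation_overrides,
    )
    return sim.generate_study(design)


def read_inputs(input_dir) -> tuple[list, dict, list]:
    """Load run CSVs and paired chromatograms from a directory.

    Expects ``run_<id>.csv`` (+ optional ``run_<id>.params.json``) and
    ``chrom_<id>_day<D>.csv`` (+ optional ``.meta.yaml``).  Returns
    (runs, {(run_id, day): chromatogram}, warnings).  A chromatogram
    without a matching (run, day) record is skipped with a warning;
    duplicated pairs are an error.
    """
    input_dir = Path(input_dir)
    run_files = sorted(input_dir.glob("run_*.csv"))
    if not run_files:
        raise ValidationError(f"no run CSVs found in {input_dir}")
    runs = []
    for path in run_files:
        if path.name.endswith(".params.json"):
            continue
        run_id = path.stem[len("run_") :]
        params_path = input_dir / f"run_{run_id}.params.json"
        runs.append(
            sim.read_fedbatch_csv(
                path, params_path if params_path.exists() else None, run_id=run_id
            )
        )
    known = {(r.run_id, rec.day) for r in runs for rec in r.records}
    chrom_map: dict = {}
    warnings = []
    for path in sorted(input_dir.glob("chrom_*_day*.csv")):
        stem = path.stem
        run_id, _, day_part = stem[len("chrom_") :].rpartition("_day")
        try:
            day = int(day_part)
        except ValueError as exc:
            raise ValidationError(f"{path}: cannot parse day from filename") from exc
        key = (run_id, day)
        if key in chrom_map:
            raise ValidationError(f"duplicated chromatogram for run {run_id} day {day}")
        meta = path.with_suffix(".meta.yaml")
        chrom = cx.read_chromatogram_csv(path, meta if meta.exists() else None)
        if key not in known:
            warnings.append(f"unpaired chromatogram {path.name}")
            logger.warning("unpaired chromatogram %s", path.name)
            continue
        chrom_map[key] = chrom
    return runs, chrom_map, warnings


def _quantify_run(run, chroms_for_run, config, cparams, chrom_seed):
    """Charge distributions for every sample of one run.

    In synthetic mode each record's chromatogram is rendered on the
    fly; traces where no product is detectable yet (early, low-titer
    days) are skipped with a warning, as they would be in practice.
    """
    rows = []
    warnings = []
    rng = np.random.default_rng(chrom_seed)
    for rec in run.records:
        chrom = chroms_for_run.get(rec.day) if chroms_for_run is not None else None
        if chrom is None:
            if not config.synthetic:
                continue
            chrom = sim.synthesize_chromatogram(rec, cparams, rng=rng)
        try:
            dist = cx.quantify_distribution(
                chrom,
                min_height=config.min_height,
                min_prominence=config.min_prominence,
                window=config.window,
                # normalized pattern of the daily reference-standard
                # injection anchors main-peak identification
                reference_positions=sorted(cparams.peak_positions_normalized.values()),
            )
        except NoPeaksError:
            warnings.append(f"{run.run_id} day {rec.day}: no product detected, skipped")
            continue
        rows.append({"run_id": run.run_id, "day": rec.day, **dist.as_dict()})
    return pd.DataFrame(rows), warnings


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full analysis and return the study report."""
    all_warnings: list[str] = []
    chrom_map = None
    if config.synthetic:
        runs = _study_runs(config)
    else:
        runs, chrom_map, w = read_inputs(config.input_dir)
        all_warnings.extend(w)

    cparams = sim.ChromatogramParams(**config.chromatogram_overrides)
    chrom_seeds = np.random.SeedSequence(config.master_seed + 1).generate_state(
        len(runs)
    ) & 0x7FFFFFFF

    dist_frames = []
    rate_frames = []
    datasets = []
    for i, run in enumerate(runs):
        all_warnings.extend(f"{run.run_id}: {w}" for w in run.warnings)
        corrected = proc.dilution_correct(run)
        rates = proc.compute_rates(run, corrected)
        if rates.attrs.get("n_clipped"):
            all_warnings.append(
                f"{run.run_id}: {rates.attrs['n_clipped']} negative IgG increment(s) clipped"
            )
        rf = rates.copy()
        rf.insert(0, "run_id", run.run_id)
        rate_frames.append(rf)

        dataset = kin.compute_D(rates, corrected, run_id=run.run_id)
        if config.use_chromatograms:
            chroms_for_run = (
                {d: c for (rid, d), c in chrom_map.items() if rid == run.run_id}
                if chrom_map is not None
                else None
            )
            dists, w = _quantify_run(run, chroms_for_run, config, cparams, int(chrom_seeds[i]))
            all_warnings.extend(w)
            if len(dists):
                dist_frames.append(dists)
                # acidic concentration = acidic% x dilution-corrected titer
                titer_by_day = dict(
                    zip(corrected["day"].astype(int), corrected["titer_total_corr"])
                )
                chrom_acidic = {
                    int(d): pct / 100.0 * titer_by_day[int(d)]
                    for d, pct in zip(dists["day"], dists["acidic_pct"])
                }
                ds_idx = {int(d): j for j, d in enumerate(dataset.times)}
                start_day = int(dataset.times[0])
                # baseline value at the series origin (shift day for shifted
                # runs, day 0 otherwise); fall back to the record titer when
                # that day's trace had no quantifiable product
                base = chrom_acidic.get(start_day)
                if base is None:
                    acidic_by_day = dict(
                        zip(corrected["day"].astype(int), corrected["titer_acidic_corr"])
                    )
                    base = acidic_by_day[start_day]
                qdays = [d for d in chrom_acidic if d in ds_idx and d != start_day]
                if qdays:
                    ds = dataset.restrict(np.array([ds_idx[d] for d in qdays]))
                    ds.acidic_conc = np.array([chrom_acidic[d] - base for d in qdays])
                    datasets.append(ds)
        else:
            datasets.append(dataset)

    fits = kin.fit_by_temperature(
        datasets,
        through_origin=config.through_origin,
        exclude_preshift=config.exclude_preshift,
    )
    distributions = (
        pd.concat(dist_frames, ignore_index=True) if dist_frames else pd.DataFrame()
    )
    rates_all = pd.concat(rate_frames, ignore_index=True) if rate_frames else pd.DataFrame()
    if all_warnings:
        logger.warning("pipeline finished with %d warning(s)", len(all_warnings))
    return StudyReport(
        config=config,
        distributions=distributions,
        rates=rates_all,
        fits=fits,
        warnings=all_warnings,
    )


def write_report(report: StudyReport, output_dir=None, force: bool | None = None) -> dict:
    """Write CSV/JSON outputs (and optional plots) to the output directory.

    Refuses to overwrite an existing report unless ``force``; plotting
    failures are logged and never alter the data outputs.  Returns the
    mapping of artifact names to paths.
    """
    config = report.config
    output_dir = Path(output_dir if output_dir is not None else config.output_dir)
    force = config.force if force is None else force
    report_json = output_dir / "report.json"
    if report_json.exists() and not force:
        raise ValidationError(f"{report_json} exists; pass force to overwrite")
    output_dir.mkdir(parents=True, exist_ok=True)

    paths = {"report": report_json}
    report.distributions.to_csv(output_dir / "distributions.csv", index=False)
    report.rates.to_csv(output_dir / "rates.csv", index=False)
    report.k_table.to_csv(output_dir / "kinetics_by_temperature.csv", index=False)
    paths.update(
        distributions=output_dir / "distributions.csv",
        rates=output_dir / "rates.csv",
        kinetics=output_dir / "kinetics_by_temperature.csv",
    )
    payload = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "k_by_temperature": {
            f"{temp:g}": {
                "k": fit.k,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "residual_sd": fit.residual_sd,
                "intercept_diagnostic": fit.intercept_diagnostic,
                "flags": fit.flags,
            }
            for temp, fit in report.fits.items()
        },
        "warnings": report.warnings,
    }
    with open(report_json, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")

    if config.make_plots:
        try:
            paths["plots"] = _write_plots(report, output_dir)
        except Exception:  # plotting must never corrupt data outputs
            logger.exception("plot generation failed; data outputs are complete")
    return paths


def _write_plots(report: StudyReport, output_dir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if len(report.rates):
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for run_id, grp in report.rates.groupby("run_id"):
            axes[0].plot(grp["midpoint_day"], grp["mu"], marker="o", ms=3, label=run_id)
            axes[1].plot(grp["mu"], grp["q_gluc"], "o", ms=3)
        axes[0].set_xlabel("day")
        axes[0].set_ylabel("µ (1/day)")
        axes[1].set_xlabel("µ (1/day)")
        axes[1].set_ylabel("q_gluc")
        fig.tight_layout()
        path = output_dir / "process_rates.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if len(report.distributions):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for run_id, grp in report.distributions.groupby("run_id"):
            ax.plot(grp["day"], grp["acidic_pct"], marker="o", ms=3, label=run_id)
        ax.set_xlabel("day")
        ax.set_ylabel("acidic variants (%)")
        ax.legend(fontsize=5)
        fig.tight_layout()
        path = output_dir / "acidic_fraction.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
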