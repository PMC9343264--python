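"""End-to-end orchestration: simulate or load, preprocess, analyse, compare.

A :class:`RunConfig` fully determines a run: given the same configuration,
seeds and input data, every output CSV is byte-identical across reruns.
Outcome labels are read only by the comparison stage — preprocessing and
per-patient index/spectral computation never see them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

import numpy as np

from .cohort import compare_groups, duration_sweep, frequency_sweep
from .errors import ConfigError, DataError
from .indices import INDEX_NAMES, compute_indices, index_battery
from .io import FLOAT_FORMAT, read_cohort, write_cohort
from .preprocessing import (
    DEFAULT_DIFF_SD_MULTIPLE,
    DEFAULT_THRESHOLD_MMHG,
    DEFAULT_WINDOW_S,
    preprocess,
)
from .resampling import DEFAULT_GRID, DEFAULT_MIN_COVERAGE, METHODS, downsample
from .spectral import spectral_battery
from .synthetic import SynthConfig, generate_cohort
from .traces import CleanTrace

logger = logging.getLogger(__name__)

#: Reference time bin (seconds) per index for the headline comparison table:
#: the bins at which each index is conventionally most discriminative
#: (mean/ARV/SV at 5 min, SD/TC at 2 min, CV at 1 min; averaging method).
DEFAULT_HEADLINE_BINS: Dict[str, float] = {
    "mean": 300.0, "sd": 120.0, "cv": 60.0, "tc": 120.0, "arv": 300.0, "sv": 300.0,
}


@dataclass
class RunConfig:
    """Everything a deterministic pipeline run needs."""

    out_dir: str = "bpvar_run"
    input_dir: Optional[str] = None  # None -> simulate a synthetic cohort
    synth: SynthConfig = field(default_factory=SynthConfig)
    channel: str = "SBP"
    window_s: float = DEFAULT_WINDOW_S  # moving-average window, s
    threshold_mmhg: float = DEFAULT_THRESHOLD_MMHG  # artifact deviation threshold
    diff_sd_multiple: float = DEFAULT_DIFF_SD_MULTIPLE  # 3-SD difference mask
    intervals: Sequence[float] = DEFAULT_GRID
    methods: Sequence[str] = METHODS
    min_coverage: float = DEFAULT_MIN_COVERAGE
    headline_bins: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEADLINE_BINS)
    )
    headline_method: str = "averaging"
    ci_method: str = "hanley-mcneil"
    n_boot: int = 2000
    seed: int = 0
    run_frequency_sweep: bool = True
    run_duration_sweep: bool = False
    duration_hours: Optional[Sequence[int]] = None
    write_traces: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        if isinstance(synth_raw, dict):
            band_sd = synth_raw.get("band_sd")
            if band_sd is not None:
                synth_raw["band_sd"] = {k: tuple(v) for k, v in band_sd.items()}
            try:
                synth = SynthConfig(**synth_raw)
            except TypeError as exc:
                raise ConfigError(f"synth: {exc}") from exc
        else:
            raise ConfigError("synth must be a mapping of SynthConfig fields")
        try:
            return cls(synth=synth, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        raw = _to_plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, range):
        return list(obj)
    return obj


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate-or-load -> preprocess -> indices -> spectra -> comparisons.

    Returns the result bundle (DataFrames and per-patient objects) and writes
    tidy CSVs plus a JSON run log under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        synth = config.synth.replace(seed=config.seed, channel=config.channel)
        raw_cohort = generate_cohort(synth)
        logger.info("simulated %d traces (channel %s)", len(raw_cohort), config.channel)
        if config.write_traces:
            write_cohort(raw_cohort, out / "traces")
    else:
        raw_cohort = read_cohort(config.input_dir, channel=config.channel)
        logger.info("loaded %d traces from %s", len(raw_cohort), config.input_dir)

    clean_cohort: List[Tuple[CleanTrace, str]] = []
    patient_log = []
    for trace, outcome in raw_cohort:
        ct = preprocess(
            trace,
            window_s=config.window_s,
            threshold_mmhg=config.threshold_mmhg,
            sd_multiple=config.diff_sd_multiple,
        )
        clean_cohort.append((ct, outcome))
        patient_log.append(
            {
                "patient_id": ct.patient_id,
                "duration_h": ct.duration_s / 3600.0,
                "n_samples": ct.n,
                "n_gap_samples": int((~ct.valid).sum()),
                "n_removed": int(ct.removed.sum()),
                "n_diffs_masked": int(ct.diff_excluded.sum()),
            }
        )

    index_rows = []
    spectra_rows = []
    for ct, _ in clean_cohort:
        battery = index_battery(
            ct, intervals=config.intervals, methods=config.methods,
            min_coverage=config.min_coverage,
        )
        battery.insert(0, "patient_id", ct.patient_id)
        battery.insert(1, "channel", ct.channel)
        index_rows.append(battery)
        bp = spectral_battery(ct)
        for band, power in bp.powers.items():
            spectra_rows.append(
                {
                    "patient_id": ct.patient_id,
                    "channel": ct.channel,
                    "band": band,
                    "power_mmhg2": power,
                    "n_samples": bp.n_samples,
                    "t_s": bp.t_s,
                }
            )
    indices_df = pd.concat(index_rows, ignore_index=True)
    indices_long = indices_df.melt(
        id_vars=["patient_id", "channel", "interval_s", "method", "n", "n_diffs_used"],
        value_vars=list(INDEX_NAMES),
        var_name="index",
        value_name="value",
    )
    spectra_df = pd.DataFrame(spectra_rows)

    outcomes = {ct.patient_id: outcome for ct, outcome in clean_cohort}

    def split(series_by_patient: Dict[str, float]):
        fav = [v for p, v in series_by_patient.items() if outcomes[p] == "favorable"]
        unf = [v for p, v in series_by_patient.items() if outcomes[p] == "unfavorable"]
        return fav, unf

    comparisons = []
    for index, interval in config.headline_bins.items():
        # computed directly so headline bins need not sit on the sweep grid
        values = {
            ct.patient_id: getattr(
                compute_indices(
                    ct if np.isclose(interval, ct.dt)
                    else downsample(ct, interval, config.headline_method,
                                    config.min_coverage)
                ),
                index,
            )
            for ct, _ in clean_cohort
        }
        fav, unf = split(values)
        cmp_ = compare_groups(
            fav, unf, name=f"{index} (T={interval:g} s, {config.headline_method})",
            ci_method=config.ci_method, n_boot=config.n_boot, seed=config.seed,
        )
        comparisons.append(cmp_.as_dict())
    for band in spectra_df.band.unique():
        sel = spectra_df.loc[spectra_df.band == band]
        values = dict(zip(sel.patient_id, sel.power_mmhg2))
        fav, unf = split(values)
        cmp_ = compare_groups(
            fav, unf, name=f"power {band} (T=1 s)",
            ci_method=config.ci_method, n_boot=config.n_boot, seed=config.seed,
        )
        comparisons.append(cmp_.as_dict())
    n_by_patient = {ct.patient_id: float(ct.clean_valid.sum()) for ct, _ in clean_cohort}
    fav, unf = split(n_by_patient)
    comparisons.append(compare_groups(fav, unf, name="n_samples").as_dict())
    comparisons_df = pd.DataFrame(comparisons)

    freq_df = None
    if config.run_frequency_sweep:
        freq_df = frequency_sweep(
            clean_cohort, intervals=config.intervals, methods=config.methods,
            min_coverage=config.min_coverage, ci_method=config.ci_method,
            n_boot=config.n_boot, seed=config.seed,
        )
    dur_df = None
    if config.run_duration_sweep:
        dur_df = duration_sweep(
            clean_cohort, hours=config.duration_hours,
            min_coverage=config.min_coverage, ci_method=config.ci_method,
            n_boot=config.n_boot, seed=config.seed,
        )

    _write_csv(indices_long, out / "indices.csv")
    _write_csv(spectra_df, out / "spectrum.csv")
    _write_csv(comparisons_df, out / "comparisons.csv")
    if freq_df is not None:
        _write_csv(freq_df, out / "frequency_sweep.csv")
    if dur_df is not None:
        _write_csv(dur_df, out / "duration_sweep.csv")

    run_log = {
        "config": json.loads(json.dumps(_to_plain(dataclasses.asdict(config)), default=str)),
        "patients": patient_log,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return {
        "cohort": raw_cohort,
        "clean": clean_cohort,
        "indices": indices_long,
        "indices_wide": indices_df,
        "spectra": spectra_df,
        "comparisons": comparisons_df,
        "frequency_sweep": freq_df,
        "duration_sweep": dur_df,
        "log": run_log,
    }
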