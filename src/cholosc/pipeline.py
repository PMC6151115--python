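"""End-to-end pipeline: preprocess -> spectra -> band detection ->
occurrence statistics, with a single JSON-serializable configuration.

Per trial the chain is: decimate to 1 kHz (if raw), 1 Hz high-pass,
multitaper spectrogram, post-stimulus average, 1/f correction, line-harmonic
excision, per-channel normalization.  Trials of one culture are averaged on
the normalized spectra (the carbachol-naive first trial excluded); detection
runs per hippocampal area on the averaged spectrum.  Across cultures the
occurrence table is collapsed over areas and modelled per band by logistic
regression with AIC selection; peak frequency and relative peak power are
compared over genotype x DIV with two-way ANOVA.
"""
from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import AREAS, ChannelSpectrum, Recording
from .detect import PROMINENCE_THRESHOLD, relative_peak_power, scan_bands
from .io import DETECTION_COLUMNS, read_recording, write_table
from .occurrence import (DEFAULT_ALPHA, collapse_areas, compare_groups,
                         select_model)
from .preprocess import PreprocessConfig, downsample, highpass
from .spectral import (SpectralConfig, average_trials, correct_one_over_f,
                       excise_line_noise, multitaper_spectrogram,
                       normalize_spectrum, post_stim_spectrum)
from .synth import BandSpec, GeneratorConfig, OccurrenceModel


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    threshold: float = PROMINENCE_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    normalize_before_average: bool = True
    rng_seed: int = 0
    out_dir: str = "results"


# ---------------------------------------------------------------- config JSON

def _tupled(x):
    if isinstance(x, list):
        return tuple(_tupled(v) for v in x)
    return x


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    gen = d["generator"]
    gen["bands"] = {k: dataclasses.asdict(v) for k, v in cfg.generator.bands.items()}
    gen["occurrence"] = {k: dataclasses.asdict(v)
                         for k, v in cfg.generator.occurrence.items()}
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    gen = dict(d["generator"])
    gen["bands"] = {k: BandSpec(**{**v, "areas": _tupled(v["areas"])})
                    for k, v in gen["bands"].items()}
    gen["occurrence"] = {
        k: OccurrenceModel(intercept=v["intercept"],
                           div_coefs={int(dk): dv for dk, dv in v["div_coefs"].items()},
                           genotype_coef=v["genotype_coef"])
        for k, v in gen["occurrence"].items()}
    gen["hum_harmonic_amplitudes"] = _tupled(gen["hum_harmonic_amplitudes"])
    if gen.get("area_map") is not None:
        gen["area_map"] = _tupled(gen["area_map"])
    spec = dict(d["spectral"])
    spec["ref_band"] = _tupled(spec["ref_band"])
    return PipelineConfig(
        generator=GeneratorConfig(**gen),
        preprocess=PreprocessConfig(**d["preprocess"]),
        spectral=SpectralConfig(**spec),
        threshold=d["threshold"], alpha=d["alpha"],
        normalize_before_average=d["normalize_before_average"],
        rng_seed=d["rng_seed"], out_dir=d["out_dir"],
    )


def save_config(cfg: PipelineConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config_to_dict(cfg), indent=1, sort_keys=True))
    return path


def load_config(path: Union[str, Path]) -> PipelineConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ analysis

def analyze_trial(rec: Recording, pre_cfg: PreprocessConfig,
                  spec_cfg: SpectralConfig) -> Dict[str, ChannelSpectrum]:
    """One trial through preprocessing and the spectral chain.

    Returns the post-stimulus spectrum at the ``notch_interpolated`` and
    ``normalized`` stages (both are needed downstream: detection runs on the
    normalized spectrum, relative peak power on the line-excised one).
    """
    if rec.fs > pre_cfg.target_fs:
        rec = downsample(rec, pre_cfg.target_fs)
    rec = highpass(rec, pre_cfg)
    sg = multitaper_spectrogram(rec, spec_cfg)
    raw = post_stim_spectrum(sg, rec.meta.onset_s)
    notch = excise_line_noise(correct_one_over_f(raw), spec_cfg)
    return {"notch_interpolated": notch, "normalized": normalize_spectrum(notch)}


def analyze_culture(trials: Sequence[Recording],
                    pre_cfg: PreprocessConfig = PreprocessConfig(),
                    spec_cfg: SpectralConfig = SpectralConfig(),
                    threshold: float = PROMINENCE_THRESHOLD,
                    normalize_before_average: bool = True) -> pd.DataFrame:
    """Detect oscillation bands per hippocampal area for one culture.

    Trials are averaged after per-trial normalization by default (making
    trials of different overall power commensurate); the alternative —
    average the line-excised spectra, then normalize once — is selectable.
    A single-trial input is analyzed directly without averaging.
    Returns one row per area x band: culture_id, genotype, div, area, band,
    present, n_active_channels, mode_freq_hz, peak_power_rel.
    """
    if not trials:
        raise ValueError("no trials given")
    meta = trials[0].meta
    # the naive first trial never enters the average; skip analyzing it
    retained = [t for t in trials if not t.meta.is_naive]
    if not retained:
        raise ValueError("all trials are flagged naive; nothing to analyze")
    analyzed = [analyze_trial(t, pre_cfg, spec_cfg) for t in retained]
    metas = [t.meta for t in retained]
    if len(retained) == 1:
        avg_notch = analyzed[0]["notch_interpolated"]
        avg_norm = analyzed[0]["normalized"]
    else:
        avg_notch = average_trials([a["notch_interpolated"] for a in analyzed], metas)
        if normalize_before_average:
            avg_norm = average_trials([a["normalized"] for a in analyzed], metas)
        else:
            avg_norm = normalize_spectrum(avg_notch)

    areas = trials[0].channel_area
    rows = []
    for area in AREAS:
        idx = np.flatnonzero(areas == area)
        if idx.size == 0:
            continue
        norm_a = avg_norm.subset(idx)
        notch_a = avg_notch.subset(idx)
        for det in scan_bands(norm_a, threshold):
            rel = relative_peak_power(notch_a, det, spec_cfg.ref_band) if det.present else np.nan
            rows.append({
                "culture_id": meta.culture_id, "genotype": meta.genotype,
                "div": meta.div, "area": area,
                "band": det.band if det.present else _range_band(det.search_range),
                "present": int(det.present),
                "n_active_channels": len(det.active_channels),
                "mode_freq_hz": det.mode_freq if det.present else np.nan,
                "peak_power_rel": rel,
            })
    return pd.DataFrame(rows)


def _range_band(search_range) -> str:
    from .core import BAND_RANGES
    for name, rng in BAND_RANGES.items():
        if tuple(rng) == tuple(search_range):
            return name
    return f"{search_range[0]:g}-{search_range[1]:g}Hz"


def occurrence_statistics(detections: pd.DataFrame, alpha: float = DEFAULT_ALPHA
                          ) -> Dict[str, object]:
    """Cross-culture statistics from a per-area detection table.

    Collapses areas (OR), runs AIC model selection per band, and compares
    peak frequency and relative peak power over genotype x DIV per band.
    Per-culture peak values are the means over that culture's present areas.
    """
    collapsed = collapse_areas(detections)
    selections = {}
    rankings = []
    for band, grp in collapsed.groupby("band", sort=False):
        try:
            sel = select_model(grp)
        except ValueError as err:
            warnings.warn(f"model selection skipped for {band}: {err}")
            continue
        selections[band] = sel
        r = sel.ranking.copy()
        r.insert(0, "band", band)
        rankings.append(r)
    ranking = pd.concat(rankings, ignore_index=True) if rankings else pd.DataFrame()

    present = detections[detections["present"] == 1]
    per_culture = (present.groupby(["band", "culture_id", "genotype", "div"],
                                   as_index=False, observed=True)
                   [["mode_freq_hz", "peak_power_rel"]].mean())
    anovas = []
    for value_col, family in (("mode_freq_hz", "peak_frequency"),
                              ("peak_power_rel", "peak_power")):
        for band, grp in per_culture.groupby("band", sort=False):
            if grp["genotype"].nunique() < 2 or grp["div"].nunique() < 2 or len(grp) < 4:
                continue
            try:
                a = compare_groups(grp.rename(columns={value_col: "value"}),
                                   alpha=alpha)
            except ValueError:
                continue
            a.insert(0, "band", band)
            a.insert(0, "family", family)
            anovas.append(a)
    anova = pd.concat(anovas, ignore_index=True) if anovas else pd.DataFrame()
    return {"collapsed": collapsed, "selections": selections,
            "model_ranking": ranking, "anova": anova}


def run_pipeline(config: PipelineConfig,
                 recordings: Union[Sequence[Union[str, Path]],
                                   Mapping[str, Sequence[Recording]]],
                 out_dir: Optional[Union[str, Path]] = None) -> Dict[str, object]:
    """Run the full analysis over a set of recordings and write all outputs.

    ``recordings`` is either a list of HDF5 paths (grouped into cultures by
    the culture_id in their metadata) or a mapping culture_id -> trials.
    Writes detections.csv, occurrence_collapsed.csv, model_ranking.csv,
    anova.csv, the resolved config and a run log; per-culture failures are
    logged and skipped, and the log carries the error count.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(recordings, Mapping):
        cultures = {k: list(v) for k, v in recordings.items()}
    else:
        cultures = {}
        for p in recordings:
            rec = read_recording(p)
            cultures.setdefault(rec.meta.culture_id, []).append(rec)

    frames, errors = [], []
    for cid in sorted(cultures):
        trials = sorted(cultures[cid], key=lambda r: r.meta.trial_index)
        try:
            frames.append(analyze_culture(
                trials, config.preprocess, config.spectral, config.threshold,
                config.normalize_before_average))
        except Exception as err:
            errors.append({"culture_id": cid, "error": str(err)})
    detections = (pd.concat(frames, ignore_index=True)
                  if frames else pd.DataFrame(columns=DETECTION_COLUMNS))
    stats = occurrence_statistics(detections, config.alpha) if frames else {
        "collapsed": pd.DataFrame(), "selections": {},
        "model_ranking": pd.DataFrame(), "anova": pd.DataFrame()}

    write_table(detections, out / "detections.csv", DETECTION_COLUMNS)
    write_table(stats["collapsed"], out / "occurrence_collapsed.csv")
    write_table(stats["model_ranking"], out / "model_ranking.csv")
    write_table(stats["anova"], out / "anova.csv")
    save_config(config, out / "resolved_config.json")
    log = {"version": __version__, "python": platform.python_version(),
           "rng_seed": config.rng_seed, "n_cultures": len(cultures),
           "n_failed": len(errors), "failures": errors}
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return {"detections": detections, **stats, "log": log}
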