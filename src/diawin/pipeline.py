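"""End-to-end orchestration: DDA library → windows → DIA quantification
→ QC statistics → differential abundance, from one TOML config.

Every stage writes its artifact into the output directory; a run log
echoes all parameters and hashes the inputs, so a rerun with the same
config and data is reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .features import detect_ms1_features
from .io import read_manifest, read_mzml
from .library import (
    MatchParams,
    annotations_to_entries,
    build_consensus,
    dedupe_entries,
    filter_adducts,
    read_library,
    search_library,
    write_library,
)
from .extract import quantify_batch
from .stats import (
    StatParams,
    differential,
    filter_for_diff,
    qc_summary,
    representative_readout,
)
from .windows import WindowParams, design_windows, write_window_table

ARTIFACTS = [
    "inhouse.msp", "windows.tsv", "quant_all.tsv", "quant_fill_all.tsv",
    "channel_stats.tsv", "qc_summary.tsv", "diff_results.tsv",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    dda_runs: list[str]
    dia_manifest: str
    reference_libraries: list[str]
    output_dir: str
    polarity: str = "positive"
    qc_group: str = "QC"
    group_order: tuple[str, str] = ("WT", "KO")
    seed: int = 0
    match: MatchParams = field(default_factory=MatchParams)
    dia_match: MatchParams = field(default_factory=lambda: MatchParams(rt_shift=20.0))
    window: WindowParams = field(default_factory=WindowParams)
    stat: StatParams = field(default_factory=StatParams)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = raw.get("paths", {})
        # Methods-style parameter keys (ms1to1, ms2to1, MS2_score, min_peaks, RT_shift)
        mk = raw.get("params", {})
        match = MatchParams(
            ms1to1=mk.get("ms1to1", 0.005),
            ms2to1=mk.get("ms2to1", 0.01),
            ms2_score_min=mk.get("MS2_score", 0.5),
            min_peaks=mk.get("min_peaks", 1),
            rt_shift=mk.get("RT_shift", 10),
            rt_shift_units=mk.get("rt_shift_units", "sec"),
        )
        dia_match = MatchParams(
            ms1to1=match.ms1to1, ms2to1=match.ms2to1,
            ms2_score_min=match.ms2_score_min, min_peaks=match.min_peaks,
            rt_shift=mk.get("RT_shift_dia", 20),
            rt_shift_units=match.rt_shift_units,
        )
        wk = raw.get("windows", {})
        window = WindowParams(
            mass_low=wk.get("mass_low", 300.0), mass_high=wk.get("mass_high", 1000.0),
            n_windows=wk.get("n_windows", 20),
            min_width=wk.get("min_width", 10.0), max_width=wk.get("max_width", 100.0),
            extension=wk.get("extension", 0.5), density_radius=wk.get("density_radius", 2.5),
        )
        sk = raw.get("stats", {})
        stat = StatParams(
            rsd_pass=sk.get("rsd_pass", 30.0), rsd_tight=sk.get("rsd_tight", 20.0),
            r2_ms1_min=sk.get("r2_ms1_min", 0.8),
            linearity_max_volume=sk.get("linearity_max_volume", 4.0),
            fc_threshold=sk.get("fc_threshold", 2.0),
            fdr_threshold=sk.get("fdr_threshold", 0.05),
        )
        return cls(
            dda_runs=list(paths.get("dda_runs", [])),
            dia_manifest=paths["dia_manifest"],
            reference_libraries=list(paths.get("reference_libraries", [])),
            output_dir=paths.get("output_dir", "diawin_out"),
            polarity=raw.get("polarity", "positive"),
            qc_group=raw.get("qc_group", "QC"),
            group_order=tuple(raw.get("group_order", ("WT", "KO"))),
            seed=int(raw.get("seed", 0)),
            match=match, dia_match=dia_match, window=window, stat=stat,
        )

    def validate(self) -> None:
        missing = [
            p for p in [*self.dda_runs, self.dia_manifest, *self.reference_libraries]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineError("validate", f"missing input path(s): {missing}")
        self.match.validate()
        self.dia_match.validate()
        self.window.validate()
        self.stat.validate()


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- spectral library from DDA ---
    stage = "library"
    try:
        dda = [read_mzml(p) for p in sorted(config.dda_runs)]
        references = []
        for p in sorted(config.reference_libraries):
            references.extend(read_library(p))
        consensus = build_consensus(dda, config.match.ms1to1, ms2to1=config.match.ms2to1)
        annotations = search_library(consensus, references, config.match)
        annotations = filter_adducts(annotations, config.polarity)
        entries = dedupe_entries(annotations_to_entries(consensus, annotations))
        entries.sort(key=lambda e: (e.sum_composition, e.adduct))
        if not entries:
            raise ValueError("no library entries passed annotation")
        write_library(entries, out / "inhouse.msp", format="msp")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- variable windows from the DDA MS1 map ---
    stage = "windows"
    try:
        features = []
        for run in dda:
            features.extend(detect_ms1_features(run, tol=config.match.ms1to1))
        windows = design_windows(features, config.window)
        write_window_table(windows, out / "windows.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- targeted DIA extraction ---
    stage = "quantify"
    try:
        manifest = read_manifest(config.dia_manifest)
        manifest.sort(key=lambda m: m.sample_id)
        dia_runs = [read_mzml(m.path) for m in manifest]
        for run, m in zip(dia_runs, manifest):
            run.sample_id = m.sample_id
        matrix = quantify_batch(dia_runs, entries, windows, config.dia_match,
                                fill=True, outdir=out)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- QC statistics ---
    stage = "qc"
    try:
        qc_samples = [m.sample_id for m in manifest if m.group == config.qc_group]
        study_samples = [m.sample_id for m in manifest if m.group != config.qc_group]
        cs, summary = qc_summary(matrix, qc_samples, config.stat)
        cs.to_csv(out / "channel_stats.tsv", sep="\t", index=False, float_format="%.6g")
        summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- differential abundance ---
    stage = "differential"
    try:
        retained = filter_for_diff(matrix, qc_samples, study_samples, config.stat)
        reps = representative_readout(matrix, retained, qc_samples)
        groups = {
            g: [m.sample_id for m in manifest if m.group == g]
            for g in config.group_order
        }
        diff = differential(matrix, reps, groups, config.stat, config.group_order)
        diff = diff.sort_values("sum_composition").reset_index(drop=True)
        diff.to_csv(out / "diff_results.tsv", sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    log = {
        "version": __version__,
        "polarity": config.polarity,
        "seed": config.seed,
        "params": {
            "match": asdict(config.match),
            "dia_match": asdict(config.dia_match),
            "window": asdict(config.window),
            "stat": asdict(config.stat),
        },
        "inputs": {
            "dda_runs": {p: _sha256(p) for p in sorted(config.dda_runs)},
            "dia_manifest": {config.dia_manifest: _sha256(config.dia_manifest)},
            "reference_libraries": {p: _sha256(p) for p in sorted(config.reference_libraries)},
        },
        "n_library_entries": len(entries),
        "n_windows": len(windows),
        "n_retained": int(len(retained)),
        "n_significant": int(diff["significant"].sum()) if len(diff) else 0,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return out
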