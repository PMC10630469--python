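"""Targeted DIA quantification against a spectral library.

For each library entry the precursor XIC (MS1) and one XIC per library
fragment (MS2, from the single isolation window whose *core* contains
the precursor) are extracted, chromatographic peaks are picked, and the
peak nearest the library retention time is integrated. Fragments must
co-elute with the chosen MS1 apex: DIA severs the precursor–product
link, and the library RT plus a co-elution gate restores it. Channels
with no qualifying peak stay null; a separate fill pass force-integrates
the RT neighbourhood so that downstream statistics see a complete
matrix (the ``quant_all`` vs ``quant_fill_all`` distinction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import ChromPeak, XICTrace, detect_chrom_peaks, extract_xic
from .io import Run
from .library import LibraryEntry, MatchParams
from .windows import IsolationWindow, assign_window

QUANT_COLUMNS = [
    "entry_id", "sum_composition", "adduct", "polarity",
    "channel", "sample", "area", "filled",
]


def channel_label(mz: float) -> str:
    return f"{mz:.4f}"


@dataclass
class QuantRecord:
    entry_id: str
    sample_id: str
    ms1_area: Optional[float] = None
    ms1_filled: bool = False
    fragment_areas: dict[str, tuple[Optional[float], bool]] = field(default_factory=dict)
    rt_observed: float = float("nan")
    n_points_ms1: int = 0
    n_points_ms2: int = 0


class QuantMatrix:
    """Entries × samples × channels of peak areas, long format.

    ``df`` columns: entry_id, sum_composition, adduct, polarity, channel
    (``"MS1"`` or a fragment m/z label), sample, area (NaN when null),
    filled (True when the area came from forced integration).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)[QUANT_COLUMNS]
        self._cache: Optional[dict] = None

    def _index(self) -> dict:
        # (entry_id, channel) -> {sample: (area, filled)}, built once
        if self._cache is None:
            cache: dict = {"cells": {}, "channels": {}}
            cols = self.df[["entry_id", "channel", "sample", "area", "filled"]]
            for entry_id, channel, sample, area, filled in cols.itertuples(index=False):
                cache["cells"].setdefault((entry_id, channel), {})[sample] = (area, bool(filled))
                cache["channels"].setdefault(entry_id, set()).add(channel)
            self._cache = cache
        return self._cache

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    @property
    def entry_ids(self) -> list[str]:
        return sorted(self.df["entry_id"].unique())

    def channels_for(self, entry_id: str) -> list[str]:
        channels = self._index()["channels"].get(entry_id, set())
        return sorted(channels, key=lambda c: (c != "MS1", c))

    def values(
        self, entry_id: str, channel: str, samples: Sequence[str],
        include_filled: bool = True,
    ) -> np.ndarray:
        cells = self._index()["cells"].get((entry_id, channel), {})
        out = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            got = cells.get(s)
            if got is None:
                continue
            area, filled = got
            if filled and not include_filled:
                continue
            out[i] = area
        return out

    def subset_samples(self, samples: Sequence[str]) -> "QuantMatrix":
        return QuantMatrix(self.df[self.df["sample"].isin(list(samples))])

    @classmethod
    def from_records(
        cls, records: Sequence[QuantRecord], entries: Sequence[LibraryEntry]
    ) -> "QuantMatrix":
        meta = {e.entry_id: e for e in entries}
        rows = []
        for r in records:
            e = meta[r.entry_id]
            rows.append(
                {
                    "entry_id": r.entry_id, "sum_composition": e.sum_composition,
                    "adduct": e.adduct, "polarity": e.polarity,
                    "channel": "MS1", "sample": r.sample_id,
                    "area": np.nan if r.ms1_area is None else r.ms1_area,
                    "filled": r.ms1_filled,
                }
            )
            for label, (area, filled) in r.fragment_areas.items():
                rows.append(
                    {
                        "entry_id": r.entry_id, "sum_composition": e.sum_composition,
                        "adduct": e.adduct, "polarity": e.polarity,
                        "channel": label, "sample": r.sample_id,
                        "area": np.nan if area is None else area,
                        "filled": filled,
                    }
                )
        return cls(pd.DataFrame(rows, columns=QUANT_COLUMNS))


def _match_run_window(run: Run, window: IsolationWindow, tol: float = 1e-6) -> int:
    for i, (lo, hi) in enumerate(run.windows):
        if abs(lo - window.ext_low) <= tol and abs(hi - window.ext_high) <= tol:
            return i
    raise ValueError(
        f"run {run.sample_id!r} has no isolation window matching "
        f"[{window.ext_low}, {window.ext_high}]"
    )


def _pick_peak(
    peaks: Sequence[ChromPeak], rt_target: float, rt_tol: float
) -> Optional[ChromPeak]:
    eligible = [p for p in peaks if abs(p.rt_apex - rt_target) <= rt_tol]
    if not eligible:
        return None
    return min(eligible, key=lambda p: abs(p.rt_apex - rt_target))


def quantify_entry(
    run: Run,
    entry: LibraryEntry,
    windows: Sequence[IsolationWindow],
    params: MatchParams = MatchParams(rt_shift=20.0),
) -> QuantRecord:
    """Quantify one library entry in one DIA run (detected peaks only)."""
    if run.mode != "DIA":
        raise ValueError(f"run {run.sample_id!r} is not DIA")
    widx = assign_window(entry.precursor_mz, windows)  # raises when out of range
    run_widx = _match_run_window(run, windows[widx])
    rt_tol = params.rt_shift_min

    rec = QuantRecord(entry_id=entry.entry_id, sample_id=run.sample_id)
    ms1_trace = extract_xic(run, entry.precursor_mz, params.ms1to1, ms_level=1)
    ms1_peaks = detect_chrom_peaks(ms1_trace)
    anchor_rt = entry.rt if entry.rt is not None else float("nan")
    ms1_peak = _pick_peak(ms1_peaks, anchor_rt, rt_tol)
    if ms1_peak is not None:
        rec.ms1_area = ms1_peak.area
        rec.rt_observed = ms1_peak.rt_apex
        rec.n_points_ms1 = ms1_peak.n_points

    # fragments co-elute with the MS1 apex when one was found
    frag_anchor = ms1_peak.rt_apex if ms1_peak is not None else anchor_rt
    frag_tol = rt_tol / 2 if ms1_peak is not None else rt_tol
    for fmz, _ in entry.fragments:
        trace = extract_xic(run, fmz, params.ms2to1, ms_level=2, window_id=run_widx)
        peak = _pick_peak(detect_chrom_peaks(trace), frag_anchor, frag_tol)
        label = channel_label(fmz)
        if peak is None:
            rec.fragment_areas[label] = (None, False)
        else:
            rec.fragment_areas[label] = (peak.area, False)
            rec.n_points_ms2 = max(rec.n_points_ms2, peak.n_points)
    return rec


def _forced_area(trace: XICTrace, rt_centre: float, half_width: float) -> float:
    sel = (trace.rt >= rt_centre - half_width) & (trace.rt <= rt_centre + half_width)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(trace.intensity[sel], trace.rt[sel]))


def fill_missing(
    run: Run,
    entry: LibraryEntry,
    windows: Sequence[IsolationWindow],
    params: MatchParams,
    record: QuantRecord,
) -> QuantRecord:
    """Force-integrate the null channels of a quantified record over
    ``entry.rt ± rt_shift``; detected channels are left untouched."""
    widx = assign_window(entry.precursor_mz, windows)
    run_widx = _match_run_window(run, windows[widx])
    w = params.rt_shift_min
    centre = entry.rt if entry.rt is not None else record.rt_observed
    if record.ms1_area is None:
        trace = extract_xic(run, entry.precursor_mz, params.ms1to1, ms_level=1)
        record.ms1_area = _forced_area(trace, centre, w)
        record.ms1_filled = True
    for fmz, _ in entry.fragments:
        label = channel_label(fmz)
        area, filled = record.fragment_areas.get(label, (None, False))
        if area is None:
            trace = extract_xic(run, fmz, params.ms2to1, ms_level=2, window_id=run_widx)
            record.fragment_areas[label] = (_forced_area(trace, centre, w), True)
    return record


def quantify_batch(
    runs: Sequence[Run],
    library: Sequence[LibraryEntry],
    windows: Sequence[IsolationWindow],
    params: MatchParams = MatchParams(rt_shift=20.0),
    fill: bool = True,
    outdir: Optional[str | Path] = None,
) -> QuantMatrix:
    """Quantify a whole library across runs; optionally write the
    ``quant_all.tsv`` (detected peaks, nulls blank) and
    ``quant_fill_all.tsv`` (forced integration added) tables."""
    for run in runs:
        bad = [e for e in library if e.polarity != run.polarity]
        if bad:
            raise ValueError(
                f"run {run.sample_id!r} ({run.polarity}) paired with "
                f"{bad[0].polarity} library entry {bad[0].species_name!r}"
            )
    detected: list[QuantRecord] = []
    for run in sorted(runs, key=lambda r: r.sample_id):
        for entry in library:
            detected.append(quantify_entry(run, entry, windows, params))
    all_matrix = QuantMatrix.from_records(detected, library)

    runs_by_id = {r.sample_id: r for r in runs}
    entries_by_id = {e.entry_id: e for e in library}
    if fill:
        import copy

        filled_records = [copy.deepcopy(r) for r in detected]
        for r in filled_records:
            fill_missing(runs_by_id[r.sample_id], entries_by_id[r.entry_id],
                         windows, params, r)
        fill_matrix = QuantMatrix.from_records(filled_records, library)
    else:
        fill_matrix = all_matrix

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_matrix.df.to_csv(outdir / "quant_all.tsv", sep="\t", index=False,
                             float_format="%.10g")
        fill_matrix.df.to_csv(outdir / "quant_fill_all.tsv", sep="\t", index=False,
                              float_format="%.10g")
    return fill_matrix if fill else all_matrix
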