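"""Extracted-ion chromatograms, chromatographic peak picking and MS1
feature detection.

Peak integration is trapezoidal on the raw (baseline-unsubtracted) trace,
so areas scale exactly linearly with intensity. MS1 features are built by
greedy mass-trace construction: the most intense unclaimed centroid seeds
a trace, which is extended across scans within the m/z tolerance, and the
trace is then segmented into chromatographic peaks. No deisotoping is
applied — isotope peaks intentionally count toward precursor density,
because they load the quadrupole like any other ion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Run, Spectrum


@dataclass
class XICTrace:
    target_mz: float
    tol: float
    ms_level: int
    rt: np.ndarray          # minutes, strictly increasing
    intensity: np.ndarray   # one point per qualifying scan
    window_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    def __len__(self) -> int:
        return int(self.rt.size)


@dataclass
class ChromPeak:
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float        # intensity * minutes
    n_points: int
    apex_index: int = -1
    start_index: int = -1
    end_index: int = -1


@dataclass
class MS1Feature:
    mz: float          # intensity-weighted apex m/z
    rt_apex: float
    area: float
    height: float
    density: int = 0   # filled by the window calculator


FEATURE_COLUMNS = ["mz", "rt_apex", "height", "area", "density"]


def _scan_intensity(spec: Spectrum, target_mz: float, tol: float) -> float:
    lo = np.searchsorted(spec.mz, target_mz - tol, side="left")
    hi = np.searchsorted(spec.mz, target_mz + tol, side="right")
    if hi <= lo:
        return 0.0
    return float(spec.intensity[lo:hi].sum())


def extract_xic(
    run: Run,
    target_mz: float,
    tol: float,
    ms_level: int = 1,
    window_id: Optional[int] = None,
) -> XICTrace:
    """Extract an ion chromatogram at ``target_mz`` ± ``tol``.

    For MS2 extraction on a DIA run, ``window_id`` selects which declared
    isolation window's scans contribute; scans of other windows are
    ignored entirely.
    """
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    if ms_level == 2 and run.mode == "DIA":
        if window_id is None:
            raise ValueError("MS2 extraction on a DIA run requires a window_id")
        if not (0 <= window_id < len(run.windows)):
            raise ValueError(f"window_id {window_id} not present in run (has {len(run.windows)})")
        bounds = run.windows[window_id]
        scans = [s for s in run.spectra if s.ms_level == 2 and s.precursor_window == bounds]
    else:
        scans = [s for s in run.spectra if s.ms_level == ms_level]
    rt = np.array([s.rt for s in scans], dtype=float)
    inten = np.array([_scan_intensity(s, target_mz, tol) for s in scans], dtype=float)
    return XICTrace(target_mz=target_mz, tol=tol, ms_level=ms_level,
                    rt=rt, intensity=inten, window_id=window_id)


def detect_chrom_peaks(
    trace: XICTrace | tuple[np.ndarray, np.ndarray],
    min_points: int = 3,
    noise_floor: float = 0.0,
) -> list[ChromPeak]:
    """Pick chromatographic peaks on a trace.

    A peak is a local maximum strictly above ``noise_floor``; its
    boundaries extend to the nearest valley or the first point at or
    below the floor on each side. Apex and valley decisions are made on
    a lightly smoothed copy of the trace (3-point binomial kernel) so
    that scan-to-scan detector noise does not truncate peak flanks; the
    area is the trapezoidal integral of the *raw* trace between the
    boundaries. Peaks are returned sorted by area, largest first.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if isinstance(trace, XICTrace):
        rt, y = trace.rt, trace.intensity
    else:
        rt, y = (np.asarray(a, dtype=float) for a in trace)
    n = y.size
    if n < min_points:
        return []
    ys = y.copy()
    if n >= 3:
        ys[1:-1] = 0.25 * y[:-2] + 0.5 * y[1:-1] + 0.25 * y[2:]

    # local maxima above the floor (plateaus: take the leftmost point)
    apexes = []
    for i in range(n):
        if ys[i] <= noise_floor:
            continue
        left = ys[i - 1] if i > 0 else -np.inf
        right = ys[i + 1] if i < n - 1 else -np.inf
        if ys[i] > left and ys[i] >= right:
            apexes.append(i)

    peaks: list[ChromPeak] = []
    for apex in apexes:
        i = apex
        while i > 0 and ys[i - 1] <= ys[i] and ys[i - 1] > noise_floor:
            i -= 1
        j = apex
        while j < n - 1 and ys[j + 1] <= ys[j] and ys[j + 1] > noise_floor:
            j += 1
        # include the first at/below-floor point as the integration boundary
        if i > 0 and y[i - 1] <= noise_floor:
            i -= 1
        if j < n - 1 and y[j + 1] <= noise_floor:
            j += 1
        npts = j - i + 1
        if npts < min_points:
            continue
        area = float(np.trapezoid(y[i : j + 1], rt[i : j + 1]))
        peaks.append(
            ChromPeak(
                rt_apex=float(rt[apex]),
                rt_start=float(rt[i]),
                rt_end=float(rt[j]),
                height=float(y[apex]),
                area=area,
                n_points=npts,
                apex_index=apex,
                start_index=i,
                end_index=j,
            )
        )
    peaks.sort(key=lambda p: -p.area)
    return peaks


def detect_ms1_features(
    run: Run,
    tol: float = 0.005,
    min_points: int = 3,
    noise_floor: float = 0.0,
) -> list[MS1Feature]:
    """Detect MS1 features via greedy mass traces + peak picking.

    Each trace claims at most one centroid per scan (the closest in m/z
    to the running intensity-weighted trace centre); every chromatographic
    peak on a trace becomes one feature. Features are returned sorted by
    m/z.
    """
    ms1 = run.ms1_spectra()
    if not ms1:
        return []
    scan_rt = np.array([s.rt for s in ms1])
    # flatten all centroids
    scan_idx = np.concatenate([np.full(s.n_peaks, k) for k, s in enumerate(ms1)]) \
        if any(s.n_peaks for s in ms1) else np.array([], dtype=int)
    all_mz = np.concatenate([s.mz for s in ms1]) if scan_idx.size else np.array([])
    all_int = np.concatenate([s.intensity for s in ms1]) if scan_idx.size else np.array([])
    claimed = np.zeros(all_mz.size, dtype=bool)
    order = np.argsort(-all_int, kind="stable")
    # per-scan slices into the flat arrays for fast lookup
    per_scan: list[np.ndarray] = []
    pos = 0
    for s in ms1:
        per_scan.append(np.arange(pos, pos + s.n_peaks))
        pos += s.n_peaks

    features: list[MS1Feature] = []
    for seed in order:
        if claimed[seed] or all_int[seed] <= noise_floor:
            continue
        centre = all_mz[seed]
        members: list[int] = []
        trace_y = np.zeros(len(ms1))
        w_sum = 0.0
        wm_sum = 0.0
        for k in range(len(ms1)):
            idxs = per_scan[k]
            if idxs.size == 0:
                continue
            cand = idxs[~claimed[idxs]]
            if cand.size == 0:
                continue
            d = np.abs(all_mz[cand] - centre)
            best = cand[np.argmin(d)]
            if abs(all_mz[best] - centre) <= tol:
                members.append(best)
                trace_y[k] = all_int[best]
                w_sum += all_int[best]
                wm_sum += all_int[best] * all_mz[best]
                centre = wm_sum / w_sum  # running weighted centre
        if not members:
            continue
        claimed[np.array(members)] = True
        for pk in detect_chrom_peaks((scan_rt, trace_y), min_points, noise_floor):
            sel = [m for m in members
                   if pk.start_index <= scan_idx[m] <= pk.end_index]
            if not sel:
                continue
            sel = np.array(sel)
            w = all_int[sel]
            mz_apex = float(np.average(all_mz[sel], weights=w)) if w.sum() > 0 else centre
            features.append(
                MS1Feature(mz=mz_apex, rt_apex=pk.rt_apex, area=pk.area, height=pk.height)
            )
    features.sort(key=lambda f: f.mz)
    return features


def write_feature_table(features: Sequence[MS1Feature], path) -> None:
    pd.DataFrame(
        [{c: getattr(f, c) for c in FEATURE_COLUMNS} for f in features],
        columns=FEATURE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[MS1Feature]:
    df = pd.read_csv(path, sep="\t")
    return [
        MS1Feature(mz=r.mz, rt_apex=r.rt_apex, area=r.area, height=r.height,
                   density=int(r.density) if not pd.isna(r.density) else 0)
        for r in df.itertuples()
    ]
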