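"""Variable isolation-window design by precursor density.

The mass range is partitioned into a fixed number of contiguous windows
whose summed MS1-feature density is approximately equal, subject to
instrument width limits, and each window is then extended on both edges
so that adjacent windows overlap.

Density of a feature is the number of features (itself included) within
``density_radius`` in m/z. Boundaries are chosen by a greedy cumulative
sweep: walking features in ascending m/z, a cut is placed — at the
midpoint between consecutive feature m/z values — once the running
density reaches the average density still owed per remaining window; the
cut is then clamped so the current window and the remaining tail both
respect the width limits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import MS1Feature


@dataclass(frozen=True)
class WindowParams:
    mass_low: float = 300.0
    mass_high: float = 1000.0
    n_windows: int = 20
    min_width: float = 10.0
    max_width: float = 100.0
    extension: float = 0.5
    density_radius: float = 2.5

    def validate(self) -> None:
        if not self.mass_low < self.mass_high:
            raise ValueError("mass_low must be < mass_high")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if not (0 < self.min_width <= self.max_width):
            raise ValueError("need 0 < min_width <= max_width")
        span = self.mass_high - self.mass_low
        if not (self.n_windows * self.min_width <= span <= self.n_windows * self.max_width):
            raise ValueError(
                f"mass range {span} Th infeasible for {self.n_windows} windows "
                f"with widths in [{self.min_width}, {self.max_width}]"
            )
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if self.density_radius <= 0:
            raise ValueError("density_radius must be > 0")


@dataclass(frozen=True)
class IsolationWindow:
    index: int
    core_low: float
    core_high: float
    ext_low: float
    ext_high: float
    summed_density: float = 0.0

    @property
    def core_width(self) -> float:
        return self.core_high - self.core_low

    @property
    def ext_bounds(self) -> tuple[float, float]:
        return (self.ext_low, self.ext_high)


WINDOW_COLUMNS = ["index", "core_low", "core_high", "ext_low", "ext_high", "summed_density"]


def compute_density(features: Sequence[MS1Feature], radius: float = 2.5) -> list[MS1Feature]:
    """Fill each feature's density: the count of features (itself
    included) within ``radius`` Th in m/z. Input order is preserved."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    mz = np.array([f.mz for f in features], dtype=float)
    order = np.sort(mz)
    for f in features:
        lo = np.searchsorted(order, f.mz - radius, side="left")
        hi = np.searchsorted(order, f.mz + radius, side="right")
        f.density = int(hi - lo)
    return list(features)


def _cut_grid(mz_sorted: np.ndarray) -> np.ndarray:
    """Candidate boundary positions: midpoints between consecutive
    distinct feature m/z values."""
    distinct = np.unique(mz_sorted)
    return 0.5 * (distinct[:-1] + distinct[1:])


def partition_windows(
    features: Sequence[MS1Feature], params: WindowParams
) -> list[IsolationWindow]:
    """Partition [mass_low, mass_high] into ``n_windows`` contiguous cores
    of approximately equal summed feature density.

    With no features the partition degenerates to equal widths. A feature
    sitting exactly on a boundary is counted in the lower window, the
    same tie rule :func:`assign_window` uses.
    """
    params.validate()
    n = params.n_windows
    lo, hi = params.mass_low, params.mass_high

    inside = [f for f in features if lo <= f.mz <= hi]
    inside.sort(key=lambda f: f.mz)
    mz = np.array([f.mz for f in inside])
    dens = np.array([float(f.density) for f in inside])

    bounds = [lo]
    if inside:
        i = 0  # first feature not yet assigned to a closed window
        for w in range(n - 1):
            remaining = n - w
            prev = bounds[-1]
            # feasibility interval for this cut
            cut_lo = max(prev + params.min_width, hi - (remaining - 1) * params.max_width)
            cut_hi = min(prev + params.max_width, hi - (remaining - 1) * params.min_width)
            rem_density = dens[i:].sum()
            if rem_density <= 0:
                cut = prev + (hi - prev) / remaining
            else:
                target = rem_density / remaining
                run = 0.0
                j = i
                while j < len(mz) and run < target:
                    run += dens[j]
                    j += 1
                if j >= len(mz):
                    # all remaining features consumed before the target:
                    # cut between the last feature and the range end
                    cut = 0.5 * (mz[-1] + hi)
                else:
                    # feature j-1 crossed the target; cut after it, or
                    # before it if that leaves the sum closer to target
                    # (never leaving the window empty)
                    cut = 0.5 * (mz[j - 1] + mz[j])
                    if j - 1 > i and abs((run - dens[j - 1]) - target) < abs(run - target):
                        cut = 0.5 * (mz[j - 2] + mz[j - 1])
            cut = min(max(cut, cut_lo), cut_hi)
            bounds.append(cut)
            while i < len(mz) and mz[i] <= cut:
                i += 1
    else:
        width = (hi - lo) / n
        bounds.extend(lo + width * k for k in range(1, n))
    bounds.append(hi)

    windows = []
    for k in range(n):
        c_lo, c_hi = bounds[k], bounds[k + 1]
        if k == 0:
            sel = (mz >= c_lo) & (mz <= c_hi)
        else:
            sel = (mz > c_lo) & (mz <= c_hi)
        windows.append(
            IsolationWindow(
                index=k, core_low=c_lo, core_high=c_hi,
                ext_low=c_lo, ext_high=c_hi,
                summed_density=float(dens[sel].sum()) if mz.size else 0.0,
            )
        )
    return extend_windows(windows, params.extension)


def extend_windows(
    windows: Sequence[IsolationWindow], extension: float
) -> list[IsolationWindow]:
    """Set extended bounds: core ± extension, giving every adjacent pair
    an overlap of exactly ``2 * extension``."""
    return [
        replace(w, ext_low=w.core_low - extension, ext_high=w.core_high + extension)
        for w in windows
    ]


def assign_window(precursor_mz: float, windows: Sequence[IsolationWindow]) -> int:
    """Index of the unique window whose *core* contains ``precursor_mz``;
    an m/z exactly on an interior boundary belongs to the lower window."""
    if not windows:
        raise ValueError("no windows")
    lo = windows[0].core_low
    hi = windows[-1].core_high
    if not (lo <= precursor_mz <= hi):
        raise ValueError(f"precursor m/z {precursor_mz} outside window scheme [{lo}, {hi}]")
    edges = np.array([w.core_high for w in windows])
    idx = int(np.searchsorted(edges, precursor_mz, side="left"))
    return min(idx, len(windows) - 1)


def design_windows(features: Sequence[MS1Feature], params: WindowParams) -> list[IsolationWindow]:
    """Convenience: compute densities then partition and extend."""
    compute_density(features, params.density_radius)
    return partition_windows(features, params)


def write_window_table(windows: Sequence[IsolationWindow], path) -> Path:
    pd.DataFrame(
        [
            {
                "index": w.index,
                "core_low": w.core_low,
                "core_high": w.core_high,
                "ext_low": w.ext_low,
                "ext_high": w.ext_high,
                "summed_density": w.summed_density,
            }
            for w in windows
        ],
        columns=WINDOW_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
    return Path(path)


def read_window_table(path) -> list[IsolationWindow]:
    df = pd.read_csv(path, sep="\t")
    return [
        IsolationWindow(
            index=int(r.index), core_low=r.core_low, core_high=r.core_high,
            ext_low=r.ext_low, ext_high=r.ext_high, summed_density=r.summed_density,
        )
        for r in df.itertuples(index=False)
    ]
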