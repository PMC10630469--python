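"""QC and differential-abundance statistics on quantification matrices.

The chain mirrors how a dilution-series / case-control lipidomics study
is evaluated: per-channel relative standard deviation (RSD) over QC
injections with the <20% / 20–30% / >30% / non-quantifiable categories,
squared Pearson correlation of each MS2 fragment against its MS1
precursor, dilution linearity restricted to the pre-saturation volumes,
a retention filter (MS1 and at least one fragment reproducible in QC,
fragment tracking MS1 with R² above threshold), a representative
readout per lipid (lowest QC RSD across channels and polarities), and a
Welch t-test on log2 areas with Benjamini–Hochberg FDR control and a
fold-change gate.

RSD always uses the sample (n−1) standard deviation and is computed on
unfilled QC values only, so forced-integration fill cannot flatter the
reproducibility metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .extract import QuantMatrix

RSD_CATEGORIES = ("<20", "20-30", ">30", "non_quantifiable")


@dataclass(frozen=True)
class StatParams:
    rsd_pass: float = 30.0        # percent
    rsd_tight: float = 20.0       # percent
    r2_ms1_min: float = 0.8
    linearity_max_volume: float = 4.0  # µL
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if not (0 < self.rsd_tight < self.rsd_pass):
            raise ValueError("need 0 < rsd_tight < rsd_pass")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must lie in (0, 1]")
        if not (0 < self.r2_ms1_min <= 1):
            raise ValueError("r2_ms1_min must lie in (0, 1]")


def rsd(values: Sequence[float]) -> Optional[float]:
    """Percent relative standard deviation (100·SD/mean, sample SD).

    Returns None — the non-quantifiable signal — with fewer than two
    non-null values or a zero mean."""
    v = np.asarray([x for x in values if x is not None and not np.isnan(x)], dtype=float)
    if v.size < 2:
        return None
    m = v.mean()
    if m == 0:
        return None
    return float(100.0 * v.std(ddof=1) / m)


def rsd_category(value: Optional[float], params: StatParams = StatParams()) -> str:
    if value is None:
        return "non_quantifiable"
    if value < params.rsd_tight:
        return "<20"
    if value < params.rsd_pass:
        return "20-30"
    return ">30"


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation over paired non-null points.

    NaN (treated as failing any threshold gate) with fewer than three
    pairs or zero variance on either side."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone in
    p-rank, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# QC summaries
# ---------------------------------------------------------------------------

def channel_stats(
    matrix: QuantMatrix,
    qc_samples: Sequence[str],
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Per-channel QC RSD and category (unfilled values only)."""
    rows = []
    for entry_id in matrix.entry_ids:
        sub = matrix.df[matrix.df.entry_id == entry_id]
        meta = sub.iloc[0]
        for channel in matrix.channels_for(entry_id):
            vals = matrix.values(entry_id, channel, qc_samples, include_filled=False)
            r = rsd(vals)
            rows.append(
                {
                    "entry_id": entry_id,
                    "sum_composition": meta.sum_composition,
                    "polarity": meta.polarity,
                    "channel": channel,
                    "is_ms1": channel == "MS1",
                    "rsd_qc": np.nan if r is None else r,
                    "rsd_category": rsd_category(r, params),
                    "n_qc_used": int(np.sum(~np.isnan(vals))),
                }
            )
    return pd.DataFrame(rows)


def qc_summary(
    matrix: QuantMatrix,
    qc_samples: Sequence[str],
    params: StatParams = StatParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Channel statistics plus the descriptive-count table.

    The summary reports, separately for MS1 and MS2 channels: total
    quantified, the three RSD categories, non-quantifiable counts, and
    two median-RSD conventions — over channels passing the RSD gate and
    over all quantifiable channels.
    """
    cs = channel_stats(matrix, qc_samples, params)
    rows = []
    for level, is_ms1 in (("MS1", True), ("MS2", False)):
        sub = cs[cs.is_ms1 == is_ms1]
        quant = sub[sub.rsd_category != "non_quantifiable"]
        passing = quant[quant.rsd_qc < params.rsd_pass]
        rows.append(
            {
                "level": level,
                "n_total": len(sub),
                "n_quantified": len(quant),
                "n_rsd_lt20": int((quant.rsd_category == "<20").sum()),
                "n_rsd_20_30": int((quant.rsd_category == "20-30").sum()),
                "n_rsd_gt30": int((quant.rsd_category == ">30").sum()),
                "n_non_quantifiable": int((sub.rsd_category == "non_quantifiable").sum()),
                "median_rsd_passing": float(passing.rsd_qc.median()) if len(passing) else np.nan,
                "median_rsd_all": float(quant.rsd_qc.median()) if len(quant) else np.nan,
            }
        )
    return cs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fragment selection and linearity
# ---------------------------------------------------------------------------

def fragment_r2_vs_ms1(
    matrix: QuantMatrix, entry_id: str, samples: Sequence[str]
) -> dict[str, float]:
    ms1 = matrix.values(entry_id, "MS1", samples)
    out = {}
    for channel in matrix.channels_for(entry_id):
        if channel == "MS1":
            continue
        out[channel] = pearson_r2(ms1, matrix.values(entry_id, channel, samples))
    return out


def select_best_fragment(
    matrix: QuantMatrix,
    entry_id: str,
    samples: Sequence[str],
    qc_samples: Optional[Sequence[str]] = None,
) -> Optional[str]:
    """The fragment channel tracking MS1 best (highest R² across
    samples); ties broken by lower QC RSD, then higher median area."""
    r2 = fragment_r2_vs_ms1(matrix, entry_id, samples)
    if not r2:
        return None
    scored = []
    for channel, value in r2.items():
        qc_rsd = rsd(matrix.values(entry_id, channel, qc_samples)) \
            if qc_samples is not None else None
        med = float(np.nanmedian(matrix.values(entry_id, channel, samples)))
        scored.append(
            (
                -1.0 if np.isnan(value) else value,
                -(qc_rsd if qc_rsd is not None else np.inf),
                med,
                channel,
            )
        )
    scored.sort(reverse=True)
    return scored[0][3]


def linearity(
    matrix: QuantMatrix,
    volumes: dict[str, float],
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Per-channel R² of area vs injection volume, restricted to volumes
    at or below the saturation cut-off (``linearity_max_volume``)."""
    usable = {s: v for s, v in volumes.items() if v <= params.linearity_max_volume}
    samples = sorted(usable, key=usable.get)
    vols = np.array([usable[s] for s in samples])
    rows = []
    for entry_id in matrix.entry_ids:
        sub = matrix.df[matrix.df.entry_id == entry_id]
        meta = sub.iloc[0]
        for channel in matrix.channels_for(entry_id):
            areas = matrix.values(entry_id, channel, samples)
            rows.append(
                {
                    "entry_id": entry_id,
                    "sum_composition": meta.sum_composition,
                    "channel": channel,
                    "is_ms1": channel == "MS1",
                    "r2_linearity": pearson_r2(vols, areas),
                    "n_volumes_used": int(np.sum(~np.isnan(areas))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Retention filter, representative readout, differential abundance
# ---------------------------------------------------------------------------

def filter_for_diff(
    matrix: QuantMatrix,
    qc_samples: Sequence[str],
    study_samples: Sequence[str],
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Entries retained for differential analysis.

    Retained iff (1) MS1 QC RSD strictly below the pass threshold and at
    least one fragment likewise, and (2) that fragment's R² against MS1
    over all study samples exceeds the R² threshold. Returns one row per
    retained entry with its qualifying fragments."""
    rows = []
    for entry_id in matrix.entry_ids:
        sub = matrix.df[matrix.df.entry_id == entry_id]
        meta = sub.iloc[0]
        ms1_rsd = rsd(matrix.values(entry_id, "MS1", qc_samples, include_filled=False))
        if ms1_rsd is None or ms1_rsd >= params.rsd_pass:
            continue
        r2 = fragment_r2_vs_ms1(matrix, entry_id, study_samples)
        qualifying = []
        for channel in matrix.channels_for(entry_id):
            if channel == "MS1":
                continue
            f_rsd = rsd(matrix.values(entry_id, channel, qc_samples, include_filled=False))
            if f_rsd is None or f_rsd >= params.rsd_pass:
                continue
            value = r2.get(channel, float("nan"))
            if not np.isnan(value) and value > params.r2_ms1_min:
                qualifying.append(channel)
        if qualifying:
            rows.append(
                {
                    "entry_id": entry_id,
                    "sum_composition": meta.sum_composition,
                    "polarity": meta.polarity,
                    "ms1_rsd_qc": ms1_rsd,
                    "qualifying_fragments": ",".join(qualifying),
                }
            )
    return pd.DataFrame(
        rows, columns=["entry_id", "sum_composition", "polarity",
                       "ms1_rsd_qc", "qualifying_fragments"]
    )


def representative_readout(
    matrix: QuantMatrix,
    retained: pd.DataFrame,
    qc_samples: Sequence[str],
) -> pd.DataFrame:
    """Per lipid (sum composition, polarities merged), the passing
    channel with the lowest QC RSD — the readout carried into the
    differential test."""
    rows = []
    for sumcomp, grp in retained.groupby("sum_composition"):
        best = None
        for row in grp.itertuples():
            channels = ["MS1"] + row.qualifying_fragments.split(",")
            for channel in channels:
                r = rsd(matrix.values(row.entry_id, channel, qc_samples,
                                      include_filled=False))
                if r is None:
                    continue
                if best is None or r < best[0]:
                    best = (r, row.entry_id, channel, row.polarity)
        if best is not None:
            rows.append(
                {
                    "sum_composition": sumcomp,
                    "entry_id": best[1],
                    "channel": best[2],
                    "polarity": best[3],
                    "rsd_qc": best[0],
                }
            )
    return pd.DataFrame(
        rows, columns=["sum_composition", "entry_id", "channel", "polarity", "rsd_qc"]
    )


def differential(
    matrix: QuantMatrix,
    representatives: pd.DataFrame,
    groups: dict[str, Sequence[str]],
    params: StatParams = StatParams(),
    group_order: tuple[str, str] = ("WT", "KO"),
) -> pd.DataFrame:
    """Two-group differential abundance on representative channels.

    Fold change is the ratio of arithmetic group means (second group
    over first); the test is a two-sided Welch t on log2 areas; q-values
    are Benjamini–Hochberg across all tested lipids. Significance
    requires fold change beyond the threshold in either direction and
    q below the FDR threshold. Zero-variance groups get a variance
    floor and are flagged."""
    params.validate()
    ref, alt = group_order
    ref_samples = list(groups[ref])
    alt_samples = list(groups[alt])
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError("differential needs >= 2 samples per group")
    rows = []
    for row in representatives.itertuples():
        a = matrix.values(row.entry_id, row.channel, ref_samples)
        b = matrix.values(row.entry_id, row.channel, alt_samples)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            continue
        fc = b.mean() / a.mean() if a.mean() > 0 else np.nan
        la = np.log2(np.maximum(a, 1e-300))
        lb = np.log2(np.maximum(b, 1e-300))
        # Welch t on log2 areas, with a variance floor for degenerate groups
        va, vb = la.var(ddof=1), lb.var(ddof=1)
        flagged = bool(va < 1e-12 or vb < 1e-12)
        va, vb = max(va, 1e-12), max(vb, 1e-12)
        na, nb = la.size, lb.size
        se2 = va / na + vb / nb
        t_stat = (lb.mean() - la.mean()) / math.sqrt(se2)
        dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * sps.t.sf(abs(t_stat), dof)
        rows.append(
            {
                "sum_composition": row.sum_composition,
                "entry_id": row.entry_id,
                "channel": row.channel,
                "polarity": row.polarity,
                "log2_fc": float(np.log2(fc)) if fc > 0 else np.nan,
                "p_value": float(p),
                "zero_variance_flag": flagged,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_value"] = []
        out["significant"] = []
        return out
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    fc_gate = np.abs(out["log2_fc"]) > math.log2(params.fc_threshold)
    out["significant"] = fc_gate & (out["q_value"] < params.fdr_threshold)
    return out


def median_center(
    matrix: QuantMatrix,
    channel: str = "MS1",
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Normalized median-centred fold changes: per lipid, each sample's
    log2(area / median area of that lipid across the samples). Row
    medians are exactly zero — the heatmap-ready matrix."""
    samples = list(samples) if samples is not None else matrix.samples
    rows = {}
    for entry_id in matrix.entry_ids:
        vals = matrix.values(entry_id, channel, samples)
        if np.all(np.isnan(vals)):
            continue
        med = np.nanmedian(vals)
        if med <= 0:
            continue
        rows[entry_id] = np.log2(vals / med)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(samples))
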