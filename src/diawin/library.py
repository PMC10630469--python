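"""Spectral-library construction, matching and lipid nomenclature.

An in-house library is built from iterative DDA injections: MS2 scans are
grouped into consensus spectra, searched against reference libraries
(MSP or tab-delimited), gated on precursor mass, retention time, match
score and matched-peak count, restricted to the accepted adducts for the
polarity, and deduplicated per sum composition.

Lipid names follow the shorthand grammar
``CLASS[-P|-O] C:D(;xO)?(/C:D(;xO)?)*`` with legacy sphingoid prefixes
d/t/m mapping to 2/3/1 hydroxyls and optional isotope-label suffixes
(e.g. ``-d9``). The sum composition aggregates chains to total
carbons:double-bonds (``SM 30:1;2O/2:0`` → ``SM 32:1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Run

POSITIVE_ADDUCTS = ("[M+H]+", "[M+NH4]+")
NEGATIVE_ADDUCTS = ("[M-H]-", "[M+HCOO]-")


@dataclass(frozen=True)
class MatchParams:
    """Tolerances and gates for library construction and extraction.

    ``rt_shift`` is interpreted in the unit given by ``rt_shift_units``
    (seconds by default); DDA library search conventionally uses 10,
    DIA extraction 20.
    """

    ms1to1: float = 0.005        # precursor tolerance, Th
    ms2to1: float = 0.01         # fragment tolerance for extraction, Th
    frag_match_tol: float = 0.01  # Da, library spectrum matching
    ms2_score_min: float = 0.5
    min_peaks: int = 1
    rt_shift: float = 10.0
    rt_shift_units: str = "sec"  # {"sec", "min", "scans"}
    scan_period: float = 0.55 / 60.0  # minutes per cycle, used for "scans"

    def validate(self) -> None:
        for name in ("ms1to1", "ms2to1", "frag_match_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.ms2_score_min <= 1):
            raise ValueError("ms2_score_min must lie in [0, 1]")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")

    @property
    def rt_shift_min(self) -> float:
        """RT-shift tolerance converted to minutes."""
        if self.rt_shift_units == "min":
            return self.rt_shift
        if self.rt_shift_units == "sec":
            return self.rt_shift / 60.0
        if self.rt_shift_units == "scans":
            return self.rt_shift * self.scan_period
        raise ValueError(f"unknown rt_shift_units {self.rt_shift_units!r}")


DIA_MATCH_PARAMS = MatchParams(rt_shift=20.0)


@dataclass
class LibraryEntry:
    species_name: str
    precursor_mz: float
    fragments: list[tuple[float, float]]  # (mz, relative intensity) desc by intensity
    adduct: str = "[M+H]+"
    polarity: str = "positive"
    rt: Optional[float] = None
    sum_composition: str = ""
    lipid_class: str = ""
    match_score: float = float("nan")
    source: str = "in_house"
    entry_id: str = ""

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"library entry {self.species_name!r} has no fragments")
        self.fragments = sorted(self.fragments, key=lambda p: -p[1])
        if not self.sum_composition:
            try:
                self.sum_composition = to_sum_composition(self.species_name)
            except LipidNameError:
                self.sum_composition = self.species_name
        if not self.lipid_class:
            self.lipid_class = self.sum_composition.split(" ")[0]
        if not self.entry_id:
            self.entry_id = f"{self.species_name}|{self.adduct}"


@dataclass
class ConsensusSpectrum:
    spectrum_id: str
    precursor_mz: float
    rt: float
    peaks: list[tuple[float, float]]
    n_scans: int = 1
    polarity: str = "positive"


@dataclass
class Annotation:
    spectrum_id: str
    candidate: LibraryEntry
    score: float
    n_matched: int
    passed: bool
    ref_position: int = -1


# ---------------------------------------------------------------------------
# Lipid shorthand
# ---------------------------------------------------------------------------

class LipidNameError(ValueError):
    pass


_CHAIN_RE = re.compile(
    r"^(?P<pref>[dtm])?(?P<c>\d+):(?P<d>\d+)(?:;(?P<ox>\d*)O(?P<ox2>\d*))?(?:-d(?P<label>\d+))?$"
)
_PREFIX_OXYGENS = {"d": 2, "t": 3, "m": 1}


@dataclass(frozen=True)
class ParsedLipid:
    lipid_class: str
    chains: tuple[tuple[int, int, int], ...]  # (carbons, double bonds, oxygens)
    ether: bool = False        # -O (ether) or -P (plasmalogen) class suffix
    class_suffix: str = ""     # "", "-P" or "-O"
    labels: tuple[int, ...] = ()  # deuterium counts per labelled chain


def parse_lipid_name(name: str) -> ParsedLipid:
    """Parse a lipid shorthand name into class + chain compositions.

    Unknown class tokens pass through opaque, with the chains still
    parsed; a name with no chain part (e.g. ``COH-d7``) is returned as a
    chain-less class.
    """
    name = name.strip()
    if not name:
        raise LipidNameError("empty lipid name")
    head, _, tail = name.partition(" ")
    if not tail:
        return ParsedLipid(lipid_class=name, chains=())
    cls = head
    suffix = ""
    if cls.endswith(("-P", "-O")):
        suffix = cls[-2:]
        cls = cls[:-2]
    chains = []
    labels = []
    for token in tail.split("/"):
        m = _CHAIN_RE.match(token.strip())
        if not m:
            raise LipidNameError(f"cannot parse chain token {token!r} in {name!r}")
        oxy = 0
        if m.group("pref"):
            oxy += _PREFIX_OXYGENS[m.group("pref")]
        if m.group("ox") is not None or m.group("ox2") is not None:
            # ";2O" and ";O2" dialects; bare ";O" means one oxygen
            count = m.group("ox") or m.group("ox2") or ""
            oxy += int(count) if count else 1
        chains.append((int(m.group("c")), int(m.group("d")), oxy))
        if m.group("label"):
            labels.append(int(m.group("label")))
    return ParsedLipid(
        lipid_class=cls,
        chains=tuple(chains),
        ether=suffix in ("-O", "-P"),
        class_suffix=suffix,
        labels=tuple(labels),
    )


def to_sum_composition(name: str) -> str:
    """Collapse a molecular-species name to its sum composition
    (``CLASS totalC:totalDB``); idempotent on already-sum names and on
    chain-less names."""
    parsed = parse_lipid_name(name)
    if not parsed.chains:
        return name.strip()
    total_c = sum(c for c, _, _ in parsed.chains)
    total_d = sum(d for _, d, _ in parsed.chains)
    return f"{parsed.lipid_class}{parsed.class_suffix} {total_c}:{total_d}"


# ---------------------------------------------------------------------------
# Spectrum matching
# ---------------------------------------------------------------------------

def match_score(
    query: Sequence[tuple[float, float]],
    reference: Sequence[tuple[float, float]],
    frag_match_tol: float = 0.01,
) -> tuple[float, int]:
    """Score two centroid peak lists.

    Peaks are paired greedily one-to-one, closest m/z difference first,
    within ``frag_match_tol``. The score is the cosine similarity of
    square-root intensities over the union of paired and unpaired peaks,
    in [0, 1]. Returns ``(score, n_matched)``.
    """
    if not query or not reference:
        raise ValueError("match_score requires non-empty peak lists")
    pairs = []
    for qi, (qmz, _) in enumerate(query):
        for ri, (rmz, _) in enumerate(reference):
            d = abs(qmz - rmz)
            if d <= frag_match_tol:
                pairs.append((d, qi, ri))
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, qi, ri in pairs:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        matched.append((qi, ri))
    qv, rv = [], []
    for qi, ri in matched:
        qv.append(np.sqrt(query[qi][1]))
        rv.append(np.sqrt(reference[ri][1]))
    for qi, (_, inten) in enumerate(query):
        if qi not in used_q:
            qv.append(np.sqrt(inten))
            rv.append(0.0)
    for ri, (_, inten) in enumerate(reference):
        if ri not in used_r:
            qv.append(0.0)
            rv.append(np.sqrt(inten))
    qv = np.asarray(qv)
    rv = np.asarray(rv)
    denom = np.linalg.norm(qv) * np.linalg.norm(rv)
    score = float(qv @ rv / denom) if denom > 0 else 0.0
    return min(max(score, 0.0), 1.0), len(matched)


# ---------------------------------------------------------------------------
# Consensus construction from iterative DDA injections
# ---------------------------------------------------------------------------

def _merge_peaks(
    peak_lists: list[list[tuple[float, float]]], tol: float
) -> list[tuple[float, float]]:
    """Merge fragment peaks across replicate scans at ``tol`` resolution;
    merged intensity is the median across contributing scans."""
    flat = sorted(p for peaks in peak_lists for p in peaks)
    merged: list[tuple[float, float]] = []
    group_mz: list[float] = []
    group_int: list[float] = []
    for mz, inten in flat:
        if group_mz and mz - group_mz[0] > tol:
            merged.append((float(np.average(group_mz, weights=group_int)),
                           float(np.median(group_int))))
            group_mz, group_int = [], []
        group_mz.append(mz)
        group_int.append(inten)
    if group_mz:
        merged.append((float(np.average(group_mz, weights=group_int)),
                       float(np.median(group_int))))
    return merged


def build_consensus(
    dda_runs: Sequence[Run],
    ms1to1: float = 0.005,
    rt_tol: float = 0.2,
    ms2to1: float = 0.01,
) -> list[ConsensusSpectrum]:
    """Group MS2 scans from iterative DDA injections into consensus
    spectra by (precursor m/z within ±ms1to1, RT within ±rt_tol).

    The consensus precursor m/z is the total-intensity-weighted mean of
    the member scans' precursor targets; peaks are merged at ``ms2to1``
    resolution with median intensity.
    """
    scans = []
    for run in dda_runs:
        if run.mode != "DDA":
            raise ValueError(f"run {run.sample_id!r} is not DDA")
        for s in run.ms2_spectra():
            lo, hi = s.precursor_window
            scans.append((0.5 * (lo + hi), s.rt, s, run.polarity))
    scans.sort(key=lambda t: (t[0], t[1]))
    groups: list[list[tuple[float, float, object, str]]] = []
    for item in scans:
        placed = False
        for g in groups:
            pmz = np.mean([x[0] for x in g])
            prt = np.mean([x[1] for x in g])
            if abs(item[0] - pmz) <= ms1to1 and abs(item[1] - prt) <= rt_tol:
                g.append(item)
                placed = True
                break
        if not placed:
            groups.append([item])
    out = []
    for k, g in enumerate(groups):
        weights = [max(float(x[2].intensity.sum()), 1e-12) for x in g]
        pmz = float(np.average([x[0] for x in g], weights=weights))
        rt = float(np.average([x[1] for x in g], weights=weights))
        peaks = _merge_peaks(
            [list(zip(x[2].mz.tolist(), x[2].intensity.tolist())) for x in g], ms2to1
        )
        out.append(
            ConsensusSpectrum(
                spectrum_id=f"cons{k:05d}", precursor_mz=pmz, rt=rt,
                peaks=peaks, n_scans=len(g), polarity=g[0][3],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Library search
# ---------------------------------------------------------------------------

def search_library(
    spectra: Sequence[ConsensusSpectrum],
    references: Sequence[LibraryEntry],
    params: MatchParams = MatchParams(),
) -> list[Annotation]:
    """Score every consensus spectrum against every gated reference.

    Candidates are gated on |Δ precursor| ≤ ms1to1 and, when the
    reference carries an RT, |ΔRT| ≤ rt_shift; all candidates are kept
    for audit, with ``passed`` set per the score / matched-peak gates.
    """
    if not references:
        raise ValueError("reference list is empty")
    params.validate()
    rt_tol = params.rt_shift_min
    annotations = []
    for spec in spectra:
        for pos, ref in enumerate(references):
            if abs(spec.precursor_mz - ref.precursor_mz) > params.ms1to1:
                continue
            if ref.rt is not None and abs(spec.rt - ref.rt) > rt_tol:
                continue
            score, n_matched = match_score(spec.peaks, ref.fragments, params.frag_match_tol)
            passed = score >= params.ms2_score_min and n_matched >= params.min_peaks
            annotations.append(
                Annotation(
                    spectrum_id=spec.spectrum_id, candidate=ref, score=score,
                    n_matched=n_matched, passed=passed, ref_position=pos,
                )
            )
    return annotations


def resolve_annotation(
    candidates: Sequence[Annotation], tie: str = "last"
) -> Optional[Annotation]:
    """Pick the winning annotation for one spectrum: highest score among
    passed candidates; ties broken by the *last* position in the
    reference list (``tie="first"`` gives the opposite convention)."""
    passed = [a for a in candidates if a.passed]
    if not passed:
        return None
    sign = 1 if tie == "last" else -1
    return max(passed, key=lambda a: (a.score, sign * a.ref_position))


def filter_adducts(
    annotations: Sequence[Annotation], polarity: str
) -> list[Annotation]:
    """Keep only the accepted adducts for the polarity: [M+H]+ and
    [M+NH4]+ in positive mode, [M-H]- and [M+HCOO]- in negative."""
    allowed = POSITIVE_ADDUCTS if polarity == "positive" else NEGATIVE_ADDUCTS
    norm = {a.replace("−", "-").replace(" ", ""): a for a in allowed}
    return [a for a in annotations
            if a.candidate.adduct.replace("−", "-").replace(" ", "") in norm]


def dedupe_entries(entries: Sequence[LibraryEntry]) -> list[LibraryEntry]:
    """One entry per (sum_composition, adduct, polarity): keep the
    highest match score, break ties by earliest RT."""
    best: dict[tuple[str, str, str], LibraryEntry] = {}
    for e in entries:
        key = (e.sum_composition, e.adduct, e.polarity)
        cur = best.get(key)
        if cur is None:
            best[key] = e
            continue
        e_score = e.match_score if not np.isnan(e.match_score) else -1.0
        c_score = cur.match_score if not np.isnan(cur.match_score) else -1.0
        if e_score > c_score or (
            e_score == c_score
            and (e.rt if e.rt is not None else np.inf) < (cur.rt if cur.rt is not None else np.inf)
        ):
            best[key] = e
    return list(best.values())


def annotations_to_entries(
    spectra: Sequence[ConsensusSpectrum],
    annotations: Sequence[Annotation],
    tie: str = "last",
) -> list[LibraryEntry]:
    """Resolve annotations per spectrum into in-house library entries
    carrying the consensus spectrum's peaks and RT."""
    by_spec: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_spec.setdefault(a.spectrum_id, []).append(a)
    spec_by_id = {s.spectrum_id: s for s in spectra}
    entries = []
    for sid, cands in by_spec.items():
        win = resolve_annotation(cands, tie=tie)
        if win is None:
            continue
        spec = spec_by_id[sid]
        ref = win.candidate
        entries.append(
            LibraryEntry(
                species_name=ref.species_name,
                precursor_mz=spec.precursor_mz,
                fragments=list(spec.peaks),
                adduct=ref.adduct,
                polarity=ref.polarity,
                rt=spec.rt,
                sum_composition=ref.sum_composition,
                lipid_class=ref.lipid_class,
                match_score=win.score,
                source="in_house",
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Serialization: NIST-style MSP and long TSV
# ---------------------------------------------------------------------------

def write_library(entries: Sequence[LibraryEntry], path, format: str = "msp") -> Path:
    path = Path(path)
    if format == "msp":
        with open(path, "w") as fh:
            for e in entries:
                fh.write(f"Name: {e.species_name}\n")
                fh.write(f"PrecursorMZ: {e.precursor_mz!r}\n")
                if e.rt is not None:
                    fh.write(f"RETENTIONTIME: {e.rt!r}\n")
                fh.write(f"Adduct: {e.adduct}\n")
                fh.write(f"Polarity: {e.polarity}\n")
                fh.write(f"SumComposition: {e.sum_composition}\n")
                fh.write(f"LipidClass: {e.lipid_class}\n")
                if not np.isnan(e.match_score):
                    fh.write(f"MatchScore: {e.match_score!r}\n")
                fh.write(f"Source: {e.source}\n")
                fh.write(f"Num Peaks: {len(e.fragments)}\n")
                for mz, inten in e.fragments:
                    fh.write(f"{mz!r} {inten!r}\n")
                fh.write("\n")
    elif format == "tsv":
        rows = []
        for e in entries:
            for rank, (mz, inten) in enumerate(e.fragments):
                rows.append(
                    {
                        "species_name": e.species_name,
                        "sum_composition": e.sum_composition,
                        "lipid_class": e.lipid_class,
                        "adduct": e.adduct,
                        "polarity": e.polarity,
                        "precursor_mz": e.precursor_mz,
                        "rt": e.rt,
                        "match_score": e.match_score,
                        "source": e.source,
                        "fragment_rank": rank,
                        "fragment_mz": mz,
                        "fragment_intensity": inten,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown library format {format!r}")
    return path


def read_library(path, format: Optional[str] = None) -> list[LibraryEntry]:
    path = Path(path)
    if format is None:
        format = "msp" if path.suffix.lower() == ".msp" else "tsv"
    if format == "msp":
        return _read_msp(path)
    df = pd.read_csv(path, sep="\t")
    entries = []
    for (name, adduct), grp in df.groupby(["species_name", "adduct"], sort=False):
        grp = grp.sort_values("fragment_rank")
        first = grp.iloc[0]
        entries.append(
            LibraryEntry(
                species_name=str(name),
                precursor_mz=float(first.precursor_mz),
                fragments=list(zip(grp.fragment_mz, grp.fragment_intensity)),
                adduct=str(adduct),
                polarity=str(first.polarity),
                rt=None if pd.isna(first.rt) else float(first.rt),
                sum_composition=str(first.sum_composition),
                lipid_class=str(first.lipid_class),
                match_score=float(first.match_score) if not pd.isna(first.match_score) else float("nan"),
                source=str(first.source),
            )
        )
    return entries


def _read_msp(path: Path) -> list[LibraryEntry]:
    entries = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        if not fields:
            return
        entries.append(
            LibraryEntry(
                species_name=fields.get("name", ""),
                precursor_mz=float(fields["precursormz"]),
                fragments=list(peaks),
                adduct=fields.get("adduct", "[M+H]+"),
                polarity=fields.get("polarity", "positive"),
                rt=float(fields["retentiontime"]) if "retentiontime" in fields else None,
                sum_composition=fields.get("sumcomposition", ""),
                lipid_class=fields.get("lipidclass", ""),
                match_score=float(fields.get("matchscore", "nan")),
                source=fields.get("source", str(path.name)),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                flush()
                fields, peaks = {}, []
                continue
            if ":" in line and not line[0].isdigit():
                key, _, val = line.partition(":")
                fields[key.strip().lower().replace(" ", "")] = val.strip()
            else:
                parts = line.replace("\t", " ").split()
                if len(parts) >= 2:
                    peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return entries
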