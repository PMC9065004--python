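"""Spectrum-library matching and the empirical S_p / delta-S_p scoring scheme.

A candidate oligonucleotide is scored against one MS/MS scan as

    S_p = (sum I_match / sum I_all) * (n / L) * (1 + sum_s B_s)

where n of the L theoretical sequence-defining ions were matched within the
MS2 ppm tolerance, intensities are normalized to the most intense peak left
after the precursor ion and its neutral-loss peaks (plus an m/z exclusion
window around each) have been set aside, and B_s = beta * alpha * k_s rewards
k_s consecutively matched index pairs (i, i+1) inside a single ion series s.
The B_s term is isolated in :func:`consecutive_bonus` so alternative reward
shapes can be swapped in.

The relative score

    delta_S_p = (S_p_top - S_p) / S_p_top

separates the top oligonucleotide-spectrum match (OSM) from its competitors;
delta_S_p2 (second-best target) and delta_S_pD (best competing decoy) are the
specificity measures carried into filtering and FDR estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import NEUTRON_DELTA, PROTON_MASS
from .library import FragmentIon, LibraryEntry, precursor_losses

__all__ = [
    "Spectrum",
    "ScoreParams",
    "MatchResult",
    "OSM",
    "MgfError",
    "read_mgf",
    "match_precursor",
    "match_fragments",
    "consecutive_bonus",
    "score_sp",
    "rank_and_delta",
    "search",
    "osm_frame",
    "write_osm_table",
]


class MgfError(ValueError):
    """Malformed Mascot Generic Format input."""


@dataclass
class Spectrum:
    """One MS/MS scan: precursor descriptor plus an m/z-sorted peak list."""

    scan_id: str
    precursor_mz: float
    charge: int  # magnitude; polarity is negative throughout
    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: invalid intensities")


@dataclass
class ScoreParams:
    """Tolerances and reward parameters of the search.

    beta/alpha are the consecutive-match reward factors; the defaults are the
    values used for the rRNA/tRNA/mRNA searches.  ``exclusion_window`` is the
    half-width (m/z units) of the neighborhood removed around the assigned
    precursor and precursor-loss peaks before normalization.
    """

    ms1_ppm: float = 20.0
    ms2_ppm: float = 40.0
    beta: float = 0.025
    alpha: float = 2.0
    exclusion_window: float = 1.5
    match_isotopologues: bool = False
    ms1_offset_ppm: float = 0.0
    ms2_offset_ppm: float = 0.0

    def __post_init__(self):
        if self.ms1_ppm <= 0 or self.ms2_ppm <= 0:
            raise ValueError("ppm tolerances must be positive")
        if self.beta < 0 or self.alpha < 1:
            raise ValueError("require beta >= 0 and alpha >= 1")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an mgf file; negative-mode charges are written with a trailing '-'.

    Spectra with empty peak lists are skipped with a warning; a block missing
    PEPMASS raises :class:`MgfError` naming the scan.
    """
    spectra = []
    block: dict | None = None
    peaks: list[tuple[float, float]] = []
    index = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if block is not None:
                raise MgfError(f"line {lineno}: nested BEGIN IONS")
            block, peaks = {}, []
            index += 1
        elif line == "END IONS":
            if block is None:
                raise MgfError(f"line {lineno}: END IONS without BEGIN IONS")
            title = block.get("TITLE", f"scan={index}")
            if "PEPMASS" not in block:
                raise MgfError(f"scan {title!r} (block {index}): missing PEPMASS")
            charge_txt = block.get("CHARGE", "1-").strip()
            charge = int(charge_txt.rstrip("+-")) if charge_txt.rstrip("+-") else 1
            if not peaks:
                warnings.warn(f"scan {title!r}: empty peak list, skipped")
                block = None
                continue
            arr = np.array(peaks)
            rt = float(block["RTINSECONDS"]) if "RTINSECONDS" in block else None
            spectra.append(
                Spectrum(
                    scan_id=title,
                    precursor_mz=float(block["PEPMASS"].split()[0]),
                    charge=abs(charge),
                    mz=arr[:, 0],
                    intensity=arr[:, 1],
                    retention_time=rt,
                )
            )
            block = None
        elif block is not None:
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                block[key.upper()] = value
            else:
                fields = line.split()
                try:
                    peaks.append((float(fields[0]), float(fields[1])))
                except (IndexError, ValueError):
                    raise MgfError(f"line {lineno}: malformed peak {line!r}") from None
    if block is not None:
        raise MgfError("unterminated BEGIN IONS block at end of file")
    return spectra


def _ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def match_precursor(
    spectrum: Spectrum, library: Sequence[LibraryEntry], params: ScoreParams
) -> list[LibraryEntry]:
    """Candidate entries whose precursor m/z and charge match the scan.

    With ``match_isotopologues`` set, matches displaced by one neutron mass
    over charge (M+1 / M-1) are accepted as well.
    """
    corrected = spectrum.precursor_mz * (1 - params.ms1_offset_ppm * 1e-6)
    out = []
    for entry in library:
        mz = entry.precursor_mz.get(spectrum.charge)
        if mz is None:
            continue
        targets = [mz]
        if params.match_isotopologues:
            shift = NEUTRON_DELTA / spectrum.charge
            targets += [mz + shift, mz - shift]
        if any(abs(_ppm_error(corrected, t)) <= params.ms1_ppm for t in targets):
            out.append(entry)
    return out


@dataclass
class MatchResult:
    """Outcome of assigning theoretical ions of one entry to spectrum peaks."""

    assignments: list[tuple[FragmentIon, int, float]]  # (ion, peak index, ppm error)
    n: int
    L: int
    sum_match: float
    sum_all: float
    series_indices: dict[str, set[int]]  # matched indices per ion series
    excluded_peaks: set[int] = field(default_factory=set)
    peak_mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_intensity: np.ndarray = field(default_factory=lambda: np.empty(0))


def match_fragments(
    spectrum: Spectrum, entry: LibraryEntry, params: ScoreParams
) -> MatchResult:
    """Greedy one-to-one assignment of theoretical fragment ions to peaks.

    The precursor peak and precursor-loss peaks are identified first and
    excluded — together with +-``exclusion_window`` m/z neighborhoods — from
    the intensity normalization and from sum I_all.  Candidate (ion, peak)
    pairs within the MS2 tolerance are then accepted in order of ascending
    absolute ppm error (ties: higher peak intensity, then lower peak m/z),
    each peak and each ion used at most once.
    """
    mz = spectrum.mz
    inten = spectrum.intensity
    corrected = mz * (1 - params.ms2_offset_ppm * 1e-6)

    # 1) locate precursor and loss peaks, build the exclusion mask
    loss_ions = precursor_losses(entry.oligo, charges=list(entry.precursor_mz))
    excluded = np.zeros(len(mz), dtype=bool)
    for ion in loss_ions:
        hits = np.abs((corrected - ion.mz) / ion.mz * 1e6) <= params.ms2_ppm
        for idx in np.nonzero(hits)[0]:
            excluded |= np.abs(mz - mz[idx]) <= params.exclusion_window

    kept = ~excluded
    sum_all_raw = float(inten[kept].sum())
    norm = float(inten[kept].max()) if kept.any() and inten[kept].max() > 0 else 1.0

    # 2) candidate pairs inside tolerance, greedy by |ppm|
    candidates = []
    for ion_idx, ion in enumerate(entry.fragments):
        errors = (corrected - ion.mz) / ion.mz * 1e6
        for pk in np.nonzero((np.abs(errors) <= params.ms2_ppm) & kept)[0]:
            candidates.append((abs(errors[pk]), -inten[pk], mz[pk], ion_idx, int(pk), errors[pk]))
    candidates.sort()

    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    assignments = []
    series_indices: dict[str, set[int]] = {}
    sum_match = 0.0
    for _, _, _, ion_idx, pk, err in candidates:
        if pk in used_peaks or ion_idx in used_ions:
            continue
        used_peaks.add(pk)
        used_ions.add(ion_idx)
        ion = entry.fragments[ion_idx]
        assignments.append((ion, pk, float(err)))
        series_indices.setdefault(ion.series, set()).add(ion.index)
        sum_match += float(inten[pk])

    return MatchResult(
        assignments=assignments,
        n=len(assignments),
        L=len(entry.fragments),
        sum_match=sum_match / norm,
        sum_all=sum_all_raw / norm,
        series_indices=series_indices,
        excluded_peaks=set(np.nonzero(excluded)[0]),
        peak_mz=mz,
        peak_intensity=inten,
    )


def consecutive_bonus(series_indices: dict[str, set[int]], params: ScoreParams) -> float:
    """sum_s B_s with B_s = beta * alpha * k_s.

    k_s counts adjacent matched index pairs (i, i+1) within one ion series,
    pooling charge states of the same series.
    """
    total = 0.0
    for indices in series_indices.values():
        k = sum(1 for i in indices if i + 1 in indices)
        total += params.beta * params.alpha * k
    return total


def score_sp(matched: MatchResult, params: ScoreParams) -> float:
    """The empirical match score S_p; zero when nothing was matched."""
    if matched.L == 0:
        raise ValueError("entry has no theoretical fragments (L = 0)")
    if matched.n == 0 or matched.sum_all <= 0:
        return 0.0
    intensity_fraction = matched.sum_match / matched.sum_all
    return (
        intensity_fraction
        * (matched.n / matched.L)
        * (1.0 + consecutive_bonus(matched.series_indices, params))
    )


@dataclass
class OSM:
    """One scored oligonucleotide-spectrum match."""

    scan_id: str
    entry: LibraryEntry
    match: MatchResult
    sp: float
    rank: int = 0
    delta_sp: float = 0.0
    delta_sp2: float | None = None  # top OSM only: second-best target
    delta_spd: float | None = None  # top OSM only: best competing decoy
    degenerate: bool = False  # top score was zero; deltas are placeholders

    @property
    def is_decoy(self) -> bool:
        return self.entry.is_decoy


def rank_and_delta(osms: list[OSM]) -> list[OSM]:
    """Rank competing OSMs of one spectrum by S_p and attach delta scores.

    Ties on S_p break deterministically: larger n, then target before decoy,
    then lexicographic sequence.  When the top score is zero all deltas are
    reported as 0 and the OSMs flagged degenerate.
    """
    if not osms:
        return []
    osms = sorted(
        osms, key=lambda o: (-o.sp, -o.match.n, o.is_decoy, o.entry.sequence)
    )
    top = osms[0].sp
    degenerate = top <= 0
    for rank, o in enumerate(osms, start=1):
        o.rank = rank
        o.delta_sp = 0.0 if degenerate else (top - o.sp) / top
        o.degenerate = degenerate
    targets = [o for o in osms if not o.is_decoy]
    decoys = [o for o in osms if o.is_decoy]
    osms[0].delta_sp2 = targets[1].delta_sp if len(targets) > 1 else None
    osms[0].delta_spd = decoys[0].delta_sp if decoys else None
    return osms


def search(
    spectra: Iterable[Spectrum],
    library: Sequence[LibraryEntry],
    params: ScoreParams | None = None,
) -> list[OSM]:
    """Score every spectrum against its precursor-matched candidates."""
    params = params or ScoreParams()
    out: list[OSM] = []
    for spectrum in spectra:
        osms = []
        for entry in match_precursor(spectrum, library, params):
            if entry.L == 0:
                continue
            matched = match_fragments(spectrum, entry, params)
            osms.append(OSM(spectrum.scan_id, entry, matched, score_sp(matched, params)))
        out.extend(rank_and_delta(osms))
    return out


def osm_frame(osms: Sequence[OSM]) -> pd.DataFrame:
    """Flat OSM table; one row per scored candidate."""
    rows = []
    for o in osms:
        mean_ppm = (
            float(np.mean([e for _, _, e in o.match.assignments]))
            if o.match.assignments
            else np.nan
        )
        rows.append(
            dict(
                scan=o.scan_id,
                name=o.entry.name,
                sequence=o.entry.sequence,
                channel=o.entry.oligo.scheme.channel,
                source_id=o.entry.oligo.source_id,
                start=o.entry.oligo.start,
                end=o.entry.oligo.end,
                is_decoy=o.is_decoy,
                n=o.match.n,
                L=o.match.L,
                sum_i_match=o.match.sum_match,
                sum_i_all=o.match.sum_all,
                sp=o.sp,
                delta_sp=o.delta_sp,
                delta_sp2=o.delta_sp2,
                delta_spd=o.delta_spd,
                rank=o.rank,
                mean_ms2_ppm=mean_ppm,
            )
        )
    return pd.DataFrame(rows)


def write_osm_table(osms: Sequence[OSM], path: str | Path) -> None:
    osm_frame(osms).to_csv(path, sep="\t", index=False, float_format="%.6f")
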