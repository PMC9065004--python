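"""Final-report filtering, sequence-coverage mapping and spectrum annotation.

After search and FDR analysis, rank-1 target OSMs are filtered on score and
specificity thresholds, optionally reduced to unique or modification-bearing
sequences (light and heavy channels counted separately), and mapped back onto
the input RNA sequences to report per-position coverage.  Each retained OSM
can be exported as a static annotated-spectrum document (TSV + simple HTML)
for manual curation.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .search import OSM

__all__ = [
    "FilterSpec",
    "CoverageMap",
    "filter_report",
    "map_coverage",
    "annotate_spectrum",
    "write_annotation_html",
    "coverage_bed_frame",
]


@dataclass
class FilterSpec:
    """User-composable OSM filters for the final report.

    ``min_delta_sp2`` keeps only matches whose runner-up target is at least
    that relative distance below the top score (a specificity filter);
    matches without any competing target always pass it.
    """

    min_sp: float = 0.0
    min_delta_sp2: float = 0.0
    unique_sequences: bool = False
    modified_only: bool = False
    modified_codes: frozenset[str] = frozenset("ACGU")  # codes NOT counting as modified

    def __post_init__(self):
        if self.min_sp < 0 or self.min_delta_sp2 < 0:
            raise ValueError("thresholds must be >= 0")


def filter_report(osms: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Rank-1 targets surviving the score/specificity/uniqueness filters."""
    out = osms[(osms["rank"] == 1) & (~osms["is_decoy"])].copy()
    out = out[out["sp"] >= spec.min_sp]
    if spec.min_delta_sp2 > 0:
        keep = out["delta_sp2"].isna() | (out["delta_sp2"] >= spec.min_delta_sp2)
        out = out[keep]
    if spec.modified_only:
        is_mod = out["sequence"].map(
            lambda s: any(c not in spec.modified_codes for c in s)
        )
        out = out[is_mod]
    if spec.unique_sequences:
        # light and heavy identifications are counted separately
        out = out.drop_duplicates(subset=["sequence", "channel"], keep="first")
    return out.reset_index(drop=True)


@dataclass
class CoverageMap:
    """Per-position identification coverage of one reference sequence."""

    reference_id: str
    length: int
    hit_counts: np.ndarray  # 1-based positions at index pos-1
    percent: float
    unique_percent: float  # restricted to fragments placeable at one locus


def _occurrences(needle: str, haystack: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def map_coverage(
    records: pd.DataFrame, references: dict[str, str]
) -> dict[str, CoverageMap]:
    """Project identified fragments onto their references.

    ``records`` needs columns source_id, start, end, sequence (1-based
    inclusive coordinates).  Overlapping fragments count each position once.
    The unique-placement percentage restricts to fragments whose sequence
    occurs at exactly one position in the (modification-substituted)
    reference.  Records from several parallel digests can simply be
    concatenated before the call — coverage is the union over records.
    """
    out = {}
    for ref_id, ref_seq in references.items():
        n = len(ref_seq)
        hits = np.zeros(n, dtype=int)
        unique_mask = np.zeros(n, dtype=bool)
        sub = records[records["source_id"] == ref_id]
        for row in sub.to_dict("records"):
            start, end = int(row["start"]), int(row["end"])
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"record {row['sequence']} at {start}-{end} exceeds "
                    f"reference {ref_id} of length {n}"
                )
            hits[start - 1 : end] += 1
            if _occurrences(str(row["sequence"]), ref_seq) == 1:
                unique_mask[start - 1 : end] = True
        percent = float((hits > 0).sum()) / n * 100.0
        out[ref_id] = CoverageMap(
            reference_id=ref_id,
            length=n,
            hit_counts=hits,
            percent=percent,
            unique_percent=float(unique_mask.sum()) / n * 100.0,
        )
    return out


def coverage_bed_frame(coverage: dict[str, CoverageMap]) -> pd.DataFrame:
    """Covered intervals as a BED-like table (1-based inclusive)."""
    rows = []
    for ref_id, cov in coverage.items():
        covered = cov.hit_counts > 0
        pos = 0
        while pos < cov.length:
            if covered[pos]:
                end = pos
                while end + 1 < cov.length and covered[end + 1]:
                    end += 1
                rows.append(dict(reference=ref_id, start=pos + 1, end=end + 1))
                pos = end + 1
            else:
                pos += 1
    return pd.DataFrame(rows, columns=["reference", "start", "end"])


def annotate_spectrum(osm: OSM) -> pd.DataFrame:
    """Per-ion annotation table of one OSM (row count = L).

    Every theoretical fragment ion appears once, with its matched peak, the
    signed ppm error and a matched flag — the machine-readable counterpart of
    a manually curated annotated spectrum.
    """
    assigned = {id(ion): (pk, err) for ion, pk, err in osm.match.assignments}
    rows = []
    for ion in osm.entry.fragments:
        pk_err = assigned.get(id(ion))
        rows.append(
            dict(
                series=ion.series,
                index=ion.index,
                charge=ion.charge,
                theoretical_mz=ion.mz,
                matched=pk_err is not None,
                peak_mz=None if pk_err is None else float(osm.match.peak_mz[pk_err[0]]),
                ppm_error=None if pk_err is None else pk_err[1],
            )
        )
    return pd.DataFrame(rows)


def write_annotation_html(annotation: pd.DataFrame, osm_name: str, path: str | Path) -> None:
    """Static HTML rendering of an annotation table (matched rows highlighted)."""
    head = (
        "<html><head><style>"
        "table{border-collapse:collapse;font-family:monospace}"
        "td,th{border:1px solid #999;padding:2px 6px}"
        "tr.hit{background:#cfe8cf}"
        "</style></head><body>"
        f"<h3>{html.escape(osm_name)}</h3><table><tr>"
        + "".join(f"<th>{c}</th>" for c in annotation.columns)
        + "</tr>"
    )
    rows = []
    for row in annotation.to_dict("records"):
        cls = ' class="hit"' if row["matched"] else ""
        cells = "".join(
            f"<td>{'' if v is None else v}</td>" for v in row.values()
        )
        rows.append(f"<tr{cls}>{cells}</tr>")
    Path(path).write_text(head + "".join(rows) + "</table></body></html>")
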