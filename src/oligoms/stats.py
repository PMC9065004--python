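"""Target-decoy FDR and m/z-offset diagnostics.

FDR follows the concatenated target-decoy convention ("simple FDR"): among
rank-1 matches above a score cutoff, the decoy count divided by the target
count estimates the fraction of false identifications.  Score cutoffs for a
requested FDR level are uniform — independent of oligonucleotide length —
which is what the length-debiased S_p score is designed to permit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FDRTable",
    "simple_fdr",
    "sp_cutoff_for_fdr",
    "fdr_table",
    "ppm_offset_stats",
    "OffsetStats",
]


def _rank1(osms: pd.DataFrame, competing_decoy_only: bool = False) -> pd.DataFrame:
    out = osms[osms["rank"] == 1] if "rank" in osms.columns else osms
    if competing_decoy_only and "delta_spd" in out.columns:
        out = out[out["is_decoy"] | out["delta_spd"].notna()]
    return out


def simple_fdr(rank1: pd.DataFrame, sp_cutoff: float) -> float:
    """Decoy/target count ratio among rank-1 OSMs with S_p >= cutoff.

    Returns NaN (not applicable) when no target survives the cutoff.
    """
    above = rank1[rank1["sp"] >= sp_cutoff]
    targets = int((~above["is_decoy"]).sum())
    decoys = int(above["is_decoy"].sum())
    if targets == 0:
        return float("nan")
    return decoys / targets


def fdr_table(rank1: pd.DataFrame) -> pd.DataFrame:
    """FDR evaluated at every observed rank-1 score, sorted descending.

    Columns: sp (candidate cutoff), targets, decoys, fdr — with targets and
    decoys the cumulative counts at score >= sp.
    """
    if rank1.empty:
        raise ValueError("no rank-1 OSMs")
    df = rank1.sort_values("sp", ascending=False, kind="stable")
    targets = np.cumsum(~df["is_decoy"].to_numpy())
    decoys = np.cumsum(df["is_decoy"].to_numpy())
    out = pd.DataFrame(
        dict(sp=df["sp"].to_numpy(), targets=targets, decoys=decoys)
    )
    # at a cutoff equal to a tied score, all tied rows are included
    out = out.groupby("sp", as_index=False).last().sort_values("sp", ascending=False)
    out["fdr"] = np.where(out["targets"] > 0, out["decoys"] / out["targets"], np.nan)
    return out.reset_index(drop=True)


FDRTable = pd.DataFrame  # alias documenting the fdr_table return contract


def sp_cutoff_for_fdr(rank1: pd.DataFrame, target_fdr: float) -> float:
    """Minimal uniform S_p cutoff whose simple FDR is <= ``target_fdr``.

    Returns +inf (with a warning) when no cutoff achieves the requested level.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    table = fdr_table(rank1)
    ok = table[table["fdr"].notna() & (table["fdr"] <= target_fdr)]
    if ok.empty:
        warnings.warn(f"FDR <= {target_fdr} unreachable; returning +inf cutoff")
        return float("inf")
    return float(ok["sp"].min())


@dataclass
class OffsetStats:
    """Summary of signed ppm matching offsets at one MS level."""

    mean: float
    sigma: float
    n: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def two_sigma(self) -> float:
        """The ~2-sigma accuracy heuristic used to pick SeqX thresholds."""
        return 2.0 * self.sigma


def ppm_offset_stats(
    offsets_ppm: np.ndarray | list[float],
    bins: int = 40,
    robust: bool = False,
) -> OffsetStats:
    """Mean/σ and histogram of signed m/z matching offsets in ppm.

    The returned mean is the global offset correction that re-centers the
    distribution at zero.  ``robust`` swaps σ for the scaled median absolute
    deviation (1.4826 × MAD).
    """
    arr = np.asarray(offsets_ppm, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no matched ions: offset statistics undefined")
    mean = float(arr.mean())
    if robust:
        sigma = float(1.4826 * np.median(np.abs(arr - np.median(arr))))
    else:
        sigma = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    counts, edges = np.histogram(arr, bins=bins)
    return OffsetStats(mean=mean, sigma=sigma, n=int(arr.size), hist_counts=counts, hist_edges=edges)
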