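"""Ground-truth MS/MS dataset synthesis from a theoretical library.

Spectra are drawn from *target* library entries: the precursor peak, each
theoretical fragment ion detected with a Bernoulli probability, log-normal
peak intensities, Gaussian ppm jitter on every m/z, and uniform-m/z noise
peaks.  The generator emulates peak-picked negative-mode CID spectra well
enough to exercise matching, scoring and FDR control end to end; it makes no
attempt at chromatography, isotope envelopes or fragmentation propensities,
so recovery rates on synthetic data bound only the bookkeeping, not real
instrument performance.

Everything is driven by one seeded generator: a fixed seed yields a
byte-identical mgf file and truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import LibraryEntry
from .search import Spectrum

__all__ = ["SimParams", "synthesize_spectrum", "synthesize_dataset", "write_mgf"]


@dataclass
class SimParams:
    """Knobs of the spectrum simulator.

    detection_p: per-fragment Bernoulli detection probability.
    intensity_mu/sigma: log-normal intensity model (natural-log scale).
    noise_peaks: count of uniform-m/z noise peaks per spectrum.
    noise_mz: (low, high) m/z range for noise peaks.
    ms1_jitter_ppm / ms2_jitter_ppm: Gaussian measurement error sigmas.
    isotopologue_p: probability the recorded precursor sits on the M+1 or
        M-1 isotopologue instead of the monoisotopic peak.
    """

    detection_p: float = 0.9
    intensity_mu: float = 9.0
    intensity_sigma: float = 1.0
    noise_peaks: int = 10
    noise_mz: tuple[float, float] = (200.0, 2000.0)
    ms1_jitter_ppm: float = 3.0
    ms2_jitter_ppm: float = 8.0
    isotopologue_p: float = 0.0

    def __post_init__(self):
        if not 0 <= self.detection_p <= 1 or not 0 <= self.isotopologue_p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.intensity_sigma < 0 or self.ms1_jitter_ppm < 0 or self.ms2_jitter_ppm < 0:
            raise ValueError("sigmas must be >= 0")


def _jitter(mz: float, ppm_sigma: float, rng: np.random.Generator) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6) if ppm_sigma > 0 else mz


def synthesize_spectrum(
    entry: LibraryEntry,
    params: SimParams,
    rng: np.random.Generator,
    scan_id: str = "scan=1",
) -> Spectrum:
    """One synthetic scan for a library entry (highest tabulated charge)."""
    if not entry.fragments:
        raise ValueError("entry has no fragments to synthesize from")
    charge = max(entry.precursor_mz)
    precursor = entry.precursor_mz[charge]
    from .chem import NEUTRON_DELTA

    recorded = precursor
    if params.isotopologue_p > 0 and rng.random() < params.isotopologue_p:
        recorded += rng.choice((-1.0, 1.0)) * NEUTRON_DELTA / charge
    recorded = _jitter(recorded, params.ms1_jitter_ppm, rng)

    mzs: list[float] = [_jitter(precursor, params.ms2_jitter_ppm, rng)]
    intens: list[float] = [float(rng.lognormal(params.intensity_mu, params.intensity_sigma))]
    for ion in entry.fragments:
        if rng.random() < params.detection_p:
            mzs.append(_jitter(ion.mz, params.ms2_jitter_ppm, rng))
            intens.append(float(rng.lognormal(params.intensity_mu, params.intensity_sigma)))
    for _ in range(params.noise_peaks):
        mzs.append(float(rng.uniform(*params.noise_mz)))
        intens.append(float(rng.lognormal(params.intensity_mu - 2.0, params.intensity_sigma)))

    return Spectrum(
        scan_id=scan_id,
        precursor_mz=recorded,
        charge=charge,
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def synthesize_dataset(
    library: Sequence[LibraryEntry],
    n_spectra: int,
    params: SimParams,
    seed: int = 0,
    mgf_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Draw ``n_spectra`` scans from target entries, with a truth table.

    Decoy entries are never sampled.  Returns the spectra and a DataFrame
    (scan, sequence, channel); both are optionally written to disk (mgf and
    TSV).
    """
    targets = [e for e in library if not e.is_decoy and e.fragments]
    if not targets:
        raise ValueError("library contains no fragment-bearing target entries")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(targets), size=n_spectra)
    spectra, truth = [], []
    for i, pick in enumerate(picks, start=1):
        entry = targets[int(pick)]
        scan_id = f"synthetic.scan={i}"
        spectra.append(synthesize_spectrum(entry, params, rng, scan_id))
        truth.append(
            dict(scan=scan_id, sequence=entry.sequence, channel=entry.oligo.scheme.channel)
        )
    truth_df = pd.DataFrame(truth)
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if truth_path is not None:
        truth_df.to_csv(truth_path, sep="\t", index=False)
    return spectra, truth_df


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Standard-dialect mgf writer; negative charges carry a trailing '-'."""
    lines = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.scan_id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        lines.append(f"CHARGE={s.charge}-")
        if s.retention_time is not None:
            lines.append(f"RTINSECONDS={s.retention_time:.2f}")
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.6f} {inten:.2f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + "\n")
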