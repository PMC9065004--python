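"""Target-decoy theoretical MS/MS library construction.

Oligos from the in silico digest are expanded into precursor m/z values per
charge and per-series fragment-ion lists following the McLuckey CID
nomenclature (a / a-B / b / c / d on the 5' side; w / x / y / z on the 3'
side, plus the y-P / z-P phosphate-loss variants for 3'-phosphate oligos).
Shuffled decoys (3'-terminal residue fixed) are appended, and SeqX
consolidation merges entries that cannot be told apart at the configured
instrument accuracy.

Fragment neutral masses use an additive offset table anchored at the d
series (prefix chain with its 3'-phosphate):

    d_i   = sum(residues 1..i) + H2O + 5'-terminus adjustment
    c_i   = d_i - H2O          b_i = d_i - HPO3        a_i = b_i - H2O
    a-B_i = a_i - neutral base of residue i
    y_j   = sum(last j residues) + H2O + 3'-terminus adjustment
    w_j   = y_j + HPO3         x_j = w_j - H2O         z_j = y_j - H2O

so the complementary pairs a+w, b+x, c+y, d+z each reconstruct the neutral
precursor mass exactly — the invariant the test suite uses as the primary
correctness oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import (
    HPO3,
    WATER,
    Alphabet,
    LabelingScheme,
    Oligo,
    default_alphabet,
    five_prime_adjustment,
    mz_from_mass,
    residue_monoisotopic_mass,
    three_prime_adjustment,
)
from .digestion import (
    EnzymeSpec,
    NucleolyticFragment,
    apply_modifications,
    digest,
    enumerate_variants,
)

__all__ = [
    "FragmentIon",
    "LibraryEntry",
    "ChargeTable",
    "SERIES_3P",
    "SERIES_OTHER",
    "fragment_series",
    "precursor_losses",
    "generate_decoy",
    "seqx_consolidate",
    "build_library",
    "write_library",
    "read_library",
    "library_frame",
]

SERIES_3P = ("a", "a-B", "b", "c", "d", "w", "x", "y", "z", "y-P", "z-P")
SERIES_OTHER = ("a", "a-B", "b", "c", "d", "w", "x", "y", "z")


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int  # 1..n-1, counted from the series' own terminus
    charge: int
    mz: float
    neutral_mass: float


@dataclass
class ChargeTable:
    """Allowed charge states keyed by chain length ranges (inclusive)."""

    rows: tuple[tuple[int, int, tuple[int, ...]], ...]

    def charges_for(self, length: int) -> tuple[int, ...]:
        for lo, hi, charges in self.rows:
            if lo <= length <= hi:
                return charges
        return (1,)

    @classmethod
    def default_precursor(cls) -> "ChargeTable":
        return cls(((1, 3, (1,)), (4, 7, (1, 2)), (8, 10_000, (1, 2, 3))))

    @classmethod
    def default_fragment(cls) -> "ChargeTable":
        return cls(((1, 3, (1,)), (4, 10_000, (1, 2))))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["min_length\tmax_length\tcharges"]
        for lo, hi, charges in self.rows:
            lines.append(f"{lo}\t{hi}\t{','.join(map(str, charges))}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChargeTable":
        rows = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            lo, hi, charges = line.split("\t")
            parsed = tuple(int(c) for c in charges.split(","))
            if any(c < 1 for c in parsed):
                raise ValueError("charges must be >= 1")
            rows.append((int(lo), int(hi), parsed))
        return cls(tuple(rows))


@dataclass
class LibraryEntry:
    """One searchable library member: an Oligo with its theoretical spectrum."""

    oligo: Oligo
    is_decoy: bool = False
    decoy_of: str = ""  # target sequence a decoy was shuffled from
    precursor_mz: dict[int, float] = field(default_factory=dict)
    neutral_mass: float = 0.0
    fragments: list[FragmentIon] = field(default_factory=list)
    consolidated_name: str = ""  # SeqX name when merged, e.g. "AXG: ACG|AYG"

    @property
    def sequence(self) -> str:
        return self.oligo.sequence

    @property
    def name(self) -> str:
        return self.consolidated_name or self.oligo.sequence

    @property
    def L(self) -> int:
        return len(self.fragments)


def _residue_masses(oligo: Oligo, alphabet: Alphabet) -> list[float]:
    return [residue_monoisotopic_mass(c, oligo.scheme, alphabet) for c in oligo.sequence]


def fragment_series(
    oligo: Oligo,
    charges: ChargeTable | None = None,
    series_set: Sequence[str] | None = None,
    alphabet: Alphabet | None = None,
) -> list[FragmentIon]:
    """Theoretical sequence-defining fragment ions for one oligonucleotide.

    Eleven series are emitted by default for 3'-P oligos, nine for 3'-OH and
    3'-cP (the phosphate-loss series y-P/z-P only exist with a 3'-terminal
    phosphate; requesting them otherwise drops them with a warning).
    """
    n = len(oligo)
    if n < 2:
        raise ValueError("fragment ions require an oligo of length >= 2")
    alphabet = alphabet if alphabet is not None else default_alphabet()
    charges = charges or ChargeTable.default_fragment()
    default_set = SERIES_3P if oligo.three_prime == "P" else SERIES_OTHER
    requested = tuple(series_set) if series_set is not None else default_set
    if oligo.three_prime != "P" and any(s in ("y-P", "z-P") for s in requested):
        warnings.warn(
            f"y-P/z-P series skipped for 3'-{oligo.three_prime} oligo {oligo.sequence}"
        )
        requested = tuple(s for s in requested if s not in ("y-P", "z-P"))

    res = _residue_masses(oligo, alphabet)
    bases = [
        oligo.scheme.apply(alphabet[c].base_formula, c).mass for c in oligo.sequence
    ]
    five_adj = five_prime_adjustment(oligo.five_prime)
    three_adj = three_prime_adjustment(oligo.three_prime)

    neutral: dict[tuple[str, int], float] = {}
    prefix = 0.0
    for i in range(1, n):
        prefix += res[i - 1]
        d = prefix + WATER + five_adj
        b = d - HPO3
        a = b - WATER
        neutral[("d", i)] = d
        neutral[("c", i)] = d - WATER
        neutral[("b", i)] = b
        neutral[("a", i)] = a
        neutral[("a-B", i)] = a - bases[i - 1]
    suffix = 0.0
    for j in range(1, n):
        suffix += res[n - j]
        y = suffix + WATER + three_adj
        w = y + HPO3
        neutral[("y", j)] = y
        neutral[("w", j)] = w
        neutral[("x", j)] = w - WATER
        neutral[("z", j)] = y - WATER
        if oligo.three_prime == "P":
            neutral[("y-P", j)] = y - HPO3
            neutral[("z-P", j)] = y - WATER - HPO3

    out = []
    for series in requested:
        for i in range(1, n):
            m = neutral[(series, i)]
            for z in charges.charges_for(i):
                out.append(FragmentIon(series, i, z, mz_from_mass(m, z), m))
    return out


def precursor_losses(
    oligo: Oligo,
    charges: Iterable[int] = (1,),
    alphabet: Alphabet | None = None,
) -> list[FragmentIon]:
    """Precursor ion and its neutral-loss companions (water, phosphate, bases).

    These are annotation/exclusion ions: they are identified in a spectrum so
    that their intensity can be excluded from scoring, and never count toward
    the matched-ion tally n or the candidate count L.
    """
    alphabet = alphabet if alphabet is not None else default_alphabet()
    from .chem import oligo_neutral_mass

    M = oligo_neutral_mass(oligo, alphabet)
    losses: list[tuple[str, float]] = [("M", M), ("M-H2O", M - WATER), ("M-HPO3", M - HPO3)]
    seen_bases: dict[str, float] = {}
    for c in oligo.sequence:
        base_class = alphabet[c].base_class or c
        key = f"M-{base_class}base" if not alphabet[c].modified else f"M-{alphabet[c].display}base"
        mass = oligo.scheme.apply(alphabet[c].base_formula, c).mass
        seen_bases.setdefault(key, mass)
    for key, bmass in seen_bases.items():
        losses.append((key, M - bmass))
    out = []
    for label, m in losses:
        for z in charges:
            out.append(FragmentIon(label, 0, z, mz_from_mass(m, z), m))
    return out


def generate_decoy(target: Oligo, rng: np.random.Generator) -> Oligo | None:
    """Shuffled decoy: permute all residues except the fixed 3'-terminal one.

    Returns None when no distinct permutation exists (homopolymeric prefix).
    Deterministic for a given generator state.
    """
    n = len(target)
    if n < 2:
        return None
    prefix = list(target.sequence[:-1])
    if len(set(prefix)) < 2:
        return None
    for _ in range(200):
        shuffled = "".join(rng.permutation(prefix)) + target.sequence[-1]
        if shuffled != target.sequence:
            return replace(target, sequence=shuffled)
    return None  # pragma: no cover - unreachable for >=2 distinct residues


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / min(a, b) * 1e6


def _indistinguishable(e1: LibraryEntry, e2: LibraryEntry, ms1_ppm: float, ms2_ppm: float) -> bool:
    if len(e1.sequence) != len(e2.sequence):
        return False
    if set(e1.precursor_mz) != set(e2.precursor_mz):
        return False
    for z, mz in e1.precursor_mz.items():
        if _ppm(mz, e2.precursor_mz[z]) > ms1_ppm:
            return False
    f1 = {(f.series, f.index, f.charge): f.mz for f in e1.fragments}
    f2 = {(f.series, f.index, f.charge): f.mz for f in e2.fragments}
    if set(f1) != set(f2):
        return False
    return all(_ppm(mz, f2[key]) <= ms2_ppm for key, mz in f1.items())


def seqx_consolidate(
    entries: list[LibraryEntry], ms1_ppm: float, ms2_ppm: float
) -> list[LibraryEntry]:
    """Merge m/z-indistinguishable same-length entries under an X-placeholder name.

    Targets are grouped by transitive closure (union-find) of the pairwise
    indistinguishability relation, so the result is independent of input
    order; each member keeps its own masses but is renamed
    ``"AXG: <own>|<other>..."`` with X at the differing positions.  Decoys are
    consolidated among themselves the same way, and any decoy
    indistinguishable from a target is removed.  The operation is idempotent.
    """
    if ms1_ppm <= 0 or ms2_ppm <= 0:
        raise ValueError("ppm tolerances must be positive")
    targets = [e for e in entries if not e.is_decoy]
    decoys = [e for e in entries if e.is_decoy]

    drop = set()
    for d in decoys:
        if any(_indistinguishable(d, t, ms1_ppm, ms2_ppm) for t in targets):
            drop.add(id(d))
    decoys = [d for d in decoys if id(d) not in drop]

    def group(pool: list[LibraryEntry]) -> None:
        parent = list(range(len(pool)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        order = sorted(range(len(pool)), key=lambda i: pool[i].neutral_mass)
        for a_pos, i in enumerate(order):
            for j in order[a_pos + 1 :]:
                if _ppm(pool[i].neutral_mass, pool[j].neutral_mass) > ms1_ppm:
                    break
                if _indistinguishable(pool[i], pool[j], ms1_ppm, ms2_ppm):
                    parent[find(i)] = find(j)
        groups: dict[int, list[LibraryEntry]] = {}
        for i, e in enumerate(pool):
            groups.setdefault(find(i), []).append(e)
        for members in groups.values():
            if len(members) == 1:
                members[0].consolidated_name = ""
                continue
            seqs = sorted({m.sequence for m in members})
            pattern = "".join(
                seqs[0][k] if len({s[k] for s in seqs}) == 1 else "X"
                for k in range(len(seqs[0]))
            )
            for m in members:
                others = [s for s in seqs if s != m.sequence]
                m.consolidated_name = f"{pattern}: {'|'.join([m.sequence] + others)}"

    group(targets)
    group(decoys)
    return targets + decoys


def _make_entry(
    oligo: Oligo,
    precursor_charges: ChargeTable,
    fragment_charges: ChargeTable,
    alphabet: Alphabet,
    is_decoy: bool = False,
    decoy_of: str = "",
) -> LibraryEntry:
    from .chem import oligo_neutral_mass

    M = oligo_neutral_mass(oligo, alphabet)
    mzs = {z: mz_from_mass(M, z) for z in precursor_charges.charges_for(len(oligo))}
    frags = fragment_series(oligo, fragment_charges, alphabet=alphabet) if len(oligo) >= 2 else []
    return LibraryEntry(
        oligo=oligo,
        is_decoy=is_decoy,
        decoy_of=decoy_of,
        precursor_mz=mzs,
        neutral_mass=M,
        fragments=frags,
    )


def build_library(
    sequences: dict[str, str],
    mod_table: dict[str, list[tuple[int, str]]] | None = None,
    enzyme: EnzymeSpec | None = None,
    max_missed: int = 0,
    termini: Sequence[tuple[str, str]] = (("OH", "P"),),
    schemes: Sequence[LabelingScheme] = (LabelingScheme(),),
    precursor_charges: ChargeTable | None = None,
    fragment_charges: ChargeTable | None = None,
    add_decoys: bool = True,
    seed: int = 0,
    seqx: tuple[float, float] | None = None,
    min_length: int = 2,
    max_length: int | None = None,
    alphabet: Alphabet | None = None,
) -> list[LibraryEntry]:
    """Digest -> terminus/label variants -> fragments -> decoys -> SeqX.

    Deterministic for a given ``seed``.  ``seqx`` is an optional
    (ms1_ppm, ms2_ppm) pair activating consolidation.  Oligos shorter than
    ``min_length`` (default 2) are dropped since they carry no
    sequence-defining fragments.
    """
    from .digestion import builtin_enzyme

    alphabet = alphabet if alphabet is not None else default_alphabet()
    enzyme = enzyme or builtin_enzyme("T1")
    precursor_charges = precursor_charges or ChargeTable.default_precursor()
    fragment_charges = fragment_charges or ChargeTable.default_fragment()
    if not sequences:
        warnings.warn("empty sequence input: returning an empty library")
        return []

    oligos: list[Oligo] = []
    for seq_id, seq in sequences.items():
        modified = apply_modifications(seq, (mod_table or {}).get(seq_id, ()), alphabet)
        for frag in digest(
            modified, enzyme, max_missed, seq_id, min_length=min_length, max_length=max_length
        ):
            oligos.extend(enumerate_variants(frag, termini, schemes))

    entries = [
        _make_entry(o, precursor_charges, fragment_charges, alphabet) for o in oligos
    ]

    if add_decoys:
        rng = np.random.default_rng(seed)
        target_keys = {
            (e.sequence, e.oligo.five_prime, e.oligo.three_prime, e.oligo.scheme.name)
            for e in entries
        }
        seen = set()
        decoy_entries = []
        for e in entries:
            d = generate_decoy(e.oligo, rng)
            if d is None:
                continue
            key = (d.sequence, d.five_prime, d.three_prime, d.scheme.name)
            if key in seen or key in target_keys:
                continue
            seen.add(key)
            decoy_entries.append(
                _make_entry(
                    d, precursor_charges, fragment_charges, alphabet,
                    is_decoy=True, decoy_of=e.sequence,
                )
            )
        entries.extend(decoy_entries)

    if seqx is not None:
        entries = seqx_consolidate(entries, *seqx)
    return entries


# ---------------------------------------------------------------------------
# serialization: fragment rows as TSV, entry metadata as a JSON sidecar


def library_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    """One row per fragment ion, indexed by a per-entry integer id."""
    rows = []
    for eid, e in enumerate(entries):
        for f in e.fragments:
            rows.append(
                dict(
                    entry_id=eid, name=e.name, sequence=e.sequence,
                    is_decoy=e.is_decoy, channel=e.oligo.scheme.channel,
                    series=f.series, index=f.index, charge=f.charge,
                    mz=f.mz, neutral_mass=f.neutral_mass,
                )
            )
    return pd.DataFrame(rows)


def _scheme_to_dict(s: LabelingScheme) -> dict:
    return dict(
        name=s.name, channel=s.channel,
        element_rules=[list(r) for r in s.element_rules],
        residue_rules=[list(r) for r in s.residue_rules],
    )


def _scheme_from_dict(d: dict) -> LabelingScheme:
    return LabelingScheme(
        d["name"], d["channel"],
        tuple(tuple(r) for r in d["element_rules"]),
        tuple(tuple(r) for r in d["residue_rules"]),
    )


def write_library(entries: list[LibraryEntry], tsv_path: str | Path, json_path: str | Path) -> None:
    library_frame(entries).to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    meta = []
    for e in entries:
        o = e.oligo
        meta.append(
            dict(
                sequence=o.sequence, five_prime=o.five_prime, three_prime=o.three_prime,
                scheme=_scheme_to_dict(o.scheme), source_id=o.source_id,
                start=o.start, end=o.end, missed_cleavages=o.missed_cleavages,
                is_decoy=e.is_decoy, decoy_of=e.decoy_of,
                precursor_mz={str(z): mz for z, mz in e.precursor_mz.items()},
                neutral_mass=e.neutral_mass, consolidated_name=e.consolidated_name,
            )
        )
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_library(tsv_path: str | Path, json_path: str | Path) -> list[LibraryEntry]:
    meta = json.loads(Path(json_path).read_text())
    frame = pd.read_csv(tsv_path, sep="\t")
    entries = []
    for eid, m in enumerate(meta):
        oligo = Oligo(
            sequence=m["sequence"], five_prime=m["five_prime"], three_prime=m["three_prime"],
            scheme=_scheme_from_dict(m["scheme"]), source_id=m["source_id"],
            start=m["start"], end=m["end"], missed_cleavages=m["missed_cleavages"],
        )
        sub = frame[frame.entry_id == eid]
        frags = [
            FragmentIon(
                r["series"], int(r["index"]), int(r["charge"]),
                float(r["mz"]), float(r["neutral_mass"]),
            )
            for r in sub.to_dict("records")
        ]
        entries.append(
            LibraryEntry(
                oligo=oligo, is_decoy=bool(m["is_decoy"]), decoy_of=m["decoy_of"],
                precursor_mz={int(z): mz for z, mz in m["precursor_mz"].items()},
                neutral_mass=m["neutral_mass"], fragments=frags,
                consolidated_name=m["consolidated_name"],
            )
        )
    return entries
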