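"""In silico endonuclease digestion of RNA sequences.

Cleavage is modeled as a cut of the phosphodiester backbone 3' of a residue in
the enzyme's specificity set, leaving a 3'-linear-phosphate on the upstream
product and a 5'-OH on the downstream product.  The parent's own 3' terminus
chemistry is inherited by the 3'-terminal fragment.  Coordinates are 1-based
inclusive throughout, matching the residue numbering used in modification
reports (e.g. "967-[m5C]AACG-971").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .chem import Alphabet, LabelingScheme, Oligo, default_alphabet

__all__ = [
    "EnzymeSpec",
    "NucleolyticFragment",
    "builtin_enzyme",
    "digest",
    "apply_modifications",
    "enumerate_variants",
    "read_fasta",
    "read_modification_table",
]


class ConfigError(ValueError):
    """Unknown enzyme or malformed digestion configuration."""


@dataclass(frozen=True)
class EnzymeSpec:
    """Endonuclease cleavage rule: cut 3' of any residue in ``cleaves_after``.

    ``nonspecific`` enumerates every substring within the configured length
    bounds; ``none`` leaves the parent intact.
    """

    name: str
    cleaves_after: frozenset[str] = frozenset()
    nonspecific: bool = False

    def __post_init__(self):
        if not self.nonspecific and self.name != "none" and not self.cleaves_after:
            raise ConfigError(f"enzyme {self.name!r} has an empty cleavage set")


# Built-in specificities.  T1 and A follow the canonical rules (T1 cuts 3' of
# G; A cuts 3' of pyrimidines, including pseudouridine isomers and
# N1-methyl-pseudouridine).  2'-O-methylated residues are excluded because
# both transesterification mechanisms require a free 2'-OH.  The plant/fungal
# nucleases ship as editable defaults drawn from common literature usage and
# can be overridden via enzyme_from_config.
_BUILTINS: dict[str, frozenset[str]] = {
    "T1": frozenset("G7"),
    "A": frozenset("CUYD135"),
    "Cusativin": frozenset("C"),
    "MC1": frozenset("UY"),
    "MAZ": frozenset("A"),
}


def builtin_enzyme(name: str) -> EnzymeSpec:
    if name == "nonspecific":
        return EnzymeSpec("nonspecific", nonspecific=True)
    if name == "none":
        return EnzymeSpec("none")
    try:
        return EnzymeSpec(name, _BUILTINS[name])
    except KeyError:
        raise ConfigError(f"unknown enzyme {name!r}") from None


def enzyme_from_config(path: str | Path) -> EnzymeSpec:
    """Load a user-defined enzyme from YAML: ``{name: ..., cleaves_after: [..]}``."""
    cfg = yaml.safe_load(Path(path).read_text())
    return EnzymeSpec(cfg["name"], frozenset(cfg.get("cleaves_after", ())),
                      bool(cfg.get("nonspecific", False)))


@dataclass(frozen=True)
class NucleolyticFragment:
    """A positioned digestion product (modifications already substituted)."""

    source_id: str
    sequence: str
    start: int  # 1-based inclusive
    end: int
    missed_cleavages: int = 0
    is_five_terminal: bool = False
    is_three_terminal: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("fragment end precedes start")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates do not match sequence length")


def apply_modifications(
    parent: str, mod_table: Iterable[tuple[int, str]], alphabet: Alphabet | None = None
) -> str:
    """Substitute modification codes at 1-based positions of a parent sequence.

    Substituting the code already present is a no-op, so the operation is
    idempotent.
    """
    alphabet = alphabet if alphabet is not None else default_alphabet()
    seq = list(parent)
    for pos, code in mod_table:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"modification position {pos} outside 1..{len(seq)}")
        alphabet[code]  # raises AlphabetError on unknown code
        seq[pos - 1] = code
    return "".join(seq)


def digest(
    sequence: str,
    enzyme: EnzymeSpec,
    max_missed: int = 0,
    source_id: str = "",
    min_length: int = 1,
    max_length: int | None = None,
) -> list[NucleolyticFragment]:
    """Exhaustive in silico digestion with up to ``max_missed`` missed cleavages.

    Returns fragments in 5'->3' order of their start position.  For the
    nonspecific enzyme every substring within the length bounds is emitted
    (missed-cleavage counting does not apply); length bounds keep that library
    finite.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    if enzyme.nonspecific:
        cap = max_length if max_length is not None else n
        out = []
        for i in range(n):
            for j in range(i + min_length, min(n, i + cap) + 1):
                out.append(
                    NucleolyticFragment(
                        source_id, sequence[i:j], i + 1, j,
                        is_five_terminal=(i == 0), is_three_terminal=(j == n),
                    )
                )
        return out

    # cut sites: after position i (1-based) when residue i is in the set
    if enzyme.name == "none":
        sites: list[int] = []
    else:
        sites = [i + 1 for i in range(n - 1) if sequence[i] in enzyme.cleaves_after]
    bounds = [0] + sites + [n]  # 0-based slice boundaries
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(bounds))):
            i, j = bounds[a], bounds[b]
            frag = sequence[i:j]
            if len(frag) < min_length or (max_length is not None and len(frag) > max_length):
                continue
            out.append(
                NucleolyticFragment(
                    source_id, frag, i + 1, j,
                    missed_cleavages=b - a - 1,
                    is_five_terminal=(i == 0),
                    is_three_terminal=(j == n),
                )
            )
    out.sort(key=lambda f: (f.start, f.end))
    return out


def enumerate_variants(
    fragment: NucleolyticFragment,
    termini: Sequence[tuple[str, str]] = (("OH", "P"),),
    schemes: Sequence[LabelingScheme] = (LabelingScheme(),),
    parent_three_prime: str = "P",
    parent_five_prime: str = "OH",
) -> list[Oligo]:
    """Cartesian expansion of a fragment over terminus chemistries and labels.

    Internal cleavage products default to 5'-OH/3'-P chemistry; the parent
    molecule's own termini are applied to the chain-terminal fragments, which
    is why those fragments ignore the ``termini`` grid on the fixed side.
    """
    if not termini or not schemes:
        raise ValueError("termini and schemes must be non-empty")
    out = []
    seen = set()
    for (five, three), scheme in product(termini, schemes):
        if fragment.is_five_terminal:
            five = parent_five_prime
        if fragment.is_three_terminal:
            three = parent_three_prime
        key = (five, three, scheme.name)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            Oligo(
                sequence=fragment.sequence,
                five_prime=five,
                three_prime=three,
                scheme=scheme,
                source_id=fragment.source_id,
                start=fragment.start,
                end=fragment.end,
                missed_cleavages=fragment.missed_cleavages,
            )
        )
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: sequence}, uppercased T->U not applied (RNA input)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_modification_table(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Modification placement TSV: columns seq_id, position (1-based), code."""
    out: dict[str, list[tuple[int, str]]] = {}
    lines = Path(path).read_text().splitlines()
    start = 1 if lines and lines[0].lower().startswith(("seq_id", "#")) else 0
    for line in lines[start:]:
        if not line.strip():
            continue
        seq_id, pos, code = line.split("\t")[:3]
        out.setdefault(seq_id, []).append((int(pos), code))
    return out
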