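"""Monoisotopic mass engine for (modified, isotope-labeled) RNA oligonucleotides.

The chain convention used throughout the package: an *internal residue* is a
nucleoside-3'-monophosphate minus one water, so that the sum of residue masses
plus one water is the neutral mass of a 5'-OH/3'-linear-phosphate chain.  Other
terminus chemistries (5'-P, 3'-OH, 2',3'-cyclic phosphate) are additive
adjustments relative to that baseline.

Isotope labeling (e.g. uniform 15N, metabolic 5,6-2H-uracil feeding) is applied
as substitution rules on elemental formulas, never as per-residue magic
constants, so heavy/light mass differences are exactly the sum of per-atom
isotope deltas.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "WATER",
    "HPO3",
    "NEUTRON_DELTA",
    "Formula",
    "ResidueDef",
    "Alphabet",
    "LabelingScheme",
    "Oligo",
    "AlphabetError",
    "SchemeError",
    "default_alphabet",
    "builtin_scheme",
    "residue_monoisotopic_mass",
    "oligo_neutral_mass",
    "mz_from_mass",
    "formula_mass",
    "five_prime_adjustment",
    "three_prime_adjustment",
]


class AlphabetError(KeyError):
    """A residue code is not present in the active alphabet."""


class SchemeError(ValueError):
    """A labeling rule cannot be applied to a residue formula."""


# CODATA/NIST monoisotopic atomic masses (Da).  Isotope variants are keyed by
# mass-number-prefixed symbols and are first-class "elements" in a Formula.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Se": 79.9165213,
    "2H": 2.01410177785,
    "13C": 13.0033548378,
    "15N": 15.0001088982,
    "18O": 17.9991610,
    "34S": 33.96786690,
}

PROTON_MASS = 1.007276466  # deprotonation convention for negative-mode ESI
NEUTRON_DELTA = 1.00336  # C12->C13 spacing used for isotopologue matching

_FORMULA_TOKEN = re.compile(r"(?:\[(\d+[A-Z][a-z]?)\]|([A-Z][a-z]?))(\d*)")


class Formula(Counter):
    """Elemental composition: a Counter over element/isotope symbols.

    Accepts Hill-style strings such as ``"C9H12N3O7P"``; isotopes are written
    in brackets, e.g. ``"[15N]3C9H12O7P"``.
    """

    def __init__(self, source: str | Mapping[str, int] | None = None):
        super().__init__()
        if source is None:
            return
        if isinstance(source, str):
            self._parse(source)
        else:
            self.update(source)

    def _parse(self, text: str) -> None:
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            if not m.group(0):
                continue
            symbol = m.group(1) or m.group(2)
            key = symbol if symbol in ELEMENT_MASSES else symbol
            if key not in ELEMENT_MASSES:
                raise ValueError(f"unknown element {symbol!r} in formula {text!r}")
            self[key] += int(m.group(3)) if m.group(3) else 1
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")

    @property
    def mass(self) -> float:
        return sum(ELEMENT_MASSES[el] * n for el, n in self.items())

    def __add__(self, other: "Formula") -> "Formula":
        out = Formula(self)
        out.update(other)
        return out

    def to_string(self) -> str:
        parts = []
        for el in sorted(self, key=lambda e: (e.lstrip("0123456789"), e)):
            n = self[el]
            if n == 0:
                continue
            sym = f"[{el}]" if el[0].isdigit() else el
            parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)


def formula_mass(formula: str | Formula) -> float:
    """Monoisotopic mass of an elemental formula in Da."""
    if isinstance(formula, str):
        formula = Formula(formula)
    return formula.mass


WATER = formula_mass("H2O")
HPO3 = formula_mass("HPO3")


@dataclass(frozen=True)
class ResidueDef:
    """One residue of the alphabet.

    ``formula`` is the internal-residue composition (nucleoside-3'-phosphate
    minus water); ``base_formula`` is the neutral nucleobase, used for a-B
    fragment ions and precursor base losses.  ``code`` is a single
    case-sensitive letter or digit; ``display`` is the human-readable name
    (e.g. ``[m5C]``).
    """

    code: str
    display: str
    formula: Formula
    base_formula: Formula
    modified: bool = False
    base_class: str = ""  # canonical residue this one derives from, e.g. "C"

    def __post_init__(self):
        if len(self.code) != 1 or not self.code.isalnum():
            raise ValueError(f"residue code must be one alphanumeric char, got {self.code!r}")
        if any(n < 0 for n in self.formula.values()) or any(
            n < 0 for n in self.base_formula.values()
        ):
            raise ValueError(f"negative element count in residue {self.code!r}")


class Alphabet(dict):
    """Mapping of residue code -> ResidueDef with TSV round-trip support."""

    def add(self, residue: ResidueDef) -> None:
        if residue.code in self:
            raise ValueError(f"duplicate residue code {residue.code!r}")
        self[residue.code] = residue

    def __missing__(self, code):
        raise AlphabetError(f"unknown residue code {code!r}")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["code\tdisplay\tformula\tbase_formula\tmodified\tbase_class"]
        for r in self.values():
            lines.append(
                f"{r.code}\t{r.display}\t{r.formula.to_string()}\t"
                f"{r.base_formula.to_string()}\t{int(r.modified)}\t{r.base_class}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Alphabet":
        out = cls()
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            if not line.strip():
                continue
            row = dict(zip(header, line.split("\t")))
            out.add(
                ResidueDef(
                    code=row["code"],
                    display=row["display"],
                    formula=Formula(row["formula"]),
                    base_formula=Formula(row["base_formula"]),
                    modified=bool(int(row.get("modified", "0"))),
                    base_class=row.get("base_class", ""),
                )
            )
        return out


def default_alphabet() -> Alphabet:
    """Built-in residue alphabet.

    Canonical A/C/G/U plus a starter set of post-transcriptional modifications;
    lowercase letters denote the 2'-O-methylated form of the uppercase
    residue.  Users extend it through :meth:`Alphabet.from_tsv`; codes are
    single case-sensitive letters or digits, so well over 50 modifications can
    coexist in one digest.
    """
    ab = Alphabet()
    CH2 = Formula("CH2")
    defs = [
        ("A", "A", "C10H12N5O6P", "C5H5N5", False, "A"),
        ("C", "C", "C9H12N3O7P", "C4H5N3O", False, "C"),
        ("G", "G", "C10H12N5O7P", "C5H5N5O", False, "G"),
        ("U", "U", "C9H11N2O8P", "C4H4N2O2", False, "U"),
        # pseudouridine: C-C glycosidic isomer of U, identical composition
        ("Y", "[Y]", "C9H11N2O8P", "C4H4N2O2", True, "U"),
        ("D", "[D]", "C9H13N2O8P", "C4H6N2O2", True, "U"),  # dihydrouridine
        ("1", "[m1Y]", "C10H13N2O8P", "C5H6N2O2", True, "U"),  # N1-methyl-pseudouridine
        ("5", "[m5C]", "C10H14N3O7P", "C5H7N3O", True, "C"),
        ("7", "[m7G]", "C11H14N5O7P", "C6H7N5O", True, "G"),
        ("6", "[m6A]", "C11H14N5O6P", "C6H7N5", True, "A"),
        ("3", "[m3U]", "C10H13N2O8P", "C5H6N2O2", True, "U"),
        ("I", "[I]", "C10H11N4O7P", "C5H4N4O", True, "A"),  # inosine
    ]
    for code, disp, f, b, mod, cls in defs:
        ab.add(ResidueDef(code, disp, Formula(f), Formula(b), mod, cls))
    # 2'-O-methyl variants: +CH2 on the ribose, base unchanged
    for code, cls in [("a", "A"), ("c", "C"), ("g", "G"), ("u", "U")]:
        parent = ab[cls]
        ab.add(
            ResidueDef(
                code,
                f"[{cls}m]",
                parent.formula + CH2,
                Formula(parent.base_formula),
                True,
                cls,
            )
        )
    return ab


@dataclass(frozen=True)
class LabelingScheme:
    """Isotope substitution rules defining one label channel.

    ``element_rules`` substitutes every atom of an element in every residue
    (uniform metabolic labeling, e.g. ``{"N": "15N"}``).  ``residue_rules``
    substitutes a fixed number of atoms in specific residue codes
    (e.g. 5,6-2H-uracil feeding: two deuteriums retained on C and U, one on
    pseudouridine).  The identity scheme has no rules and changes no mass.
    """

    name: str = "unlabeled"
    channel: str = "light"
    element_rules: tuple[tuple[str, str], ...] = ()
    residue_rules: tuple[tuple[str, str, str, int], ...] = ()  # (code, elem, isotope, count)

    def apply(self, formula: Formula, code: str) -> Formula:
        out = Formula(formula)
        for elem, iso in self.element_rules:
            n = out.pop(elem, 0)
            if n:
                out[iso] += n
        for rcode, elem, iso, count in self.residue_rules:
            if rcode != code:
                continue
            if out.get(elem, 0) < count:
                raise SchemeError(
                    f"scheme {self.name!r}: residue {code!r} has fewer than "
                    f"{count} {elem} atoms to substitute"
                )
            out[elem] -= count
            out[iso] += count
        return out


# 5,6-2H-uracil metabolic labeling: pyrimidines are biosynthesized from the fed
# uracil.  C and U retain both ring deuteriums; pseudouridine exchanges the one
# at C5 during C-C glycosidic bond formation and retains a single deuterium.
# Purines are not derived from uracil and stay unlabeled.
_D_URACIL_RULES = (
    ("U", "H", "2H", 2),
    ("C", "H", "2H", 2),
    ("Y", "H", "2H", 1),
    ("D", "H", "2H", 2),
    ("5", "H", "2H", 2),
    ("3", "H", "2H", 2),
    ("c", "H", "2H", 2),
    ("u", "H", "2H", 2),
)

_BUILTIN_SCHEMES: dict[str, LabelingScheme] = {
    "unlabeled": LabelingScheme(),
    "15N": LabelingScheme("15N", "heavy", (("N", "15N"),)),
    "13C": LabelingScheme("13C", "heavy", (("C", "13C"),)),
    "D-uracil": LabelingScheme("D-uracil", "light", (), _D_URACIL_RULES),
    "D-uracil-15N": LabelingScheme("D-uracil-15N", "heavy", (("N", "15N"),), _D_URACIL_RULES),
}


def builtin_scheme(name: str) -> LabelingScheme:
    try:
        return _BUILTIN_SCHEMES[name]
    except KeyError:
        raise SchemeError(f"unknown labeling scheme {name!r}") from None


# Terminus adjustments relative to the 5'-OH / 3'-linear-phosphate baseline.
_FIVE_PRIME = {"OH": 0.0, "P": HPO3}
_THREE_PRIME = {"P": 0.0, "OH": -HPO3, "cP": -WATER}


def five_prime_adjustment(chem: str) -> float:
    try:
        return _FIVE_PRIME[chem]
    except KeyError:
        raise ValueError(f"unknown 5' terminus {chem!r}; expected OH or P") from None


def three_prime_adjustment(chem: str) -> float:
    try:
        return _THREE_PRIME[chem]
    except KeyError:
        raise ValueError(f"unknown 3' terminus {chem!r}; expected P, OH or cP") from None


@dataclass(frozen=True)
class Oligo:
    """A nucleolytic fragment ready for mass computation.

    ``sequence`` is the residue-code string with modifications already
    substituted; positions are 1-based inclusive on the parent.
    """

    sequence: str
    five_prime: str = "OH"
    three_prime: str = "P"
    scheme: LabelingScheme = field(default_factory=LabelingScheme)
    source_id: str = ""
    start: int = 0
    end: int = 0
    missed_cleavages: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def with_termini(self, five_prime: str, three_prime: str) -> "Oligo":
        return replace(self, five_prime=five_prime, three_prime=three_prime)


def residue_monoisotopic_mass(
    code: str,
    scheme: LabelingScheme | None = None,
    alphabet: Alphabet | None = None,
) -> float:
    """Neutral monoisotopic mass (Da) of one internal residue under a scheme.

    The internal residue includes its 3'-phosphate and excludes one water.
    """
    alphabet = alphabet if alphabet is not None else default_alphabet()
    scheme = scheme or LabelingScheme()
    residue = alphabet[code]
    return scheme.apply(residue.formula, code).mass


def oligo_neutral_mass(oligo: Oligo, alphabet: Alphabet | None = None) -> float:
    """Neutral monoisotopic mass of an oligonucleotide with its termini."""
    if not oligo.sequence:
        raise ValueError("empty oligonucleotide sequence")
    alphabet = alphabet if alphabet is not None else default_alphabet()
    total = sum(
        residue_monoisotopic_mass(code, oligo.scheme, alphabet) for code in oligo.sequence
    )
    return (
        total
        + WATER
        + five_prime_adjustment(oligo.five_prime)
        + three_prime_adjustment(oligo.three_prime)
    )


def mz_from_mass(neutral_mass: float, charge: int, polarity: str = "negative") -> float:
    """m/z of a deprotonated ion [M - zH]^z- in negative-mode ESI."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if polarity != "negative":
        raise ValueError("only negative-mode ESI is supported")
    return (neutral_mass - charge * PROTON_MASS) / charge
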