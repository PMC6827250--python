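"""Core domain types for alginate chains, monomers and mixtures.

Alginate is a linear 1->4-linked copolymer of beta-D-mannuronate (M) and its
C5 epimer alpha-L-guluronate (G).  Lyases cleave the glycosidic bond by
beta-elimination, which installs a 4,5-unsaturated ring (the "Delta unit",
written ``Δ``) at the *non-reducing* end of the fragment that keeps the
reducing end.  The elimination destroys the C5 stereocentre, so the M/G
identity of that ring is unrecoverable: unsaturated chains are therefore
written ``ΔX1..Xm`` where the letters cover only the identifiable residues,
and the degree of polymerisation (DP, the number of rings) of such a chain is
``m + 1``.

Notation grammar (non-reducing end leftmost)::

    [Δ|d]? [MG]+ (-2AB)?

``d`` is an ASCII alias for ``Δ``; the optional ``-2AB`` suffix marks a
reducing end derivatised with 2-aminobenzamide (a fluorescent label used to
track digestion directionality).  ``parse_sequence`` / ``format_sequence``
round-trip exactly on canonical strings.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "RESIDUE_CODES",
    "ParseError",
    "MixtureError",
    "GlycanChain",
    "Monomer",
    "Mixture",
    "parse_sequence",
    "format_sequence",
    "composition",
]

RESIDUE_CODES = ("M", "G")

#: canonical unicode symbol for the unsaturated terminal ring
DELTA = "Δ"

LABEL_FREE = "free"
LABEL_2AB = "2AB"
_2AB_SUFFIX = "-2AB"


class ParseError(ValueError):
    """Malformed sequence notation; reports the offending character."""

    def __init__(self, text: str, position: int, message: str):
        self.text = text
        self.position = position  # 0-based index into the original string
        super().__init__(
            f"cannot parse {text!r}: {message} at position {position} "
            f"(character {text[position]!r})"
            if 0 <= position < len(text)
            else f"cannot parse {text!r}: {message}"
        )


class MixtureError(ValueError):
    """Inconsistent mixture definition."""


@dataclass(frozen=True, order=True)
class GlycanChain:
    """One alginate chain, non-reducing end first.

    Parameters
    ----------
    residues
        Ordered identifiable residues (``"M"``/``"G"``).  For an unsaturated
        chain this excludes the Δ terminus, whose original identity is erased.
    unsaturated
        Whether the non-reducing end carries the 4,5-unsaturated Δ ring.
    label
        Reducing-end state: ``"free"`` or ``"2AB"`` (2-aminobenzamide).

    The Δ monomer released by exolytic cleavage is representable as an
    unsaturated chain with no residue letters (DP 1), although downstream
    bookkeeping normally uses :class:`Monomer` for released units.
    """

    residues: Tuple[str, ...]
    unsaturated: bool = False
    label: str = LABEL_FREE

    def __post_init__(self):
        if not isinstance(self.residues, tuple):
            object.__setattr__(self, "residues", tuple(self.residues))
        for r in self.residues:
            if r not in RESIDUE_CODES:
                raise ValueError(f"unknown residue code {r!r}; expected one of {RESIDUE_CODES}")
        if self.label not in (LABEL_FREE, LABEL_2AB):
            raise ValueError(f"unknown reducing-end label {self.label!r}")
        if self.dp < 1:
            raise ValueError("a chain must contain at least one ring")

    @property
    def dp(self) -> int:
        """Degree of polymerisation: number of rings including the Δ terminus."""
        return len(self.residues) + (1 if self.unsaturated else 0)

    @classmethod
    def parse(cls, text: str) -> "GlycanChain":
        return parse_sequence(text)

    def format(self, ascii: bool = False) -> str:
        return format_sequence(self, ascii=ascii)

    def __str__(self) -> str:  # canonical unicode notation
        return format_sequence(self)

    def composition(self) -> Dict[str, object]:
        return composition(self)


def parse_sequence(text: str) -> GlycanChain:
    """Parse notation ``[Δ|d]? [MG]+ (-2AB)?`` into a :class:`GlycanChain`.

    The leftmost symbol is the non-reducing end.  A lone ``Δ``/``d`` parses to
    the DP-1 unsaturated monomer chain.

    Raises
    ------
    ParseError
        Naming the offending character and its position.
    """
    if not isinstance(text, str):
        raise TypeError("sequence notation must be a string")
    s = text.strip()
    if not s:
        raise ParseError(text, 0, "empty sequence")
    label = LABEL_FREE
    core = s
    if s.endswith(_2AB_SUFFIX):
        label = LABEL_2AB
        core = s[: -len(_2AB_SUFFIX)]
        if not core:
            raise ParseError(text, 0, "label suffix without a chain")
    unsaturated = False
    i = 0
    if core[0] in (DELTA, "d"):
        unsaturated = True
        i = 1
    residues = []
    for j, ch in enumerate(core[i:], start=i):
        if ch not in RESIDUE_CODES:
            raise ParseError(text, j, "expected residue code 'M' or 'G'")
        residues.append(ch)
    if not residues and not unsaturated:
        raise ParseError(text, 0, "no residues")
    if not residues and label == LABEL_2AB:
        raise ParseError(text, 0, "a 2-AB label requires at least one residue")
    return GlycanChain(tuple(residues), unsaturated=unsaturated, label=label)


def format_sequence(chain: GlycanChain, ascii: bool = False) -> str:
    """Canonical notation for a chain; ``ascii=True`` uses ``d`` for ``Δ``."""
    prefix = ("d" if ascii else DELTA) if chain.unsaturated else ""
    suffix = _2AB_SUFFIX if chain.label == LABEL_2AB else ""
    return prefix + "".join(chain.residues) + suffix


def composition(chain: GlycanChain) -> Dict[str, object]:
    """Counts of M and G residues plus the Δ-terminus flag.

    The Δ ring is reported as a flag, not an M/G count, because its identity
    is erased by beta-elimination.  Used by residue-conservation checks.
    """
    return {
        "M": sum(1 for r in chain.residues if r == "M"),
        "G": sum(1 for r in chain.residues if r == "G"),
        "delta": chain.unsaturated,
    }


class Monomer(str, enum.Enum):
    """Released single rings.

    UDP1 is the unsaturated monomer freed by exolytic cleavage; in solution it
    opens non-enzymatically to DEH (4-deoxy-L-erythro-5-hexoseulose uronic
    acid) and then hydrates/cyclises to TPC.  The conversion order is
    UDP1 -> DEH -> TPC only.  SAT_M/SAT_G are saturated rings released from
    saturated chain ends.
    """

    UDP1 = "UDP1"
    DEH = "DEH"
    TPC = "TPC"
    SAT_M = "M"
    SAT_G = "G"

    @property
    def is_unsaturated_derived(self) -> bool:
        """True for the unsaturated-monomer pool (UDP1 and its conversion products)."""
        return self in (Monomer.UDP1, Monomer.DEH, Monomer.TPC)


_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Mixture:
    """Molar composition over distinct chains of one size class.

    All member chains must share DP, saturation state and reducing-end label;
    fractions are strictly positive and sum to 1 (within 1e-9).
    """

    entries: Mapping[GlycanChain, float]

    def __post_init__(self):
        entries = dict(self.entries)
        if not entries:
            raise MixtureError("mixture has no entries")
        chains = list(entries)
        dp0, unsat0, label0 = chains[0].dp, chains[0].unsaturated, chains[0].label
        for ch in chains[1:]:
            if (ch.dp, ch.unsaturated, ch.label) != (dp0, unsat0, label0):
                raise MixtureError(
                    "all chains in a mixture must share dp, saturation state and label; "
                    f"got {ch} vs {chains[0]}"
                )
        for ch, f in entries.items():
            if not (f > 0):
                raise MixtureError(f"fraction for {ch} must be > 0, got {f}")
        total = math.fsum(entries.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise MixtureError(f"fractions must sum to 1 within {_FRACTION_TOL}; got {total!r}")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_fractions(
        cls, fractions: Mapping[str, float], renormalize: bool = False
    ) -> "Mixture":
        """Build from ``{notation: fraction}``; optionally renormalize to 1."""
        parsed = {parse_sequence(seq): float(f) for seq, f in fractions.items()}
        if renormalize:
            total = math.fsum(parsed.values())
            if total <= 0:
                raise MixtureError("cannot renormalize non-positive total")
            parsed = {ch: f / total for ch, f in parsed.items()}
        return cls(parsed)

    @property
    def dp(self) -> int:
        return next(iter(self.entries)).dp

    @property
    def unsaturated(self) -> bool:
        return next(iter(self.entries)).unsaturated

    @property
    def label(self) -> str:
        return next(iter(self.entries)).label

    def items_sorted(self):
        """(chain, fraction) pairs, descending fraction then canonical order."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def as_str_dict(self) -> Dict[str, float]:
        return {str(ch): f for ch, f in self.items_sorted()}

    def fraction(self, seq: "str | GlycanChain") -> float:
        ch = parse_sequence(seq) if isinstance(seq, str) else seq
        return self.entries.get(ch, 0.0)
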