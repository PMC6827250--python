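"""Exact-mass and negative-mode m/z computation for uronate chains.

A glycosidically linked uronate residue contributes C6H8O6 (monoisotopic
176.0321 Da); a saturated chain additionally carries one water for its free
ends, while an unsaturated chain has lost that water through beta-elimination.
Deprotonation gives the [M-H]- ion observed in negative-mode ESI.  The ladder
of unsaturated oligomers is therefore spaced by exactly one residue mass, and
DP2..DP6 fall at nominal m/z 351, 527, 703, 879 and 1055.  The released
unsaturated monomer and its open-chain form DEH share C6H8O6 (nominal 175);
the cyclised hydrate TPC is C6H10O7 (nominal 193), indistinguishable by mass
from a free saturated uronic acid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

import pandas as pd

from .chains import GlycanChain, Monomer, parse_sequence

__all__ = ["MassConstants", "MassError", "MzValue", "mz_negative", "mass_report"]


class MassError(ValueError):
    """Species whose adduct mass is not modelled."""


@dataclass(frozen=True)
class MassConstants:
    """CODATA monoisotopic masses, Da."""

    residue: float = 176.03209  # C6H8O6, glycosidically linked uronate
    water: float = 18.0105646
    proton: float = 1.00727646


DEFAULT_CONSTANTS = MassConstants()


class MzValue(NamedTuple):
    monoisotopic: float
    nominal: int


def mz_negative(
    species: Union[GlycanChain, Monomer, str],
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> MzValue:
    """Monoisotopic [M-H]- m/z and its nominal integer for a chain or monomer.

    2-AB-labelled chains are rejected: the label is a fluorescent tag used for
    chromatographic detection and its adduct mass is not modelled here.
    """
    if isinstance(species, str) and not isinstance(species, Monomer):
        species = parse_sequence(species)
    if isinstance(species, GlycanChain):
        if species.label == "2AB":
            raise MassError("2-AB-labelled chains are not supported (label adduct mass not modelled)")
        n = species.dp
        neutral = n * constants.residue + (0.0 if species.unsaturated else constants.water)
    elif isinstance(species, Monomer):
        if species in (Monomer.UDP1, Monomer.DEH):
            neutral = constants.residue  # C6H8O6
        else:  # TPC and saturated M/G are all C6H10O7
            neutral = constants.residue + constants.water
    else:
        raise TypeError(f"cannot compute m/z for {type(species).__name__}")
    mono = neutral - constants.proton
    return MzValue(mono, round(mono))


def mass_report(
    species: Iterable[Union[GlycanChain, Monomer, str]],
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Tabulate [M-H]- masses: columns sequence, dp, mz_monoisotopic, mz_nominal."""
    rows = []
    for sp in species:
        if isinstance(sp, str) and not isinstance(sp, Monomer):
            sp = parse_sequence(sp)
        mz = mz_negative(sp, constants)
        if isinstance(sp, GlycanChain):
            name, dp = str(sp), sp.dp
        else:
            name, dp = sp.value, 1
        rows.append({"sequence": name, "dp": dp,
                     "mz_monoisotopic": mz.monoisotopic, "mz_nominal": mz.nominal})
    return pd.DataFrame(rows, columns=["sequence", "dp", "mz_monoisotopic", "mz_nominal"])
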