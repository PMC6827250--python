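"""Forward 1H NMR model: mixture -> integrated signal areas, and back.

Two observables identify the outermost positions of an unsaturated alginate
oligosaccharide:

* the H-4 proton of the Δ ring resonates at ~5.71/5.67 ppm when the residue
  *next to* the Δ unit is G and at ~5.61/5.56 ppm when it is M, so the
  integrated area ratio reads out the position-1 composition directly;
* the beta-anomeric proton of the reducing-end residue gives a doublet at
  4.71 ppm (3J_HH = 8.4 Hz) for G and a singlet in 4.70-4.80 ppm for M,
  reading out the reducing-end composition.

Quantification assumes exactly one H-4 proton per Δ terminus and one
beta-anomeric proton per reducing end, so areas are proportional to moles and
only area *ratios* are meaningful.  The model operates on pre-integrated
areas; peak fitting and baseline correction are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

from .chains import Mixture

__all__ = [
    "AssignmentTable",
    "NMRReadout",
    "NMRModelError",
    "forward_readout",
    "neighbor_marginal",
    "reducing_end_composition",
    "ratio_to_fractions",
]


class NMRModelError(ValueError):
    """Readout not interpretable (no signal, saturated sample, ...)."""


@dataclass(frozen=True)
class AssignmentTable:
    """Chemical-shift assignments (ppm) used to name the four areas.

    Documentation constants only: quantification uses areas, never shifts.
    The two alternative ΔG shifts (5.71 vs 5.67) belong to one analyte class.
    """

    h4_dG_ppm: Tuple[float, float] = (5.71, 5.67)
    h4_dM_ppm: Tuple[float, float] = (5.61, 5.56)
    re_G_ppm: float = 4.71
    re_G_j_hh_hz: float = 8.4
    re_M_ppm_range: Tuple[float, float] = (4.70, 4.80)


@dataclass(frozen=True)
class NMRReadout:
    """Four integrated signal areas (arbitrary units, non-negative).

    ``h4_dG``/``h4_dM``: H-4 Δ areas for a G/M neighbour of the Δ unit.
    ``re_G``/``re_M``: reducing-end beta-anomeric areas for G/M.
    """

    h4_dG: float
    h4_dM: float
    re_G: float
    re_M: float

    def __post_init__(self):
        for name in ("h4_dG", "h4_dM", "re_G", "re_M"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"signal area {name} must be non-negative, got {v}")

    def scaled(self, c: float) -> "NMRReadout":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return NMRReadout(self.h4_dG * c, self.h4_dM * c, self.re_G * c, self.re_M * c)


def forward_readout(mixture: Mixture) -> NMRReadout:
    """Predict signal areas for an unsaturated mixture (proportionality 1).

    area_h4_dG is the summed molar fraction of chains whose position-1 residue
    (the neighbour of the Δ unit) is G, and likewise for M; the reducing-end
    areas sum fractions by the identity of the last residue.  The map is
    linear in the mixture fractions.
    """
    if not mixture.unsaturated:
        raise NMRModelError("saturated mixture produces no H-4 Δ signal")
    if mixture.dp < 2:
        raise NMRModelError("forward model requires dp >= 2 (a Δ monomer has no neighbour)")
    h4_g = h4_m = re_g = re_m = 0.0
    for chain, frac in mixture.entries.items():
        if chain.residues[0] == "G":
            h4_g += frac
        else:
            h4_m += frac
        if chain.residues[-1] == "G":
            re_g += frac
        else:
            re_m += frac
    return NMRReadout(h4_g, h4_m, re_g, re_m)


def neighbor_marginal(readout: NMRReadout) -> float:
    """Fraction of G at the position adjacent to the Δ unit, in [0, 1]."""
    total = readout.h4_dG + readout.h4_dM
    if total <= 0:
        raise NMRModelError("both H-4 Δ areas are zero; neighbour marginal undefined")
    return readout.h4_dG / total


def reducing_end_composition(readout: NMRReadout) -> Tuple[float, float]:
    """Normalised (G fraction, M fraction) at the reducing end."""
    total = readout.re_G + readout.re_M
    if total <= 0:
        raise NMRModelError("both reducing-end areas are zero; composition undefined")
    return readout.re_G / total, readout.re_M / total


def ratio_to_fractions(ratio: Union[str, Sequence[float]]) -> Tuple[float, ...]:
    """Convert a molar ratio like ``"3.4:1.0"`` to rounded percentages.

    Rounding convention follows the product tables this mirrors: integer
    percentages for two-component ratios, one decimal for three or more.
    """
    if isinstance(ratio, str):
        parts = [p.strip() for p in ratio.split(":")]
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise NMRModelError(f"cannot parse ratio {ratio!r}") from exc
    else:
        values = [float(v) for v in ratio]
    if len(values) < 2:
        raise NMRModelError("a ratio needs at least two components")
    if any(v <= 0 for v in values):
        raise NMRModelError("ratio components must be positive")
    total = sum(values)
    pct = [100.0 * v / total for v in values]
    if len(values) == 2:
        return tuple(float(round(p)) for p in pct)
    return tuple(round(p, 1) for p in pct)
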