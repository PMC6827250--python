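"""Synthetic-data generators: block-structured chains, noisy readout series,
and gel-filtration-style peak tables.

These generators emulate the inputs the analysis pipeline consumes so that
every stage is testable without instrument data:

* ``generate_chains`` draws alginate chains from a first-order Markov model
  over {M, G}.  Stay probabilities control blockiness (mean block length is
  1/(1 - stay)); presets emulate polyM (>90 % M), polyG (>90 % G) and a mixed
  block copolymer.  First-order structure is the simplest model expressing
  M/G blockiness; higher-order correlation is out of scope.
* ``generate_series`` builds an in-silico truncation series from a known
  mixture by composing the deterministic truncation operator with the forward
  NMR model, then applying multiplicative area noise.
* ``fixture_chromatogram`` renders size-class proportions as Gaussian peaks
  on an elution axis with area proportional to molar amount — valid for
  Δ-containing species because each chain carries exactly one 235-nm
  chromophore — and ``integrate_chromatogram`` recovers the proportions.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .chains import GlycanChain, Mixture
from .digestion import truncate
from .nmr import NMRReadout, forward_readout
from .sequencing import TruncationSeries

__all__ = [
    "AlginateModel",
    "NoiseModel",
    "generate_chains",
    "generate_series",
    "fixture_chromatogram",
    "integrate_chromatogram",
]


@dataclass(frozen=True)
class AlginateModel:
    """First-order Markov block model of an alginate chain.

    ``init_g`` is the probability that the first (non-reducing-end) residue
    is G; ``g_stay``/``m_stay`` are the probabilities of repeating the
    current residue, giving geometric blocks of mean length 1/(1 - stay).
    ``length`` is either a fixed chain length (rings) or an inclusive
    (lo, hi) range sampled uniformly.
    """

    init_g: float = 0.5
    g_stay: float = 0.7
    m_stay: float = 0.7
    length: Union[int, Tuple[int, int]] = 60

    def __post_init__(self):
        for name in ("init_g", "g_stay", "m_stay"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if isinstance(self.length, int):
            if self.length < 1:
                raise ValueError("chain length must be >= 1")
        else:
            lo, hi = self.length
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid length range {self.length}")

    @property
    def stationary_g(self) -> float:
        """Long-run G fraction of the Markov chain."""
        a, b = 1.0 - self.g_stay, 1.0 - self.m_stay  # leave rates
        if a + b == 0:
            return self.init_g
        return b / (a + b)

    @classmethod
    def poly_g(cls, length: Union[int, Tuple[int, int]] = 60) -> "AlginateModel":
        """G-rich preparation (> 90 % G)."""
        return cls(init_g=0.96, g_stay=0.97, m_stay=0.3, length=length)

    @classmethod
    def poly_m(cls, length: Union[int, Tuple[int, int]] = 60) -> "AlginateModel":
        """M-rich preparation (> 90 % M)."""
        return cls(init_g=0.04, g_stay=0.3, m_stay=0.97, length=length)

    @classmethod
    def mixed(cls, length: Union[int, Tuple[int, int]] = 60) -> "AlginateModel":
        """Block copolymer with equal M/G content and mean block length ~3.3."""
        return cls()


def generate_chains(
    model: AlginateModel,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[GlycanChain]:
    """Draw ``n`` saturated chains from the block model; pure in (params, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    chains = []
    for _ in range(n):
        if isinstance(model.length, int):
            length = model.length
        else:
            lo, hi = model.length
            length = int(rng.integers(lo, hi + 1))
        residues = []
        is_g = rng.random() < model.init_g
        for _ in range(length):
            residues.append("G" if is_g else "M")
            stay = model.g_stay if is_g else model.m_stay
            if rng.random() >= stay:
                is_g = not is_g
        chains.append(GlycanChain(tuple(residues)))
    return chains


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative signal-area noise: area * max(N(1, cv), 0)."""

    cv: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def generate_series(
    mixture: Mixture,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> TruncationSeries:
    """In-silico truncation series for a known unsaturated mixture.

    Applies ``truncate`` at every cut level 0 .. dp-3 (just the parent for
    DP 2), predicts areas with the forward NMR model, and perturbs each area
    with multiplicative noise.  With zero noise the series composed with the
    sequencing model is the identity on independence-factorising mixtures.
    """
    if not mixture.unsaturated:
        raise ValueError("a truncation series requires an unsaturated mixture")
    if noise is None:
        noise = NoiseModel(cv=0.0)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    levels = range(0, max(mixture.dp - 2, 1))
    readouts = {}
    for k in levels:
        clean = forward_readout(truncate(mixture, k))
        if noise.cv > 0:
            f = lambda a: a * max(float(rng.normal(1.0, noise.cv)), 0.0)
            readouts[k] = NMRReadout(
                f(clean.h4_dG), f(clean.h4_dM), f(clean.re_G), f(clean.re_M)
            )
        else:
            readouts[k] = clean
    return TruncationSeries(mixture.dp, readouts)


#: default elution calibration: centre (ml) for a species of dp rings; larger
#: species elute earlier on a gel-filtration column
def _default_centre(dp: int) -> float:
    return 24.0 - 1.8 * dp


def fixture_chromatogram(
    proportions: Mapping[int, float],
    *,
    sigma_ml: float = 0.25,
    grid_step_ml: float = 0.01,
    baseline_sd: float = 0.0,
    seed: Optional[int] = None,
    centres: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Gaussian peak table emulating a 235-nm gel-filtration trace.

    ``proportions`` maps dp -> molar fraction (must sum to 1); each peak's
    area equals its fraction (one chromophore per Δ chain makes area
    proportional to moles).  Returns a DataFrame with columns ``elution_ml``
    and ``absorbance_235``; peak metadata is stored in ``DataFrame.attrs``.
    """
    props = {int(d): float(f) for d, f in proportions.items()}
    total = math.fsum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {total!r}")
    pos = {d: (centres[d] if centres else _default_centre(d)) for d in props}
    lo = min(pos.values()) - 6 * sigma_ml
    hi = max(pos.values()) + 6 * sigma_ml
    x = np.arange(lo, hi + grid_step_ml, grid_step_ml)
    y = np.zeros_like(x)
    norm = sigma_ml * math.sqrt(2 * math.pi)
    for d, f in props.items():
        y += f / norm * np.exp(-0.5 * ((x - pos[d]) / sigma_ml) ** 2)
    if baseline_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, baseline_sd, size=y.shape), 0.0, None)
    df = pd.DataFrame({"elution_ml": x, "absorbance_235": y})
    df.attrs["peaks"] = pos
    df.attrs["sigma_ml"] = sigma_ml
    return df


def integrate_chromatogram(
    trace: pd.DataFrame,
    centres: Optional[Mapping[int, float]] = None,
    sigma_ml: Optional[float] = None,
) -> Tuple[pd.DataFrame, List[Tuple[int, int]]]:
    """Integrate peak areas and convert to molar percentages.

    Windows span +-4 sigma around each centre, clipped midway between
    neighbouring peaks.  Returns (report, overlap_warnings): the report has
    columns ``species`` (dp), ``area`` and ``molar_percent``; pairs of peaks
    separated by less than 4 sigma are flagged as unresolvable.
    """
    if centres is None:
        centres = trace.attrs.get("peaks")
        if centres is None:
            raise ValueError("no peak centres supplied and none stored on the trace")
    if sigma_ml is None:
        sigma_ml = trace.attrs.get("sigma_ml", 0.25)
    x = trace["elution_ml"].to_numpy()
    y = trace["absorbance_235"].to_numpy()
    items = sorted(centres.items(), key=lambda kv: kv[1])
    overlaps = []
    for (d0, c0), (d1, c1) in zip(items, items[1:]):
        if abs(c1 - c0) < 4 * sigma_ml:
            overlaps.append((d0, d1))
    rows = []
    for i, (d, c) in enumerate(items):
        lo = c - 4 * sigma_ml
        hi = c + 4 * sigma_ml
        if i > 0:
            lo = max(lo, (items[i - 1][1] + c) / 2)
        if i < len(items) - 1:
            hi = min(hi, (c + items[i + 1][1]) / 2)
        mask = (x >= lo) & (x <= hi)
        area = float(np.trapezoid(y[mask], x[mask]))
        rows.append({"species": d, "area": area})
    report = pd.DataFrame(rows)
    report["molar_percent"] = 100.0 * report["area"] / report["area"].sum()
    report = report.sort_values("species").reset_index(drop=True)
    return report, overlaps
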