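"""Endo + exo co-digestion synergy: monosaccharide yield at matched activity.

An exolytic lyase working alone on polymeric alginate is slow because long
chains are poor substrates (the size-dependent rate profile bottoms out at
its polymer tail).  An endolytic partner fragments the polymer into
oligosaccharides near the exo optimum (DP ~4), so the combination releases
unsaturated monomers far faster than the exolyase alone at the same total
activity.  ``run_synergy`` quantifies this with three simulated arms —
combined (activity split between the enzymes), endo-only and exo-only at the
same total mU — and reports the unsaturated-monomer yield of each with the
synergy ratio combined / exo-only.

The absolute wet-bench fold change depends on rate calibrations this model
does not claim; the reported ratio is a property of the frozen default
presets (size profile anchored at r(4)/r(polymer) = 6.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .chains import GlycanChain
from .digestion import (
    DEFAULT_CALIBRATION,
    DigestError,
    EndoRateTable,
    ExoRateProfile,
    simulate_digest,
)
from .synthetic import AlginateModel, generate_chains

__all__ = ["SynergyExperiment", "SynergyReport", "run_synergy", "size_activity_curve",
           "default_substrate_pool"]


def default_substrate_pool(seed: Optional[int] = None, n_chains: int = 25,
                           length: int = 60) -> List[GlycanChain]:
    """Desk-scale polymeric alginate substrate: mixed block copolymer chains."""
    return generate_chains(AlginateModel.mixed(length=length), n_chains, seed=seed)


@dataclass(frozen=True)
class SynergyExperiment:
    """One synergy assay: substrate pool, activities, duration, replication."""

    pool: Tuple[GlycanChain, ...]
    endo_mU: float = 50.0
    exo_mU: float = 50.0
    minutes: float = 10.0
    replicates: int = 3
    seed: Optional[int] = None

    def __post_init__(self):
        if self.endo_mU < 0 or self.exo_mU < 0:
            raise ValueError("activities must be >= 0")
        if self.minutes <= 0:
            raise ValueError("duration must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "pool", tuple(self.pool))


@dataclass
class SynergyReport:
    """Unsaturated-monomer yields per arm with Monte-Carlo standard errors."""

    yields: Dict[str, float]
    se: Dict[str, float]
    ratio: Optional[float]
    replicates: int

    def summary(self) -> str:
        lines = ["Endo/exo synergy assay", "=" * 40,
                 f"{'arm':<12}{'UDP1-equiv yield':>18}{'SE':>8}"]
        for arm in ("combined", "endo_only", "exo_only"):
            lines.append(f"{arm:<12}{self.yields[arm]:>18.2f}{self.se[arm]:>8.2f}")
        r = "undefined (exo-only yield is zero)" if self.ratio is None else f"{self.ratio:.2f}"
        lines.append(f"synergy ratio (combined / exo-only): {r}")
        return "\n".join(lines)

    def to_dict(self) -> Dict[str, object]:
        return {
            "yields": self.yields,
            "se": self.se,
            "synergy_ratio": self.ratio,
            "replicates": self.replicates,
        }


def run_synergy(
    experiment: SynergyExperiment,
    endo: Optional[EndoRateTable] = None,
    exo: Optional[ExoRateProfile] = None,
    calibration: float = DEFAULT_CALIBRATION,
) -> SynergyReport:
    """Simulate the three matched-activity arms and report yields.

    The combined arm splits the experiment's activities between the two
    enzymes; each single-enzyme control receives the full total (endo_mU +
    exo_mU).  Yield is the released unsaturated-monomer pool (UDP1 plus its
    DEH/TPC conversion products).  The synergy ratio is combined / exo-only
    and is undefined when the exolyase is absent from every arm.
    """
    endo = endo or EndoRateTable.g_preferring()
    exo = exo or ExoRateProfile.size_dependent()
    total = experiment.endo_mU + experiment.exo_mU
    if total <= 0:
        raise DigestError("no enzyme activity in any arm")
    if experiment.exo_mU <= 0:
        raise DigestError("synergy ratio undefined: exolyase absent from every arm")
    arms = {
        "combined": (experiment.endo_mU, experiment.exo_mU),
        "endo_only": (total, 0.0),
        "exo_only": (0.0, total),
    }
    master = np.random.default_rng(experiment.seed)
    yields: Dict[str, float] = {}
    ses: Dict[str, float] = {}
    for arm, (u1, u2) in arms.items():
        vals = []
        for _ in range(experiment.replicates):
            child = np.random.default_rng(master.integers(0, 2**31 - 1))
            traj = simulate_digest(
                list(experiment.pool),
                endo=endo, exo=exo, endo_mU=u1, exo_mU=u2,
                t_end=experiment.minutes, rng=child, calibration=calibration,
            )
            vals.append(traj[-1].unsaturated_monomer_yield())
        arr = np.asarray(vals, dtype=float)
        yields[arm] = float(arr.mean())
        ses[arm] = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    ratio = yields["combined"] / yields["exo_only"] if yields["exo_only"] > 0 else None
    return SynergyReport(yields=yields, se=ses, ratio=ratio, replicates=experiment.replicates)


def size_activity_curve(
    profile: ExoRateProfile,
    sizes: Iterable[Union[int, str]] = tuple(range(2, 11)) + ("polymer",),
) -> pd.DataFrame:
    """Relative exolytic activity r(dp) / r(polymer) per substrate size.

    ``"polymer"`` denotes the profile's polymer tail.  Under the default
    preset the optimum sits at dp = 4 with a 6.5-fold advantage over
    polymeric substrate.
    """
    r_poly = profile.polymer_rate
    if r_poly <= 0:
        raise ValueError("polymer rate must be > 0 to normalise the curve")
    rows = []
    for s in sizes:
        if s == "polymer":
            r = r_poly
        else:
            r = profile.rate(int(s))
        rows.append({"substrate": s, "relative_activity": r / r_poly})
    return pd.DataFrame(rows)
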