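"""Matplotlib helpers for traces, profiles and inferred compositions."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_chromatogram(trace, ax=None):
    """Elution trace (absorbance at 235 nm vs ml)."""
    ax = _get_ax(ax)
    ax.plot(trace["elution_ml"], trace["absorbance_235"], lw=1.0)
    ax.set_xlabel("elution volume (ml)")
    ax.set_ylabel("A235 (a.u.)")
    ax.invert_xaxis()  # larger species elute first
    return ax


def plot_size_activity(profile, sizes: Sequence[int] = tuple(range(2, 11)), ax=None):
    """Relative exolytic activity per substrate size, normalised to polymer."""
    from .synergy import size_activity_curve

    ax = _get_ax(ax)
    df = size_activity_curve(profile, tuple(sizes) + ("polymer",))
    labels = [str(s) for s in df["substrate"]]
    ax.bar(labels, df["relative_activity"])
    ax.set_xlabel("substrate size (dp)")
    ax.set_ylabel("activity relative to polymer")
    return ax


def plot_composition(results, ax=None):
    """Bar chart of an inferred mixture composition (molar %)."""
    ax = _get_ax(ax)
    seqs = list(results.composition)
    ax.bar(seqs, [100 * f for f in results.composition.values()])
    ax.set_ylabel("molar fraction (%)")
    ax.set_title(f"inferred DP{results.dp} composition")
    return ax


def plot_monomer_time_course(traj, ax=None):
    """Released unsaturated-monomer pool along a recorded trajectory."""
    ax = _get_ax(ax)
    times = [s.time for s in traj]
    yields = [s.unsaturated_monomer_yield() for s in traj]
    ax.step(times, yields, where="post")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("unsaturated monomers released")
    return ax
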