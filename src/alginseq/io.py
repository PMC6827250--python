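"""Plain-text readers/writers for mixtures, readouts, series, reports and trajectories.

Every output embeds provenance metadata (package version, config hash, seed):
TSV files as leading ``# key=value`` comment lines, JSON files under a
``_meta`` object.  ``load_* . save_*`` is the identity for all artifact
types.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd

from ._version import __version__
from .chains import GlycanChain, Mixture, Monomer
from .digestion import DigestState
from .nmr import NMRReadout
from .sequencing import SequencingResults, TruncationSeries

logger = logging.getLogger("alginseq")

__all__ = [
    "SchemaError",
    "save_mixture", "load_mixture",
    "save_readout", "load_readout",
    "save_readout_table", "load_readout_table",
    "save_series", "load_series",
    "save_report", "load_report",
    "save_trajectory", "load_trajectory",
]

_PathLike = Union[str, Path]


class SchemaError(ValueError):
    """File does not match the expected schema; names the offending field."""


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _meta(seed=None, config=None) -> Dict[str, object]:
    meta = {"package": "alginseq", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_sha256"] = _config_hash(config)
    return meta


def _tsv_header(seed=None, config=None) -> str:
    return "".join(f"# {k}={v}\n" for k, v in _meta(seed, config).items())


# -- mixtures -----------------------------------------------------------------

def save_mixture(mixture: Mixture, path: _PathLike, *, ascii: bool = False,
                 seed=None, config=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_tsv_header(seed, config))
        fh.write("sequence\tmolar_fraction\n")
        for ch, f in mixture.items_sorted():
            fh.write(f"{ch.format(ascii=ascii)}\t{f!r}\n")


def load_mixture(path: _PathLike) -> Mixture:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sequence": str})
    for col in ("sequence", "molar_fraction"):
        if col not in df.columns:
            raise SchemaError(f"mixture file {path}: missing column {col!r}")
    fractions = {row.sequence: float(row.molar_fraction) for row in df.itertuples()}
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-6:
        logger.warning("mixture fractions in %s sum to %.8f; renormalizing", path, total)
        return Mixture.from_fractions(fractions, renormalize=True)
    return Mixture.from_fractions(fractions, renormalize=True)


# -- NMR readouts -------------------------------------------------------------

_READOUT_FIELDS = ("h4_dG", "h4_dM", "re_G", "re_M")


def save_readout(readout: NMRReadout, path: _PathLike, *, seed=None, config=None) -> None:
    doc = {f: getattr(readout, f) for f in _READOUT_FIELDS}
    doc["_meta"] = _meta(seed, config)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def _readout_from_mapping(d: Mapping, where: str) -> NMRReadout:
    vals = {}
    for f in _READOUT_FIELDS:
        if f not in d:
            raise SchemaError(f"{where}: missing field {f!r}")
        vals[f] = float(d[f])
    return NMRReadout(**vals)


def load_readout(path: _PathLike) -> NMRReadout:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return _readout_from_mapping(doc, f"readout file {path}")


def save_readout_table(readouts: Mapping[str, NMRReadout], path: _PathLike, *,
                       seed=None, config=None) -> None:
    """TSV with one row per sample: sample_id, h4_dG, h4_dM, re_G, re_M."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_tsv_header(seed, config))
        fh.write("sample_id\t" + "\t".join(_READOUT_FIELDS) + "\n")
        for sample_id, r in readouts.items():
            fh.write(sample_id + "\t" + "\t".join(repr(getattr(r, f)) for f in _READOUT_FIELDS) + "\n")


def load_readout_table(path: _PathLike) -> Dict[str, NMRReadout]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"readout table {path}: missing column 'sample_id'")
    out = {}
    for row in df.itertuples():
        out[row.sample_id] = _readout_from_mapping(row._asdict(), f"readout table {path}")
    return out


# -- truncation series --------------------------------------------------------

def save_series(series: TruncationSeries, path: _PathLike, *, seed=None, config=None) -> None:
    doc = {
        "dp": series.dp,
        "readouts": [
            {"cuts": k, **{f: getattr(r, f) for f in _READOUT_FIELDS}}
            for k, r in sorted(series.readouts.items())
        ],
        "_meta": _meta(seed, config),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_series(path: _PathLike) -> TruncationSeries:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    for f in ("dp", "readouts"):
        if f not in doc:
            raise SchemaError(f"series file {path}: missing field {f!r}")
    readouts = {}
    for i, entry in enumerate(doc["readouts"]):
        if "cuts" not in entry:
            raise SchemaError(f"series file {path}: readout {i} missing field 'cuts'")
        readouts[int(entry["cuts"])] = _readout_from_mapping(entry, f"series file {path} readout {i}")
    return TruncationSeries(int(doc["dp"]), readouts)


# -- sequencing reports -------------------------------------------------------

def save_report(results: SequencingResults, path: _PathLike, *, seed=None, config=None) -> None:
    doc = results.to_dict()
    doc["_meta"] = _meta(seed, config)
    Path(path).write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")


def load_report(path: _PathLike) -> Dict[str, object]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    for f in ("dp", "marginals", "composition"):
        if f not in doc:
            raise SchemaError(f"report file {path}: missing field {f!r}")
    return doc


def save_report_tsv(results: SequencingResults, path: _PathLike, *, seed=None, config=None) -> None:
    pct = results.percentages()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_tsv_header(seed, config))
        fh.write("sequence\tmolar_fraction\tmolar_percent_rounded\n")
        for seq, f in results.composition.items():
            fh.write(f"{seq}\t{f!r}\t{pct[seq]:g}\n")


# -- digestion trajectories ---------------------------------------------------

def save_trajectory(traj: Sequence[DigestState], path: _PathLike, *, seed=None,
                    config=None, ascii: bool = False) -> None:
    """Long-format TSV: time, species (canonical notation or monomer name), count."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_tsv_header(seed, config))
        fh.write("time\tspecies\tcount\n")
        for state in traj:
            for ch in sorted(state.chains):
                fh.write(f"{state.time!r}\t{ch.format(ascii=ascii)}\t{state.chains[ch]}\n")
            for m in sorted(state.monomers, key=lambda m: m.name):
                fh.write(f"{state.time!r}\t{m.value}\t{state.monomers[m]}\n")


def load_trajectory(path: _PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species": str})
    for col in ("time", "species", "count"):
        if col not in df.columns:
            raise SchemaError(f"trajectory file {path}: missing column {col!r}")
    return df
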