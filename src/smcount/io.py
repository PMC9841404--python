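"""Trace bundle formats and pipeline configuration.

Two interchangeable on-disk forms for multi-molecule trace bundles:

* CSV — header ``molecule,frame,donor,acceptor,gfp`` (the ``molecule``
  column may be omitted for a single-molecule file, leaving the documented
  ``frame,donor,acceptor,gfp`` dialect); floats are written with 17
  significant digits so a write/read round trip is exact in float64.
* HDF5 — one group per molecule, ``/molecules/<id>/{donor,acceptor,gfp}``
  float64 datasets, with ``frame_interval`` and a JSON manifest stored as
  root attributes.

Ground truth from the simulators is stored in a JSON sidecar, never inside
the trace files, so analysis code cannot accidentally read it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .trace import IntensityTrace

__all__ = [
    "MoleculeTraces",
    "TraceBundle",
    "PipelineConfig",
    "ParseError",
    "read_traces",
    "write_traces",
    "bundle_from_experiment",
    "write_truth",
]

CHANNELS = ("donor", "acceptor", "gfp")
SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed trace file; the message names the offending line."""


@dataclass
class MoleculeTraces:
    molecule_id: int
    donor: IntensityTrace | None = None
    acceptor: IntensityTrace | None = None
    gfp: IntensityTrace | None = None

    def channel(self, name: str) -> IntensityTrace | None:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class TraceBundle:
    molecules: list[MoleculeTraces] = field(default_factory=list)
    frame_interval: float = 0.4
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)


# ---------------------------------------------------------------------------
# CSV / HDF5 round trip
# ---------------------------------------------------------------------------

def write_traces(bundle: TraceBundle, path) -> None:
    """Serialize a bundle; format chosen by suffix (.csv, .h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        _write_csv(bundle, path)
    elif path.suffix in (".h5", ".hdf5"):
        _write_hdf5(bundle, path)
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")


def read_traces(path) -> TraceBundle:
    """Read a bundle written by :func:`write_traces` (values float64)."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    raise ValueError(f"unsupported trace format {path.suffix!r}")


def _write_csv(bundle: TraceBundle, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule,frame,donor,acceptor,gfp\n")
        for mol in bundle.molecules:
            n = max(len(t) for t in (mol.donor, mol.acceptor, mol.gfp)
                    if t is not None)
            for t in range(n):
                cells = [str(mol.molecule_id), str(t)]
                for ch in CHANNELS:
                    tr = mol.channel(ch)
                    cells.append("" if tr is None
                                 else format(tr.values[t], ".17g"))
                fh.write(",".join(cells) + "\n")


def _read_csv(path: Path) -> TraceBundle:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    if header == ["frame", "donor", "acceptor", "gfp"]:
        has_mol = False
    elif header == ["molecule", "frame", "donor", "acceptor", "gfp"]:
        has_mol = True
    else:
        raise ParseError(f"{path}, line 1: malformed header {lines[0]!r}")
    ncol = len(header)
    data: dict[int, dict[str, list[float | None]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != ncol:
            raise ParseError(f"{path}, line {lineno}: expected {ncol} "
                             f"columns, got {len(cells)}")
        try:
            mol_id = int(cells[0]) if has_mol else 0
            vals = [None if c.strip() == "" else float(c)
                    for c in cells[ncol - 3:]]
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from None
        rec = data.setdefault(mol_id, {ch: [] for ch in CHANNELS})
        for ch, v in zip(CHANNELS, vals):
            rec[ch].append(v)
    if not data:
        raise ParseError(f"{path}: no trace rows")
    molecules = []
    for mol_id in sorted(data):
        rec = data[mol_id]
        traces = {}
        for ch in CHANNELS:
            col = rec[ch]
            if all(v is None for v in col):
                traces[ch] = None
            elif any(v is None for v in col):
                raise ParseError(f"{path}: molecule {mol_id} channel {ch} "
                                 "has missing values")
            else:
                traces[ch] = IntensityTrace(np.array(col), channel=ch)
        molecules.append(MoleculeTraces(mol_id, **traces))
    return TraceBundle(molecules)


def _write_hdf5(bundle: TraceBundle, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["frame_interval"] = bundle.frame_interval
        f.attrs["manifest"] = json.dumps(bundle.manifest, sort_keys=True)
        grp = f.create_group("molecules")
        for mol in bundle.molecules:
            g = grp.create_group(str(mol.molecule_id))
            for ch in CHANNELS:
                tr = mol.channel(ch)
                if tr is not None:
                    g.create_dataset(ch, data=tr.values.astype(np.float64))


def _read_hdf5(path: Path) -> TraceBundle:
    with h5py.File(path, "r") as f:
        fi = float(f.attrs.get("frame_interval", 0.4))
        manifest = json.loads(f.attrs.get("manifest", "{}"))
        molecules = []
        for key in sorted(f["molecules"], key=int):
            g = f["molecules"][key]
            traces = {ch: IntensityTrace(g[ch][()], fi, channel=ch)
                      if ch in g else None for ch in CHANNELS}
            molecules.append(MoleculeTraces(int(key), **traces))
    return TraceBundle(molecules, fi, manifest)


def bundle_from_experiment(dataset: dict) -> TraceBundle:
    """Convert :func:`smcount.synthgen.simulate_experiment` output."""
    fi = dataset["manifest"]["config"]["frame_interval"]
    molecules = [MoleculeTraces(m["id"], donor=m["donor"],
                                acceptor=m["acceptor"], gfp=m["gfp"])
                 for m in dataset["molecules"]]
    return TraceBundle(molecules, fi, dict(dataset["manifest"]))


def write_truth(dataset: dict, path) -> None:
    """JSON ground-truth sidecar for a simulated dataset."""
    out = {"manifest": dataset["manifest"], "molecules": []}
    for m in dataset["molecules"]:
        ct, ft = m["complex_truth"], m["fret_truth"]
        out["molecules"].append({
            "id": m["id"],
            "m_subunits": ct.m_subunits,
            "fluorescent_count": ct.fluorescent_count,
            "bind_frame": ct.bind_frame,
            "bleach_frames": list(ct.bleach_frames),
            "events": [[k, int(f)] for k, f in ft.events],
            "active": bool(ft.active),
        })
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

SCHEMES = ("count_then_activity", "activity_conditioned")
MODES = ("unwinding", "regression")

_STAGE_KEYS = {
    "stepcount": {"min_step", "min_jump", "min_significance"},
    "fit": {"truncated", "n_fixed"},
    "classify": {"lo", "hi", "min_cycles", "sustain", "smooth"},
}


@dataclass
class PipelineConfig:
    """Validated, JSON-round-trippable configuration of the full pipeline.

    Exactly one of ``simulate`` (a dataset recipe for
    :func:`smcount.synthgen.simulate_experiment`, seed injected from
    ``seed``) or ``traces_path`` must be provided.  Unknown keys anywhere
    are rejected rather than ignored.
    """

    seed: int
    scheme: str = "count_then_activity"
    mode: str = "unwinding"
    simulate: dict | None = None
    traces_path: str | None = None
    stepcount: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; "
                             f"expected one of {SCHEMES}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.simulate is None) == (self.traces_path is None):
            raise ValueError("exactly one of simulate/traces_path required")
        for stage, allowed in _STAGE_KEYS.items():
            extra = set(getattr(self, stage)) - allowed
            if extra:
                raise ValueError(f"unknown {stage} keys: {sorted(extra)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
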