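"""Trajectory container and file formats.

The native format is a self-describing plain-text container (`.cgt`): a
JSON metadata header followed by one block per frame. It is lossless to
the stored precision (9 significant digits) and is the authoritative
format; multi-model PDB and DCD exporters are provided for
interoperability with standard visualization/analysis tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .energetics import Box

FORMAT_MAGIC = "#CGT 1"


class TrajectoryError(RuntimeError):
    pass


@dataclass
class TrajectoryHandle:
    """In-memory trajectory: metadata plus (positions, box, time) frames."""

    metadata: dict
    _positions: list = field(default_factory=list)
    _boxes: list = field(default_factory=list)
    _times: list = field(default_factory=list)

    def __post_init__(self):
        required = {"unit_system", "provenance", "seed"}
        missing = required - set(self.metadata)
        if missing:
            raise TrajectoryError(f"trajectory metadata missing {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return len(self._positions)

    @property
    def times(self) -> np.ndarray:
        return np.array(self._times)

    def append(self, positions: np.ndarray, box: Box, time: float) -> None:
        if self._times and time <= self._times[-1]:
            raise TrajectoryError("frame times must be strictly increasing")
        self._positions.append(np.array(positions, dtype=float))
        self._boxes.append(box)
        self._times.append(float(time))

    def frame(self, i: int) -> tuple[np.ndarray, Box, float]:
        return self._positions[i], self._boxes[i], self._times[i]

    def positions(self, i: int) -> np.ndarray:
        return self._positions[i]

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def new(cls, provenance: str, seed: int, extra: Optional[dict] = None,
            ) -> "TrajectoryHandle":
        meta = {"unit_system": "nm,ps,amu,kJ/mol,e,K",
                "provenance": provenance, "seed": int(seed)}
        if extra:
            meta.update(extra)
        return cls(metadata=meta)


def write_trajectory(handle: TrajectoryHandle, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_MAGIC + "\n")
        fh.write("#META " + json.dumps(handle.metadata, sort_keys=True) + "\n")
        for pos, box, t in handle:
            lx, ly, lz = box.lengths
            fh.write(f"#FRAME t={t:.9g} box={lx:.9g},{ly:.9g},{lz:.9g} "
                     f"n={len(pos)}\n")
            np.savetxt(fh, pos, fmt="%.9g")


def read_trajectory(path) -> TrajectoryHandle:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != FORMAT_MAGIC:
            raise TrajectoryError(f"not a cgt trajectory: {path}")
        meta_line = fh.readline().strip()
        if not meta_line.startswith("#META "):
            raise TrajectoryError("missing metadata header")
        handle = TrajectoryHandle(metadata=json.loads(meta_line[6:]))
        frame_index = 0
        line = fh.readline()
        while line:
            if not line.startswith("#FRAME"):
                raise TrajectoryError(f"corrupted frame {frame_index}")
            try:
                fields = dict(kv.split("=") for kv in line.split()[1:])
                t = float(fields["t"])
                box = Box(tuple(float(x) for x in fields["box"].split(",")))
                n = int(fields["n"])
                pos = np.loadtxt(fh, max_rows=n).reshape(n, 3)
            except Exception as exc:
                raise TrajectoryError(
                    f"corrupted frame {frame_index}: {exc}") from exc
            handle.append(pos, box, t)
            frame_index += 1
            line = fh.readline()
    return handle


def export_pdb(handle: TrajectoryHandle, topology, path,
               frames: Optional[list[int]] = None) -> None:
    """Multi-model PDB export readable by :func:`cgphase.topology.parse_cg_pdb`."""
    from .topology import write_cg_pdb, flatten_system, SystemTopology
    if isinstance(topology, SystemTopology):
        topology = flatten_system(topology)
    idx = frames if frames is not None else list(range(handle.n_frames))
    coords = [handle.positions(i) for i in idx]
    write_cg_pdb(topology, coords[0], path, multi_model_coords=coords)


def export_dcd(handle: TrajectoryHandle, topology, path) -> None:
    """DCD export (via mdtraj) for interoperability."""
    import mdtraj as md
    top = md.Topology()
    chain_map: dict[tuple, object] = {}
    copies = (topology.iter_copies() if hasattr(topology, "iter_copies")
              else [(topology, 0, None)])
    for mol, ci, _ in copies:
        for bead in mol.beads:
            key = (ci, bead.chain_id)
            if key not in chain_map:
                chain_map[key] = top.add_chain()
            res = top.add_residue(bead.residue_code, chain_map[key])
            top.add_atom("CA", md.element.carbon, res)
    xyz = np.array([handle.positions(i) for i in range(handle.n_frames)])
    lengths = np.array([b.lengths for _, b, _ in handle])
    traj = md.Trajectory(xyz, top, time=handle.times,
                         unitcell_lengths=lengths,
                         unitcell_angles=np.full((handle.n_frames, 3), 90.0))
    traj.save_dcd(str(path))
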