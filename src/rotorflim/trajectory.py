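"""Trajectory container, atom-role definitions and GRO input/output.

Coordinates are in nm (GRO convention) with an orthorhombic box.  Atom
roles — which atom is the probe reference, which are lipid phosphorus,
onium nitrogen, phosphate, ester oxygens, chain carbons with their bonded
hydrogens, and water oxygens — are carried separately from the coordinates
as a JSON-serialisable group definition, so the same analysis code runs on
generated toy systems and on externally produced trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "ChainCarbon",
    "LipidRecord",
    "BilayerTopology",
    "write_gro",
    "read_gro",
]


@dataclass
class Trajectory:
    """Frames x atoms x (x, y, z) coordinates in nm with a constant box.

    ``coords`` holds the primary (typically wrapped) coordinates;
    ``unwrapped`` optionally stores the continuous coordinates needed for
    displacement analyses.
    """

    coords: np.ndarray
    box: np.ndarray
    dt_ps: float
    roles: dict[str, list[int]] = field(default_factory=dict)
    unwrapped: np.ndarray | None = None
    is_wrapped: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (nm)")
        if self.dt_ps <= 0:
            raise ValueError("frame spacing dt_ps must be positive")
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float)
            if self.unwrapped.shape != self.coords.shape:
                raise ValueError("unwrapped coords must match coords shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps

    def select(self, role: str) -> np.ndarray:
        if role == "all":
            return np.arange(self.n_atoms)
        if role not in self.roles:
            raise KeyError(f"role {role!r} not defined; have {sorted(self.roles)}")
        idx = np.asarray(self.roles[role], dtype=int)
        if idx.size == 0:
            raise ValueError(f"role {role!r} selects no atoms")
        return idx


@dataclass(frozen=True)
class ChainCarbon:
    """One acyl-chain carbon and its bonded hydrogens."""

    carbon: int
    hydrogens: tuple[int, ...]


@dataclass(frozen=True)
class LipidRecord:
    """Atom indices of the analysed sites of one lipid molecule."""

    phosphorus: int
    onium: int
    phosphate: tuple[int, ...]
    ester_oxygens: tuple[int, ...]
    sn1: tuple[ChainCarbon, ...] = ()
    sn2: tuple[ChainCarbon, ...] = ()

    def group_atoms(self, group: str) -> tuple[int, ...]:
        """Headgroup atoms of one hydration group (onium/phosphate/ester)."""
        if group == "onium":
            return (self.onium,)
        if group == "phosphate":
            return tuple(self.phosphate)
        if group == "ester":
            return tuple(self.ester_oxygens)
        raise ValueError(f"unknown headgroup group {group!r}")


@dataclass
class BilayerTopology:
    """Role map for bilayer analyses: probe, lipids, water oxygens."""

    lipids: list[LipidRecord]
    water_oxygens: list[int] = field(default_factory=list)
    probe_atom: int | None = None

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    def phosphorus_indices(self) -> np.ndarray:
        return np.array([lip.phosphorus for lip in self.lipids], dtype=int)

    def to_json(self, path: str | Path | None = None) -> str:
        def chain(cs):
            return [{"carbon": c.carbon, "hydrogens": list(c.hydrogens)} for c in cs]

        payload = json.dumps(
            {
                "probe_atom": self.probe_atom,
                "water_oxygens": list(self.water_oxygens),
                "lipids": [
                    {
                        "phosphorus": lip.phosphorus,
                        "onium": lip.onium,
                        "phosphate": list(lip.phosphate),
                        "ester_oxygens": list(lip.ester_oxygens),
                        "sn1": chain(lip.sn1),
                        "sn2": chain(lip.sn2),
                    }
                    for lip in self.lipids
                ],
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "BilayerTopology":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)

        def chain(items):
            return tuple(
                ChainCarbon(it["carbon"], tuple(it["hydrogens"])) for it in items
            )

        lipids = [
            LipidRecord(
                phosphorus=it["phosphorus"],
                onium=it["onium"],
                phosphate=tuple(it["phosphate"]),
                ester_oxygens=tuple(it["ester_oxygens"]),
                sn1=chain(it.get("sn1", [])),
                sn2=chain(it.get("sn2", [])),
            )
            for it in d["lipids"]
        ]
        return cls(lipids, list(d.get("water_oxygens", [])), d.get("probe_atom"))


# ---------------------------------------------------------------------------
# GRO I/O (concatenated frames), via mdtraj
# ---------------------------------------------------------------------------


def _mdtraj_topology(n_atoms: int, names: list[str] | None):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("SYS", chain)
    carbon = md.core.element.carbon
    for i in range(n_atoms):
        name = names[i] if names else f"A{i + 1}"
        top.add_atom(name, carbon, res)
    return top


def write_gro(traj: Trajectory, path: str | Path, names: list[str] | None = None,
              use_unwrapped: bool = False) -> None:
    """Write all frames as a concatenated GRO trajectory."""
    import mdtraj as md

    xyz = traj.unwrapped if (use_unwrapped and traj.unwrapped is not None) \
        else traj.coords
    t = md.Trajectory(
        xyz=xyz.astype(np.float32),
        topology=_mdtraj_topology(traj.n_atoms, names),
        time=traj.times_ps / 1000.0,  # mdtraj time unit also stores ps; cosmetic
        unitcell_lengths=np.tile(traj.box, (traj.n_frames, 1)).astype(np.float32),
        unitcell_angles=np.full((traj.n_frames, 3), 90.0, dtype=np.float32),
    )
    t.save_gro(str(path))


def read_gro(path: str | Path, dt_ps: float,
             roles: dict[str, list[int]] | None = None) -> Trajectory:
    """Read a (possibly multi-frame) GRO file into a :class:`Trajectory`."""
    import mdtraj as md

    t = md.load(str(path))
    if t.unitcell_lengths is None:
        raise ValueError("GRO file has no box vectors")
    box = np.asarray(t.unitcell_lengths[0], dtype=float)
    return Trajectory(
        coords=np.asarray(t.xyz, dtype=float),
        box=box,
        dt_ps=dt_ps,
        roles=roles or {},
    )
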