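"""Trajectory I/O and the internal bead-system data model.

Coordinates are stored in nm (GRO convention); PDB/MDAnalysis Å values are
converted on load. Frame selection by time is half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .constants import DEFAULT_BEAD_MASS

logger = logging.getLogger(__name__)

ANGSTROM_TO_NM = 0.1


class TrajectoryFormatError(ValueError):
    """Topology/trajectory inconsistency (e.g. mismatched bead counts)."""


class FrameRangeError(ValueError):
    """Frame selection matched no frames."""


@dataclass(frozen=True)
class FrameRange:
    """Half-open time window ``[start_ps, end_ps)`` with a frame stride."""

    start_ps: float = 0.0
    end_ps: float = np.inf
    stride: int = 1

    def __post_init__(self) -> None:
        if not self.start_ps < self.end_ps:
            raise ValueError(f"start ({self.start_ps}) must be < end ({self.end_ps})")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    def select(self, times_ps: np.ndarray) -> np.ndarray:
        """Indices of frames whose time falls inside the window, strided."""
        times_ps = np.asarray(times_ps, dtype=float)
        inside = np.nonzero((times_ps >= self.start_ps) & (times_ps < self.end_ps))[0]
        return inside[:: self.stride]


@dataclass
class BeadSystem:
    """A set of trajectory frames for a multi-chain coarse-grained system.

    Attributes
    ----------
    coords:
        Positions, shape ``(n_frames, n_beads, 3)``, nm.
    chain_id:
        Integer chain label per bead, shape ``(n_beads,)``. Beads are grouped
        by chain, then by residue.
    residue_index:
        1-based residue index within its chain, per bead.
    mass:
        Bead masses in amu.
    box:
        Orthorhombic box edge lengths per frame, shape ``(n_frames, 3)``, nm.
    time:
        Frame times in ps.
    wrapped:
        Whether coordinates are wrapped into the primary box image. Analyses
        that require whole molecules (gyration tensors, MSD) either unwrap
        internally or refuse wrapped input.
    """

    coords: np.ndarray
    chain_id: np.ndarray
    residue_index: np.ndarray
    mass: np.ndarray
    box: np.ndarray
    time: np.ndarray
    wrapped: bool = True
    _chain_indices: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_id = np.asarray(self.chain_id, dtype=int)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.mass = np.asarray(self.mass, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.validate()
        self._chain_indices = {
            int(c): np.nonzero(self.chain_id == c)[0] for c in np.unique(self.chain_id)
        }

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def chain_ids(self) -> list[int]:
        return sorted(self._chain_indices)

    @property
    def n_chains(self) -> int:
        return len(self._chain_indices)

    def chain_indices(self, chain: int) -> np.ndarray:
        try:
            return self._chain_indices[int(chain)]
        except KeyError:
            raise KeyError(f"unknown chain id {chain!r}") from None

    def chain_coords(self, frame: int, chain: int) -> np.ndarray:
        return self.coords[frame, self.chain_indices(chain)]

    def chain_masses(self, chain: int) -> np.ndarray:
        return self.mass[self.chain_indices(chain)]

    def residues_per_chain(self) -> int:
        counts = {int(self.residue_index[idx].max()) for idx in self._chain_indices.values()}
        if len(counts) != 1:
            raise ValueError(f"chains have differing residue counts: {sorted(counts)}")
        return counts.pop()

    def validate(self) -> None:
        nf, nb, three = self.coords.shape
        if three != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for name, arr in (("chain_id", self.chain_id), ("residue_index", self.residue_index), ("mass", self.mass)):
            if arr.shape != (nb,):
                raise ValueError(f"{name} must have one entry per bead")
        if np.any(self.mass <= 0):
            raise ValueError("bead masses must be positive")
        if self.box.shape != (nf, 3) or np.any(self.box <= 0):
            raise ValueError("box must be (n_frames, 3) with positive edges")
        if self.time.shape != (nf,):
            raise ValueError("time must have one entry per frame")
        # bead order groups by chain: each chain id occupies one contiguous run
        changes = np.count_nonzero(np.diff(self.chain_id) != 0)
        if changes + 1 != len(np.unique(self.chain_id)):
            raise ValueError("beads must be grouped contiguously by chain")

    def select_frames(self, frame_range: FrameRange) -> "BeadSystem":
        """Restrict to frames inside ``frame_range`` (half-open, idempotent)."""
        idx = frame_range.select(self.time)
        if idx.size == 0:
            raise FrameRangeError(
                f"no frames in [{frame_range.start_ps}, {frame_range.end_ps}) ps"
            )
        return BeadSystem(
            coords=self.coords[idx],
            chain_id=self.chain_id,
            residue_index=self.residue_index,
            mass=self.mass,
            box=self.box[idx],
            time=self.time[idx],
            wrapped=self.wrapped,
        )


# -----------------------------------------------------------------------------
# MDAnalysis-backed loading / writing
# -----------------------------------------------------------------------------

def _chain_ids_from_universe(universe) -> np.ndarray:
    """Chain labels from segments; fall back to residue-index resets."""
    atoms = universe.atoms
    n_segments = len(universe.segments)
    if n_segments > 1:
        seg_labels = {seg.segid: i for i, seg in enumerate(universe.segments)}
        return np.array([seg_labels[a.segid] for a in atoms], dtype=int)
    # single segment: infer chains wherever the residue numbering restarts
    resids = atoms.resids
    chain = np.zeros(len(atoms), dtype=int)
    current = 0
    for k in range(1, len(atoms)):
        if resids[k] < resids[k - 1]:
            current += 1
        chain[k] = current
    return chain


def load_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    frame_range: FrameRange | None = None,
    default_mass: float = DEFAULT_BEAD_MASS,
    wrapped: bool = True,
) -> BeadSystem:
    """Read a GRO/PDB topology plus optional XTC/DCD trajectory.

    Masses are taken from the topology when present; otherwise every bead is
    assigned ``default_mass`` (72 amu, a regular coarse-grained bead) with a
    logged warning — real masses are honoured whenever the file carries them.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    args = [str(topology_path)]
    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FileNotFoundError(trajectory_path)
        args.append(str(trajectory_path))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(*args)
        except Exception as exc:  # bead-count mismatch surfaces here
            raise TrajectoryFormatError(str(exc)) from exc

        n_beads = len(universe.atoms)
        guessed = {
            getattr(attr, "attrname", "") for attr in
            getattr(universe._topology, "guessed_attributes", [])
        }
        try:
            masses = np.asarray(universe.atoms.masses, dtype=float)
            has_masses = "masses" not in guessed and np.all(masses > 0)
        except Exception:
            has_masses = False
        if not has_masses:
            # GRO/PDB topologies carry no masses; element guesses from CG
            # bead names are meaningless, so fall back to the regular bead
            # mass — real masses are honoured whenever the file has them
            masses = np.full(n_beads, default_mass)
            logger.warning(
                "topology %s carries no usable masses; defaulting all beads to %.1f amu",
                topology_path, default_mass,
            )

        chain_id = _chain_ids_from_universe(universe)
        resids = np.asarray(universe.atoms.resids, dtype=int)
        # make residue indices 1-based within each chain
        residue_index = np.empty(n_beads, dtype=int)
        for c in np.unique(chain_id):
            sel = chain_id == c
            residue_index[sel] = resids[sel] - resids[sel].min() + 1

        coords, boxes, times = [], [], []
        for ts in universe.trajectory:
            coords.append(ts.positions * ANGSTROM_TO_NM)
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float) * ANGSTROM_TO_NM)
            times.append(float(ts.time))

    system = BeadSystem(
        coords=np.array(coords),
        chain_id=chain_id,
        residue_index=residue_index,
        mass=masses,
        box=np.array(boxes),
        time=np.array(times),
        wrapped=wrapped,
    )
    if frame_range is not None:
        system = system.select_frames(frame_range)
    return system


def save_system(
    system: BeadSystem,
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
) -> None:
    """Write a BeadSystem as a GRO topology plus optional XTC/DCD trajectory."""
    import MDAnalysis as mda

    n = system.n_beads
    universe = mda.Universe.empty(
        n_atoms=n,
        n_residues=n,
        n_segments=system.n_chains,
        atom_resindex=np.arange(n),
        residue_segindex=np.searchsorted(system.chain_ids, system.chain_id),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", ["BB"] * n)
    universe.add_TopologyAttr("resnames", ["GLY"] * n)
    universe.add_TopologyAttr("resids", system.residue_index)
    universe.add_TopologyAttr("masses", system.mass)
    universe.add_TopologyAttr("segids", [f"C{c:04d}" for c in system.chain_ids])

    universe.atoms.positions = system.coords[0] / ANGSTROM_TO_NM
    universe.dimensions = [*(system.box[0] / ANGSTROM_TO_NM), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(str(trajectory_path), n_atoms=n) as writer:
                for f in range(system.n_frames):
                    universe.atoms.positions = system.coords[f] / ANGSTROM_TO_NM
                    universe.dimensions = [*(system.box[f] / ANGSTROM_TO_NM), 90, 90, 90]
                    universe.trajectory.ts.time = system.time[f]
                    universe.trajectory.ts.frame = f
                    writer.write(universe.atoms)


# -----------------------------------------------------------------------------
# Tabular / graph output
# -----------------------------------------------------------------------------

def write_table(
    records: pd.DataFrame | Sequence[dict] | dict,
    path: str | Path,
    format: str | None = None,
    allow_empty: bool = False,
) -> None:
    """Write tabular records as CSV or JSON with a stable column order."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(records)
    if frame.empty and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def write_graph(graph: nx.Graph, path: str | Path, edge_list_path: str | Path | None = None) -> None:
    """Write a droplet graph as GraphML (node ids are chain ids)."""
    if graph.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    nx.write_graphml(graph, str(path))
    if edge_list_path is not None:
        nx.write_edgelist(graph, str(edge_list_path), data=False)


def read_graph(path: str | Path) -> nx.Graph:
    graph = nx.read_graphml(str(path))
    return nx.relabel_nodes(graph, {n: int(n) for n in graph.nodes})
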