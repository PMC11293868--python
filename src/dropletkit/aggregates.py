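"""Chain-chain contacts, cluster detection, and phase classification.

Two chains are "bound" when their minimum bead-bead distance (minimum-image
convention for periodic boxes) is below the contact cutoff, 0.8 nm by
default. Clusters are the connected components of the resulting contact
graph; chains in clusters of three or fewer belong to the dilute phase,
chains in aggregates of six or more belong to the dense (droplet) phase, and
tetramers/pentamers are labelled intermediate and excluded from both phase
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import CONTACT_CUTOFF_NM
from .model_io import BeadSystem

DILUTE_MAX_DEFAULT = 3
DENSE_MIN_DEFAULT = 6

PHASE_DILUTE = "dilute"
PHASE_DENSE = "dense"
PHASE_INTERMEDIATE = "intermediate"


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors."""
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_chain_distance(
    system: BeadSystem,
    frame: int,
    chain_i: int,
    chain_j: int,
    use_pbc: bool = True,
) -> float:
    """Minimum bead-bead distance between two chains in one frame, nm."""
    if chain_i == chain_j:
        raise ValueError("chain ids must differ")
    a = system.chain_coords(frame, chain_i)
    b = system.chain_coords(frame, chain_j)
    box = system.box[frame] if use_pbc else None
    delta = minimum_image_displacement(a[:, None, :] - b[None, :, :], box)
    return float(np.sqrt(np.einsum("ijk,ijk->ij", delta, delta).min()))


def contact_matrix(
    system: BeadSystem,
    frame: int,
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
) -> np.ndarray:
    """Symmetric boolean chain-by-chain contact matrix for one frame.

    Entry (i, j) is True iff the minimum inter-chain distance is below
    ``cutoff``. The diagonal is False. Row/column order follows
    ``system.chain_ids``. Chain pairs whose bounding spheres cannot approach
    within the cutoff are pruned before the all-pairs bead scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chains = system.chain_ids
    n = len(chains)
    box = system.box[frame] if use_pbc else None

    coords = [system.chain_coords(frame, c) for c in chains]
    centers = np.array([c.mean(axis=0) for c in coords])
    radii = np.array(
        [np.sqrt(((c - ctr) ** 2).sum(axis=1).max()) for c, ctr in zip(coords, centers)]
    )

    # the center-distance bound is only a valid prune when both bounding
    # spheres fit well inside half the box
    half_box = np.inf if box is None else float(np.min(box)) / 2.0

    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            prunable = radii[i] + radii[j] + cutoff < half_box
            dc = minimum_image_displacement(centers[i] - centers[j], box)
            if prunable and np.sqrt((dc**2).sum()) - radii[i] - radii[j] >= cutoff:
                continue
            delta = minimum_image_displacement(
                coords[i][:, None, :] - coords[j][None, :, :], box
            )
            dmin = np.sqrt(np.einsum("abk,abk->ab", delta, delta).min())
            if dmin < cutoff:
                out[i, j] = out[j, i] = True
    return out


@dataclass
class ClusterAssignment:
    """Partition of chains into contact clusters for one frame."""

    frame_index: int
    clusters: list[list[int]]
    phase_label: dict[int, str]
    n_free_monomers: int
    largest_cluster_size: int

    @property
    def chains(self) -> list[int]:
        return sorted(c for cluster in self.clusters for c in cluster)

    def chains_in_phase(self, phase: str) -> list[int]:
        return sorted(c for c, p in self.phase_label.items() if p == phase)

    def dense_clusters(self) -> list[list[int]]:
        return [cl for cl in self.clusters if self.phase_label[cl[0]] == PHASE_DENSE]

    def cluster_of(self, chain: int) -> list[int]:
        for cl in self.clusters:
            if chain in cl:
                return cl
        raise KeyError(f"chain {chain} not in assignment")


def find_clusters(contacts: np.ndarray, chain_ids: Sequence[int] | None = None) -> list[list[int]]:
    """Connected components of a boolean contact matrix.

    Clusters are ordered largest first, ties broken by the smallest member
    chain id; members within a cluster are sorted ascending.
    """
    contacts = np.asarray(contacts)
    if contacts.ndim != 2 or contacts.shape[0] != contacts.shape[1]:
        raise ValueError("contact matrix must be square")
    if contacts.dtype != bool:
        raise ValueError("contact matrix must be boolean")
    if not np.array_equal(contacts, contacts.T):
        raise ValueError("contact matrix must be symmetric")
    n = contacts.shape[0]
    if chain_ids is None:
        chain_ids = list(range(n))
    _, labels = connected_components(csr_matrix(contacts), directed=False)
    clusters: dict[int, list[int]] = {}
    for cid, lab in zip(chain_ids, labels):
        clusters.setdefault(lab, []).append(cid)
    out = [sorted(members) for members in clusters.values()]
    out.sort(key=lambda cl: (-len(cl), cl[0]))
    return out


def classify_phases(
    clusters: Iterable[Sequence[int]],
    dilute_max: int = DILUTE_MAX_DEFAULT,
    dense_min: int = DENSE_MIN_DEFAULT,
) -> dict[int, str]:
    """Label every chain dilute / dense / intermediate from its cluster size."""
    if not dilute_max < dense_min:
        raise ValueError("dilute_max must be < dense_min")
    labels: dict[int, str] = {}
    for cluster in clusters:
        size = len(cluster)
        if size <= dilute_max:
            phase = PHASE_DILUTE
        elif size >= dense_min:
            phase = PHASE_DENSE
        else:
            phase = PHASE_INTERMEDIATE
        for chain in cluster:
            labels[chain] = phase
    return labels


def assign_frame(
    system: BeadSystem,
    frame: int,
    cutoff: float = CONTACT_CUTOFF_NM,
    dilute_max: int = DILUTE_MAX_DEFAULT,
    dense_min: int = DENSE_MIN_DEFAULT,
    use_pbc: bool = True,
) -> ClusterAssignment:
    """Full contact → cluster → phase pipeline for one frame."""
    contacts = contact_matrix(system, frame, cutoff=cutoff, use_pbc=use_pbc)
    clusters = find_clusters(contacts, system.chain_ids)
    labels = classify_phases(clusters, dilute_max=dilute_max, dense_min=dense_min)
    return ClusterAssignment(
        frame_index=frame,
        clusters=clusters,
        phase_label=labels,
        n_free_monomers=sum(1 for cl in clusters if len(cl) == 1),
        largest_cluster_size=max(len(cl) for cl in clusters),
    )


def assign_all_frames(
    system: BeadSystem,
    cutoff: float = CONTACT_CUTOFF_NM,
    dilute_max: int = DILUTE_MAX_DEFAULT,
    dense_min: int = DENSE_MIN_DEFAULT,
    use_pbc: bool = True,
) -> list[ClusterAssignment]:
    return [
        assign_frame(system, f, cutoff=cutoff, dilute_max=dilute_max,
                     dense_min=dense_min, use_pbc=use_pbc)
        for f in range(system.n_frames)
    ]


def fraction_bound(
    system: BeadSystem,
    chain_i: int,
    chain_j: int,
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
) -> float:
    """Percentage of frames in which two chains are bound (< cutoff)."""
    if chain_i == chain_j:
        raise ValueError("chain ids must differ")
    if system.n_frames < 1:
        raise ValueError("need at least one frame")
    bound = sum(
        min_chain_distance(system, f, chain_i, chain_j, use_pbc=use_pbc) < cutoff
        for f in range(system.n_frames)
    )
    return 100.0 * bound / system.n_frames


def monomer_count_series(
    system: BeadSystem,
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
    assignments: Sequence[ClusterAssignment] | None = None,
) -> dict:
    """Per-frame free-monomer (strict singleton) counts plus summary stats."""
    if assignments is None:
        assignments = assign_all_frames(system, cutoff=cutoff, use_pbc=use_pbc)
    counts = np.array([a.n_free_monomers for a in assignments])
    largest = np.array([a.largest_cluster_size for a in assignments])
    return {
        "time_ps": system.time.tolist(),
        "n_free_monomers": counts.tolist(),
        "largest_cluster_size": largest.tolist(),
        "mean_free_monomers": float(counts.mean()),
        "mean_largest_cluster": float(largest.mean()),
    }
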