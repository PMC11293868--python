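"""Residue-resolved contact probability maps and region reductions.

A residue pair is in contact in a frame when any bead of one residue lies
within the cutoff (minimum-image) of any bead of the other. Intra-chain maps
sample every (chain, frame) in a phase once; inter-chain maps sample ordered
chain pairs sharing a droplet, then symmetrize. The dense-minus-dilute
difference map highlights interactions gained or lost on entering a droplet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregates import PHASE_DENSE, ClusterAssignment, minimum_image_displacement
from .constants import CONTACT_CUTOFF_NM
from .model_io import BeadSystem

#: default alpha-synuclein domain boundaries, 1-based inclusive
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "Nter": (1, 60),
    "NAC": (61, 95),
    "Cter": (96, 140),
}


class EmptyMapError(ValueError):
    """No samples available for the requested phase/scope."""


@dataclass
class ContactMap:
    matrix: np.ndarray          # n_res x n_res probabilities in [0, 1]
    counts: int                 # samples contributing
    scope: str                  # "intra" | "inter"
    phase: str                  # "dense" | "dilute" | "all"
    residue_labels: list[int]

    def masked(self, band: int = 2) -> np.ndarray:
        """Copy with the |i-j| <= band near-diagonal set to NaN (intra maps)."""
        out = self.matrix.astype(float).copy()
        n = out.shape[0]
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= band
        out[idx] = np.nan
        return out


def _residue_bead_groups(system: BeadSystem, chain: int) -> list[np.ndarray]:
    idx = system.chain_indices(chain)
    res = system.residue_index[idx]
    return [idx[res == r] for r in range(1, res.max() + 1)]


def _residue_contacts_bool(
    system: BeadSystem,
    frame: int,
    chain_a: int,
    chain_b: int,
    cutoff: float,
    use_pbc: bool,
) -> np.ndarray:
    """Boolean residue x residue contact matrix between two chains (or one)."""
    box = system.box[frame] if use_pbc else None
    ga = _residue_bead_groups(system, chain_a)
    gb = _residue_bead_groups(system, chain_b)
    xa = system.coords[frame]
    # all-bead pair distances, then reduce to residue blocks
    A = xa[np.concatenate(ga)]
    B = xa[np.concatenate(gb)]
    delta = minimum_image_displacement(A[:, None, :] - B[None, :, :], box)
    close = np.einsum("ijk,ijk->ij", delta, delta) < cutoff * cutoff
    bounds_a = np.cumsum([0] + [len(g) for g in ga])
    bounds_b = np.cumsum([0] + [len(g) for g in gb])
    out = np.zeros((len(ga), len(gb)), dtype=bool)
    for i in range(len(ga)):
        block = close[bounds_a[i]:bounds_a[i + 1]]
        for j in range(len(gb)):
            out[i, j] = block[:, bounds_b[j]:bounds_b[j + 1]].any()
    return out


def intra_contact_map(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    phase: str,
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
) -> ContactMap:
    """Average intra-chain residue contact map over chains in a phase."""
    n_res = system.residues_per_chain()
    total = np.zeros((n_res, n_res), dtype=np.int64)
    samples = 0
    for assignment in assignments:
        f = assignment.frame_index
        for chain, label in assignment.phase_label.items():
            if phase != "all" and label != phase:
                continue
            total += _residue_contacts_bool(system, f, chain, chain, cutoff, use_pbc)
            samples += 1
    if samples == 0:
        raise EmptyMapError(f"no chain-frame samples in phase {phase!r}")
    return ContactMap(
        matrix=total / samples,
        counts=samples,
        scope="intra",
        phase=phase,
        residue_labels=list(range(1, n_res + 1)),
    )


def inter_contact_map(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    cutoff: float = CONTACT_CUTOFF_NM,
    use_pbc: bool = True,
) -> ContactMap:
    """Average inter-chain residue contact map over droplet chain pairs.

    Samples are ordered chain pairs (A, B), A != B, within the same dense
    cluster per frame; the accumulated matrix is symmetrized by construction
    since both (A, B) and (B, A) contribute.
    """
    n_res = system.residues_per_chain()
    total = np.zeros((n_res, n_res), dtype=np.int64)
    samples = 0
    for assignment in assignments:
        f = assignment.frame_index
        for cluster in assignment.dense_clusters():
            for a in cluster:
                for b in cluster:
                    if a == b:
                        continue
                    total += _residue_contacts_bool(system, f, a, b, cutoff, use_pbc)
                    samples += 1
    if samples == 0:
        raise EmptyMapError("no multi-chain dense cluster in any frame")
    return ContactMap(
        matrix=total / samples,
        counts=samples,
        scope="inter",
        phase=PHASE_DENSE,
        residue_labels=list(range(1, n_res + 1)),
    )


def difference_map(map_dense: ContactMap, map_dilute: ContactMap) -> np.ndarray:
    """Dense minus dilute contact probabilities; entries in [-1, 1]."""
    if map_dense.matrix.shape != map_dilute.matrix.shape:
        raise ValueError("contact maps have different dimensions")
    if map_dense.scope != map_dilute.scope:
        raise ValueError("contact maps have different scopes")
    return map_dense.matrix - map_dilute.matrix


def region_reduce(
    matrix: np.ndarray | ContactMap,
    regions: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Mean probability per region pair (regions as 1-based inclusive ranges)."""
    if isinstance(matrix, ContactMap):
        matrix = matrix.matrix
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if regions is None:
        regions = DEFAULT_REGIONS
    for name, (lo, hi) in regions.items():
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"region {name!r} range ({lo}, {hi}) outside 1..{n}")
    names = list(regions)
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for ni, (lo_i, hi_i) in regions.items():
        for nj, (lo_j, hi_j) in regions.items():
            block = matrix[lo_i - 1:hi_i, lo_j - 1:hi_j]
            table.loc[ni, nj] = float(block.mean())
    return table
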