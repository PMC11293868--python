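"""Gyration-tensor geometry: shape tensors, ellipsoid semi-axes, chain Rg,
Kabsch RMSD, and principal-axis orientation angles between neighbouring chains.

The mass-weighted gyration (covariance) tensor of a bead set is

    C_ab = sum_i m_i (r_ia - r_cm,a)(r_ib - r_cm,b) / sum_i m_i

with eigenvalues l1 >= l2 >= l3 (nm^2) and Rg^2 = l1 + l2 + l3. A droplet is
mapped onto an ellipsoid of the same shape: instantaneous semi-axes use the
uniform-density convention a_hat = sqrt(5 l), and the per-frame normalized
semi-axes satisfy a*b*c = R^3 where R is the droplet's mean radius — so the
shape-fluctuation statistics fed to the surface-tension estimator are
independent of the sqrt(5) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregates import (
    PHASE_DENSE,
    ClusterAssignment,
    min_chain_distance,
    minimum_image_displacement,
)
from .model_io import BeadSystem


class DegenerateShapeError(ValueError):
    """An operation required strictly positive gyration eigenvalues."""


@dataclass(frozen=True)
class GyrationResult:
    tensor: np.ndarray          # 3x3, nm^2
    eigenvalues: np.ndarray     # descending, nm^2
    eigenvectors: np.ndarray    # columns match eigenvalues
    rg: float                   # nm

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue (sign arbitrary)."""
        return self.eigenvectors[:, 0]


@dataclass(frozen=True)
class EllipsoidAxes:
    """Volume-normalized ellipsoid semi-axes (a >= b >= c, abc = R^3)."""

    a: float
    b: float
    c: float
    R: float

    @property
    def deltas(self) -> tuple[float, float, float]:
        return (self.a - self.R, self.b - self.R, self.c - self.R)


def gyration_tensor(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
    weighted: bool = True,
) -> GyrationResult:
    """Mass-weighted gyration tensor of a bead cloud (coordinates in nm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must be (n_beads, 3) with n_beads >= 1")
    if masses is None or not weighted:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = masses @ coords / total
    centered = coords - com
    tensor = np.einsum("i,ia,ib->ab", masses, centered, centered) / total
    eigvals, eigvecs = np.linalg.eigh(tensor)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    return GyrationResult(
        tensor=tensor,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        rg=float(np.sqrt(eigvals.sum())),
    )


def instantaneous_semi_axes(eigenvalues: np.ndarray) -> np.ndarray:
    """Semi-axes sqrt(5 l) of the uniform ellipsoid with these eigenvalues."""
    return np.sqrt(5.0 * np.asarray(eigenvalues, dtype=float))


def ellipsoid_axes(eigenvalues: Sequence[float], R: float) -> EllipsoidAxes:
    """Shape-only semi-axes scaled so that a*b*c = R^3 exactly.

        a = R l1^{1/3} / (l2 l3)^{1/6}   (and cyclically for b, c)

    Only eigenvalue ratios enter, so any overall scale convention on the
    eigenvalues cancels.
    """
    l1, l2, l3 = (float(x) for x in eigenvalues)
    if min(l1, l2, l3) <= 0:
        raise DegenerateShapeError(f"eigenvalues must be positive, got {eigenvalues}")
    if R <= 0:
        raise ValueError("R must be positive")
    a = R * l1 ** (1 / 3) / (l2 * l3) ** (1 / 6)
    b = R * l2 ** (1 / 3) / (l1 * l3) ** (1 / 6)
    c = R * l3 ** (1 / 3) / (l1 * l2) ** (1 / 6)
    return EllipsoidAxes(a=a, b=b, c=c, R=R)


def mean_droplet_radius(eigenvalues_per_frame: Iterable[Sequence[float]]) -> float:
    """Time-averaged droplet radius R = <(a_hat b_hat c_hat)^{1/3}>.

    Instantaneous semi-axes use the uniform-ellipsoid convention
    a_hat = sqrt(5 l); the geometric mean of the three is averaged
    arithmetically over frames.
    """
    radii = []
    for eigs in eigenvalues_per_frame:
        axes = instantaneous_semi_axes(eigs)
        if np.any(axes <= 0):
            raise DegenerateShapeError("zero eigenvalue in a droplet frame")
        radii.append(float(np.prod(axes) ** (1 / 3)))
    if not radii:
        raise ValueError("need at least one frame")
    return float(np.mean(radii))


def axes_series(eigenvalues_per_frame: Sequence[Sequence[float]]) -> tuple[float, list[EllipsoidAxes]]:
    """Mean radius and per-frame volume-normalized semi-axes for one droplet."""
    R = mean_droplet_radius(eigenvalues_per_frame)
    return R, [ellipsoid_axes(eigs, R) for eigs in eigenvalues_per_frame]


# -----------------------------------------------------------------------------
# unwrapping helpers (periodic boxes)
# -----------------------------------------------------------------------------

def make_chain_whole(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps along a chain by minimum-image continuation."""
    coords = np.asarray(coords, dtype=float).copy()
    steps = minimum_image_displacement(np.diff(coords, axis=0), box)
    coords[1:] = coords[0] + np.cumsum(steps, axis=0)
    return coords


def droplet_coords(
    system: BeadSystem,
    frame: int,
    chains: Sequence[int],
    use_pbc: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped coordinates and masses of a droplet's beads.

    Each chain is first made whole, then chains are assembled across the
    periodic boundary by minimum-image growth from the largest chain: every
    subsequent chain is shifted by whole box vectors so its center sits in
    the image nearest the running center of mass of the chains placed so far.
    Assumes the droplet is smaller than half the box in each direction.
    """
    box = system.box[frame]
    chains = sorted(chains, key=lambda c: -len(system.chain_indices(c)))
    parts, masses = [], []
    for c in chains:
        xyz = system.chain_coords(frame, c)
        m = system.chain_masses(c)
        if use_pbc:
            xyz = make_chain_whole(xyz, box)
        if parts:
            placed = np.concatenate(parts)
            ref = placed.mean(axis=0)
            if use_pbc:
                center = xyz.mean(axis=0)
                shift = minimum_image_displacement(center - ref, box) - (center - ref)
                xyz = xyz + shift
        parts.append(xyz)
        masses.append(m)
    # order of output beads follows descending chain size; callers only use
    # the point cloud, not per-bead identity
    return np.concatenate(parts), np.concatenate(masses)


def chain_rg(system: BeadSystem, frame: int, chain: int, use_pbc: bool = True) -> float:
    """Mass-weighted radius of gyration of one chain in one frame, nm."""
    xyz = system.chain_coords(frame, chain)
    if use_pbc:
        xyz = make_chain_whole(xyz, system.box[frame])
    return gyration_tensor(xyz, system.chain_masses(chain)).rg


def chain_rg_by_phase(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    use_pbc: bool = True,
) -> pd.DataFrame:
    """One Rg sample per chain per frame, labelled with its phase."""
    rows = []
    for assignment in assignments:
        f = assignment.frame_index
        for chain, phase in assignment.phase_label.items():
            rows.append(
                {"frame": f, "time_ps": system.time[f], "chain": chain,
                 "phase": phase, "rg_nm": chain_rg(system, f, chain, use_pbc)}
            )
    return pd.DataFrame(rows, columns=["frame", "time_ps", "chain", "phase", "rg_nm"])


# -----------------------------------------------------------------------------
# RMSD
# -----------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(coords: np.ndarray, ref: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two conformations, optionally after optimal superposition."""
    P = np.asarray(coords, dtype=float)
    Q = np.asarray(ref, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"conformation shapes differ: {P.shape} vs {Q.shape}")
    if superpose:
        P = P - P.mean(axis=0)
        Q = Q - Q.mean(axis=0)
        P = P @ kabsch_rotation(P, Q).T
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))


# -----------------------------------------------------------------------------
# orientation angles
# -----------------------------------------------------------------------------

def axis_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two sign-ambiguous axes, folded to [0, 90] degrees."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cosang = abs(float(u @ v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def neighbour_orientation_angles(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    neighbour_cutoff: float = 0.8,
    use_pbc: bool = True,
) -> pd.DataFrame:
    """Angles between major gyration axes of nearest-neighbour droplet chains.

    For every chain in a dense cluster the nearest neighbour is the cluster
    chain at minimum approach distance, required to be below the cutoff.
    Each unordered pair is counted once per frame. Angles are folded to
    [0, 90] degrees because principal axes carry no sign.
    """
    rows = []
    for assignment in assignments:
        f = assignment.frame_index
        for cluster in assignment.dense_clusters():
            axes = {}
            for c in cluster:
                xyz = system.chain_coords(f, c)
                if use_pbc:
                    xyz = make_chain_whole(xyz, system.box[f])
                axes[c] = gyration_tensor(xyz, system.chain_masses(c)).principal_axis
            pairs = set()
            for c in cluster:
                others = [o for o in cluster if o != c]
                dists = [min_chain_distance(system, f, c, o, use_pbc) for o in others]
                k = int(np.argmin(dists))
                if dists[k] < neighbour_cutoff:
                    pairs.add(tuple(sorted((c, others[k]))))
            for i, j in sorted(pairs):
                rows.append(
                    {"frame": f, "chain_i": i, "chain_j": j,
                     "angle_deg": axis_angle_deg(axes[i], axes[j])}
                )
    return pd.DataFrame(rows, columns=["frame", "chain_i", "chain_j", "angle_deg"])
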