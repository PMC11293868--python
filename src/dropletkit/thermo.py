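"""Phase thermodynamics and transport.

Covers droplet volumes from gyration eigenvalues, dense/dilute phase
concentrations, the excess free energy of chain transfer between the phases,
surface tension from thermal fluctuations of the droplet's ellipsoidal
semi-axes (quadrupolar l=2 modes), dilute-phase concentration time series,
and mean squared displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .aggregates import PHASE_DENSE, PHASE_DILUTE, ClusterAssignment
from .constants import (
    DEFAULT_TEMPERATURE,
    JOULE_PER_M2_TO_MN_PER_M,
    K_BOLTZMANN,
    R_GAS,
    concentration_micromolar,
)
from .geometry import DegenerateShapeError, EllipsoidAxes
from .model_io import BeadSystem

#: droplet volume conventions: semi-axes sqrt(l) vs physical sqrt(5 l)
VOLUME_CONVENTIONS = ("sqrt-lambda", "sqrt-5-lambda")


def droplet_volume(eigenvalues: Sequence[float], convention: str = "sqrt-lambda") -> float:
    """Ellipsoid volume (nm^3) from gyration eigenvalues (nm^2).

    ``sqrt-lambda`` (default): V = (4 pi / 3) sqrt(l1 l2 l3).
    ``sqrt-5-lambda``: uniform-density physical semi-axes sqrt(5 l), i.e. the
    same expression multiplied by 5^{3/2} ~ 11.18. The choice shifts absolute
    concentrations but not the dense >> dilute contrast.
    """
    l1, l2, l3 = (float(x) for x in eigenvalues)
    if min(l1, l2, l3) <= 0:
        raise DegenerateShapeError(f"eigenvalues must be positive, got {eigenvalues}")
    v = 4.0 * np.pi / 3.0 * np.sqrt(l1 * l2 * l3)
    if convention == "sqrt-lambda":
        return v
    if convention == "sqrt-5-lambda":
        return v * 5.0 ** 1.5
    raise ValueError(f"unknown volume convention {convention!r}")


@dataclass
class PhaseConcentrations:
    """Dense and dilute phase concentrations for one frame (µM)."""

    frame_index: int
    c_dense_uM: float | None
    c_dilute_uM: float
    v_dense_total_nm3: float
    v_dilute_nm3: float
    n_dense: int
    n_dilute: int

    @property
    def ratio(self) -> float | None:
        if self.c_dense_uM is None or self.c_dilute_uM == 0:
            return None
        return self.c_dense_uM / self.c_dilute_uM


def phase_concentrations(
    system: BeadSystem,
    assignment: ClusterAssignment,
    frame: int | None = None,
    convention: str = "sqrt-lambda",
    use_pbc: bool = True,
) -> PhaseConcentrations:
    """Per-frame phase concentrations from the cluster assignment.

    Dense chains are counted against the summed ellipsoid volumes of their
    droplets (mass-weighted gyration tensors on unwrapped droplets); dilute
    chains against the remaining box volume. Chains in intermediate clusters
    (tetramers/pentamers) enter neither numerator. With no dense cluster the
    dense concentration is reported as missing (None), not zero.
    """
    if frame is None:
        frame = assignment.frame_index
    box_volume = float(np.prod(system.box[frame]))
    v_dense = 0.0
    n_dense = 0
    for cluster in assignment.dense_clusters():
        xyz, masses = geometry.droplet_coords(system, frame, cluster, use_pbc=use_pbc)
        eigs = geometry.gyration_tensor(xyz, masses).eigenvalues
        v_dense += droplet_volume(eigs, convention)
        n_dense += len(cluster)
    n_dilute = len(assignment.chains_in_phase(PHASE_DILUTE))
    v_dilute = max(box_volume - v_dense, 0.0)
    return PhaseConcentrations(
        frame_index=frame,
        c_dense_uM=concentration_micromolar(n_dense, v_dense) if n_dense else None,
        c_dilute_uM=concentration_micromolar(n_dilute, v_dilute) if v_dilute > 0 else 0.0,
        v_dense_total_nm3=v_dense,
        v_dilute_nm3=v_dilute,
        n_dense=n_dense,
        n_dilute=n_dilute,
    )


def delta_g_transfer(
    c_dilute: float,
    c_dense: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Excess free energy of moving a chain from the dense to the dilute
    phase: dG = R T ln(c_dilute / c_dense), kJ/mol. Negative when the dense
    phase is favoured."""
    if c_dilute <= 0 or c_dense <= 0:
        raise ValueError("concentrations must be positive")
    return R_GAS * temperature * np.log(c_dilute / c_dense) / 1000.0


# -----------------------------------------------------------------------------
# surface tension from shape fluctuations
# -----------------------------------------------------------------------------

@dataclass
class SurfaceTensionEstimate:
    """Surface tension from the l=2 shape-fluctuation modes of a droplet.

        gamma20 = 5 kB T / (16 pi <(da + db)^2>)
        gamma22 = 15 kB T / (16 pi <(da - db)^2>)

    where da = a - R etc. and the pair mean squares average the three
    unordered semi-axis pairs: <(da +/- db)^2> = (1/3) sum_{i<j} <(d_i +/- d_j)^2>.
    Reported in mN/m; a rigid droplet (zero fluctuation) yields infinity.
    """

    gamma20_mN_m: float
    gamma22_mN_m: float
    mean_sq_sum_nm2: float
    mean_sq_diff_nm2: float
    n_frames: int
    temperature: float

    @property
    def rigid(self) -> bool:
        return np.isinf(self.gamma20_mN_m) or np.isinf(self.gamma22_mN_m)


def _pair_mean_squares(deltas: np.ndarray) -> tuple[float, float]:
    pairs = [(0, 1), (0, 2), (1, 2)]
    msum = float(np.mean([np.mean((deltas[:, i] + deltas[:, j]) ** 2) for i, j in pairs]))
    mdiff = float(np.mean([np.mean((deltas[:, i] - deltas[:, j]) ** 2) for i, j in pairs]))
    return msum, mdiff


def surface_tension(
    droplet_frames: Sequence[EllipsoidAxes],
    temperature: float = DEFAULT_TEMPERATURE,
) -> SurfaceTensionEstimate:
    """Estimate surface tension from a persistent droplet's semi-axis series."""
    if len(droplet_frames) < 2:
        raise ValueError("need at least two frames of one droplet")
    deltas = np.array([axes.deltas for axes in droplet_frames])  # (n_frames, 3), nm
    msum, mdiff = _pair_mean_squares(deltas)
    kbt = K_BOLTZMANN * temperature

    def gamma(prefactor: float, mean_sq_nm2: float) -> float:
        if mean_sq_nm2 <= 0:
            return float("inf")
        return prefactor * kbt / (16.0 * np.pi * mean_sq_nm2 * 1e-18) * JOULE_PER_M2_TO_MN_PER_M

    return SurfaceTensionEstimate(
        gamma20_mN_m=gamma(5.0, msum),
        gamma22_mN_m=gamma(15.0, mdiff),
        mean_sq_sum_nm2=msum,
        mean_sq_diff_nm2=mdiff,
        n_frames=len(droplet_frames),
        temperature=temperature,
    )


def track_droplets(
    assignments: Sequence[ClusterAssignment],
    min_frames: int = 2,
) -> list[list[tuple[int, list[int]]]]:
    """Persistent droplet segments across frames by maximal membership overlap.

    A dense cluster in frame f continues the frame f-1 droplet with which it
    shares the most chains, provided that droplet is not claimed by a larger
    overlap and the overlap is unique in both directions (merges and splits
    terminate fluctuation segments). Returns segments as lists of
    (frame_index, member chain ids).
    """
    segments: list[list[tuple[int, list[int]]]] = []
    active: list[list[tuple[int, list[int]]]] = []
    for assignment in assignments:
        f = assignment.frame_index
        clusters = assignment.dense_clusters()
        prev = [seg[-1][1] for seg in active]
        # overlap matrix between active segments and current dense clusters
        claims: dict[int, list[int]] = {}
        for ci, cluster in enumerate(clusters):
            overlaps = [len(set(cluster) & set(p)) for p in prev]
            if overlaps and max(overlaps) > 0:
                claims.setdefault(int(np.argmax(overlaps)), []).append(ci)
        next_active: list[list[tuple[int, list[int]]]] = []
        matched_clusters = set()
        for si, seg in enumerate(active):
            owners = claims.get(si, [])
            if len(owners) == 1:
                ci = owners[0]
                # the cluster must not also best-match another segment
                cluster = clusters[ci]
                best_seg = int(np.argmax([len(set(cluster) & set(p)) for p in prev]))
                if best_seg == si and ci not in matched_clusters:
                    seg.append((f, cluster))
                    next_active.append(seg)
                    matched_clusters.add(ci)
                    continue
            segments.append(seg)  # terminated (split, merge, or vanished)
        for ci, cluster in enumerate(clusters):
            if ci not in matched_clusters:
                next_active.append([(f, cluster)])
        active = next_active
    segments.extend(active)
    return [seg for seg in segments if len(seg) >= min_frames]


def droplet_surface_tensions(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    temperature: float = DEFAULT_TEMPERATURE,
    min_droplet_frames: int = 10,
    use_pbc: bool = True,
) -> list[SurfaceTensionEstimate]:
    """Per-droplet surface tensions over tracked persistent droplets."""
    estimates = []
    for segment in track_droplets(assignments, min_frames=min_droplet_frames):
        eigs_per_frame = []
        for frame, chains in segment:
            xyz, masses = geometry.droplet_coords(system, frame, chains, use_pbc=use_pbc)
            eigs = geometry.gyration_tensor(xyz, masses).eigenvalues
            if np.any(eigs <= 0):
                continue
            eigs_per_frame.append(eigs)
        if len(eigs_per_frame) >= 2:
            _, axes = geometry.axes_series(eigs_per_frame)
            estimates.append(surface_tension(axes, temperature))
    return estimates


def pooled_surface_tension(estimates: Sequence[SurfaceTensionEstimate]) -> dict:
    """Two pooled summaries: unweighted per-droplet mean, and frame-pooled."""
    finite = [e for e in estimates if not e.rigid]
    if not finite:
        return {"per_droplet_mean_gamma20": None, "per_droplet_mean_gamma22": None,
                "pooled_gamma20": None, "pooled_gamma22": None}
    w = np.array([e.n_frames for e in finite], dtype=float)
    msum = float(np.average([e.mean_sq_sum_nm2 for e in finite], weights=w))
    mdiff = float(np.average([e.mean_sq_diff_nm2 for e in finite], weights=w))
    kbt = K_BOLTZMANN * finite[0].temperature
    return {
        "per_droplet_mean_gamma20": float(np.mean([e.gamma20_mN_m for e in finite])),
        "per_droplet_mean_gamma22": float(np.mean([e.gamma22_mN_m for e in finite])),
        "pooled_gamma20": 5.0 * kbt / (16 * np.pi * msum * 1e-18) * JOULE_PER_M2_TO_MN_PER_M,
        "pooled_gamma22": 15.0 * kbt / (16 * np.pi * mdiff * 1e-18) * JOULE_PER_M2_TO_MN_PER_M,
    }


# -----------------------------------------------------------------------------
# steady state and transport
# -----------------------------------------------------------------------------

def dilute_concentration_series(
    system: BeadSystem,
    assignments: Sequence[ClusterAssignment],
    convention: str = "sqrt-lambda",
    window: int = 5,
    use_pbc: bool = True,
) -> dict:
    """Per-frame dilute-phase concentration with a stationarity summary.

    The drift statistic is the difference between the last and first
    sliding-window means, normalized by the overall mean (0 for a static
    series; ~0 at steady state).
    """
    if system.n_frames < 2:
        raise ValueError("need at least two frames")
    conc = []
    for assignment in assignments:
        pc = phase_concentrations(system, assignment, convention=convention, use_pbc=use_pbc)
        conc.append(pc.c_dilute_uM)
    series = pd.Series(conc, dtype=float)
    window = min(window, len(series))
    rolling = series.rolling(window).mean().dropna()
    mean = float(series.mean())
    drift = float(rolling.iloc[-1] - rolling.iloc[0]) / mean if mean > 0 else 0.0
    return {
        "time_ps": system.time.tolist(),
        "c_dilute_uM": [float(c) for c in conc],
        "mean_uM": mean,
        "relative_drift": drift,
    }


def msd(
    coords: np.ndarray,
    max_lag: int | None = None,
) -> np.ndarray:
    """Mean squared displacement over lag times, nm^2.

    ``coords`` must be unwrapped positions of shape (n_frames, n_particles, 3)
    at uniform frame spacing. MSD(tau) averages over all particles and all
    time origins; MSD(0) = 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ValueError("coords must be (n_frames, n_particles, 3)")
    n_frames = coords.shape[0]
    if max_lag is None:
        max_lag = n_frames // 2
    max_lag = min(max_lag, n_frames - 1)
    out = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = coords[lag:] - coords[:-lag]
        out[lag] = float(np.mean(np.einsum("fpk,fpk->fp", disp, disp)))
    return out


def msd_system(system: BeadSystem, max_lag: int | None = None) -> np.ndarray:
    """MSD of all beads of a BeadSystem; refuses wrapped trajectories."""
    if system.wrapped:
        raise ValueError(
            "MSD requires unwrapped coordinates: periodic jumps in wrapped "
            "trajectories corrupt displacements; load with wrapped=False "
            "after unwrapping upstream"
        )
    return msd(system.coords, max_lag=max_lag)


def fit_diffusion(msd_curve: np.ndarray, dt: float, fit_slice: slice | None = None) -> float:
    """Diffusion coefficient from the Einstein relation MSD = 6 D tau.

    ``dt`` is the time per lag step; the fit is a least-squares line over
    the chosen lag window (default: lags 1..end), D = slope / 6.
    """
    msd_curve = np.asarray(msd_curve, dtype=float)
    if fit_slice is None:
        fit_slice = slice(1, len(msd_curve))
    lags = np.arange(len(msd_curve))[fit_slice] * dt
    values = msd_curve[fit_slice]
    slope = stats.linregress(lags, values).slope
    return float(slope / 6.0)
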