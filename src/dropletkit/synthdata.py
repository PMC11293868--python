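"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the statistical structure the analyses assume — a cubic
periodic box with a quasi-ellipsoidal droplet of connected chains plus
dispersed free monomers, droplet shape fluctuations of prescribed
amplitude, freely rotating chains of controllable stiffness, Brownian
tracers, and reference graphs — without any physical dynamics. Everything is
fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .aggregates import PHASE_DENSE, PHASE_DILUTE, minimum_image_displacement
from .constants import CONTACT_CUTOFF_NM, DEFAULT_BEAD_MASS
from .geometry import gyration_tensor
from .model_io import BeadSystem


class PackingError(RuntimeError):
    """Rejection sampling could not place a chain within the retry cap."""


# -----------------------------------------------------------------------------
# chains
# -----------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a unit vector from a von Mises-Fisher distribution around mu."""
    if np.isinf(kappa):
        return mu
    if kappa <= 0:
        v = rng.normal(size=3)
        return _unit(v)
    u = rng.random()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around mu
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(mu, helper))
    e2 = np.cross(mu, e1)
    s = np.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def gen_chain(
    n_beads: int,
    bond_length: float = 0.38,
    stiffness: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """A freely rotating chain with fixed bond length and tunable stiffness.

    Each bond direction is drawn from a von Mises-Fisher distribution around
    the previous direction with concentration ``stiffness``; 0 gives an ideal
    random walk and infinity a straight rod. Returns (n_beads, 3) nm,
    starting at the origin.
    """
    if n_beads < 2:
        raise ValueError("a chain needs at least 2 beads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.zeros((n_beads, 3))
    direction = _unit(rng.normal(size=3))
    for k in range(1, n_beads):
        coords[k] = coords[k - 1] + bond_length * direction
        direction = _unit(_sample_vmf(direction, stiffness, rng))
    return coords


def rod_rg(n_beads: int, bond_length: float) -> float:
    """Closed-form Rg of a straight discrete rod of equal-mass beads."""
    return bond_length * np.sqrt((n_beads**2 - 1) / 12.0)


# -----------------------------------------------------------------------------
# droplet systems
# -----------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Parameters of a synthetic phase-separated bead system."""

    n_chains_dense: int = 10
    n_chains_dilute: int = 5
    beads_per_chain: int = 20
    bond_length: float = 0.38
    stiffness: float = 2.0
    droplet_axes: tuple[float, float, float] = (4.0, 4.0, 4.0)
    box_edge: float = 25.0
    n_frames: int = 1
    jitter_sigma: float = 0.0
    contact_cutoff: float = CONTACT_CUTOFF_NM
    mass_mode: Literal["uniform", "heterogeneous"] = "uniform"
    seed: int = 0
    retry_cap: int = 100_000

    def __post_init__(self) -> None:
        if max(self.droplet_axes) * 2 >= self.box_edge:
            raise ValueError("droplet must fit inside the box")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Construction labels emitted alongside a synthetic system."""

    phase: dict[int, str]
    droplet_chains: list[int]
    droplet_center: np.ndarray
    droplet_axes: tuple[float, float, float]

    def as_dict(self) -> dict:
        return {
            "phase": {str(k): v for k, v in self.phase.items()},
            "droplet_chains": self.droplet_chains,
            "droplet_center": self.droplet_center.tolist(),
            "droplet_axes": list(self.droplet_axes),
        }


def _min_dist_sq(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    delta = minimum_image_displacement(a[:, None, :] - b[None, :, :], box)
    return float(np.einsum("ijk,ijk->ij", delta, delta).min())


def gen_droplet_system(spec: SynthSpec) -> tuple[BeadSystem, GroundTruth]:
    """A box with one connected droplet plus well-separated free monomers.

    Dense chains have centers inside the prescribed ellipsoid and each is
    placed within the contact cutoff of a previously placed dense chain, so
    the droplet is a single connected cluster by construction. Dilute chains
    keep pairwise minimum distances above twice the cutoff from everything.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.full(3, float(spec.box_edge))
    center = box / 2.0
    axes = np.asarray(spec.droplet_axes, dtype=float)
    cutoff = spec.contact_cutoff
    margin = 4.0 * spec.jitter_sigma

    chains: list[np.ndarray] = []
    labels: dict[int, str] = {}

    def place_chain() -> np.ndarray:
        xyz = gen_chain(spec.beads_per_chain, spec.bond_length, spec.stiffness, rng)
        return xyz - xyz.mean(axis=0)

    # dense chains: centers uniform in the ellipsoid; whole configurations
    # are resampled until the contact graph is one connected cluster, so the
    # droplet both fills the prescribed volume and is connected by
    # construction
    dense: list[np.ndarray] = []
    if spec.n_chains_dense == 1:
        u = rng.normal(size=3)
        dense = [place_chain() + center + axes * (_unit(u) * rng.random() ** (1 / 3))]
    elif spec.n_chains_dense > 1:
        config_cap = max(1, spec.retry_cap // 100)
        for _ in range(config_cap):
            candidate = []
            for _ in range(spec.n_chains_dense):
                u = rng.normal(size=3)
                point = center + axes * (_unit(u) * rng.random() ** (1 / 3))
                candidate.append(place_chain() + point)
            m = spec.n_chains_dense
            adj = np.zeros((m, m), dtype=bool)
            for i in range(m):
                for j in range(i + 1, m):
                    d2 = _min_dist_sq(candidate[i], candidate[j], box)
                    adj[i, j] = adj[j, i] = d2 < (cutoff - margin) ** 2
            # single-component check via boolean reachability
            reach = adj.copy()
            np.fill_diagonal(reach, True)
            for _ in range(m):
                reach = reach | (reach @ reach)
            if reach.all():
                dense = candidate
                break
        else:
            raise PackingError(
                f"no connected configuration of {spec.n_chains_dense} dense "
                f"chains in ellipsoid {tuple(axes)} after {config_cap} tries"
            )
    chains.extend(dense)
    labels.update({i: PHASE_DENSE for i in range(spec.n_chains_dense)})

    # dilute chains, isolated by construction
    exclusion = max(axes) + spec.beads_per_chain * spec.bond_length + 2 * cutoff
    dilute: list[np.ndarray] = []
    for i in range(spec.n_chains_dilute):
        for _ in range(spec.retry_cap):
            point = rng.random(3) * box
            if np.linalg.norm(minimum_image_displacement(point - center, box)) < exclusion:
                continue
            xyz = place_chain() + point
            ok = all(
                _min_dist_sq(xyz, other, box) > (2 * cutoff + margin) ** 2
                for other in dilute + dense
            )
            if ok:
                dilute.append(xyz)
                break
        else:
            raise PackingError(f"could not place dilute chain {i}")
    chains.extend(dilute)
    labels.update(
        {spec.n_chains_dense + i: PHASE_DILUTE for i in range(spec.n_chains_dilute)}
    )

    n_chains = len(chains)
    coords0 = np.concatenate(chains)
    n_beads = coords0.shape[0]
    frames = np.empty((spec.n_frames, n_beads, 3))
    for f in range(spec.n_frames):
        jitter = (
            rng.normal(0.0, spec.jitter_sigma, size=(n_beads, 3))
            if spec.jitter_sigma > 0
            else 0.0
        )
        frames[f] = coords0 + jitter

    if spec.mass_mode == "uniform":
        masses = np.full(n_beads, DEFAULT_BEAD_MASS)
    else:
        masses = rng.choice([36.0, 54.0, 72.0], size=n_beads)

    system = BeadSystem(
        coords=frames,
        chain_id=np.repeat(np.arange(n_chains), spec.beads_per_chain),
        residue_index=np.tile(np.arange(1, spec.beads_per_chain + 1), n_chains),
        mass=masses,
        box=np.tile(box, (spec.n_frames, 1)),
        time=np.arange(spec.n_frames, dtype=float),
        wrapped=False,
    )
    truth = GroundTruth(
        phase=labels,
        droplet_chains=list(range(spec.n_chains_dense)),
        droplet_center=center,
        droplet_axes=tuple(axes),
    )
    return system, truth


# -----------------------------------------------------------------------------
# fluctuating ellipsoid droplets
# -----------------------------------------------------------------------------

def _uniform_ball(n: int, rng: np.random.Generator) -> np.ndarray:
    g = rng.normal(size=(n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g * (rng.random(n) ** (1 / 3))[:, None]


def _sobol_ball(n: int, seed) -> np.ndarray:
    """Scrambled low-discrepancy uniform fill of the unit ball."""
    import warnings

    from scipy.stats import qmc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n need not be a power of two
        u = qmc.Sobol(d=3, scramble=True, seed=seed).random(n)
    r = u[:, 0] ** (1 / 3)
    cos_t = 1.0 - 2.0 * u[:, 1]
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * np.pi * u[:, 2]
    return np.column_stack((r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t))


@dataclass
class FluctuatingEllipsoid:
    """A droplet whose semi-axes fluctuate around a mean radius R.

    Per frame, semi-axes are drawn as R + delta with delta i.i.d. Gaussian
    (sd = ``fluct_sigma``) and then renormalized so that a b c = R^3
    (volume-conserving shape fluctuation); beads fill the ellipsoid
    uniformly. ``true_axes`` holds the post-renormalization semi-axes sorted
    descending — the construction ground truth the analysis should recover.

    ``fill_mode="affine-sobol"`` (default) draws one scrambled
    low-discrepancy fill of the unit ball and deforms it affinely with the
    per-frame shape — the beads behave as material points of the deforming
    droplet and the recovered shape is limited by the prescribed
    fluctuations, not by bead shot noise. ``fill_mode="resample-random"``
    redraws an independent uniform fill every frame, adding realistic
    finite-sampling noise. Frames are generated lazily so long trajectories
    stay cheap.
    """

    R: float
    fluct_sigma: float
    n_frames: int
    n_beads: int
    seed: int
    fill_mode: Literal["affine-sobol", "resample-random"] = "affine-sobol"
    random_orientation: bool = False
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    true_axes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.fluct_sigma >= self.R / 3:
            raise ValueError("fluct_sigma must be < R/3")
        rng = np.random.default_rng([self.seed, 0])
        axes = self.R + rng.normal(0.0, self.fluct_sigma, size=(self.n_frames, 3))
        axes = np.clip(axes, 0.05 * self.R, None)
        scale = self.R / np.cbrt(axes.prod(axis=1))
        axes *= scale[:, None]
        self.true_axes = -np.sort(-axes, axis=1)
        self._base_fill = (
            _sobol_ball(self.n_beads, np.random.default_rng([self.seed, 2]))
            if self.fill_mode == "affine-sobol"
            else None
        )

    @property
    def true_deltas(self) -> np.ndarray:
        return self.true_axes - self.R

    def frame_coords(self, frame: int) -> np.ndarray:
        """Beads uniformly filling the frame's ellipsoid, (n_beads, 3) nm."""
        if self._base_fill is not None:
            pts = self._base_fill * self.true_axes[frame]
        else:
            rng = np.random.default_rng([self.seed, 1 + frame])
            pts = _uniform_ball(self.n_beads, rng) * self.true_axes[frame]
        if self.random_orientation:
            from scipy.stats import special_ortho_group

            rot = special_ortho_group.rvs(3, random_state=np.random.default_rng([self.seed, 10_000 + frame]))
            pts = pts @ rot.T
        return pts + self.center

    def eigenvalue_series(self, masses: np.ndarray | None = None) -> np.ndarray:
        """Per-frame mass-weighted gyration eigenvalues, (n_frames, 3) nm^2."""
        out = np.empty((self.n_frames, 3))
        for f in range(self.n_frames):
            out[f] = gyration_tensor(self.frame_coords(f), masses).eigenvalues
        return out


def gen_fluctuating_ellipsoid(
    R: float,
    fluct_sigma: float,
    n_frames: int,
    n_beads: int,
    seed: int = 0,
    fill_mode: Literal["affine-sobol", "resample-random"] = "affine-sobol",
    random_orientation: bool = False,
) -> FluctuatingEllipsoid:
    return FluctuatingEllipsoid(
        R=R,
        fluct_sigma=fluct_sigma,
        n_frames=n_frames,
        n_beads=n_beads,
        seed=seed,
        fill_mode=fill_mode,
        random_orientation=random_orientation,
    )


# -----------------------------------------------------------------------------
# Brownian tracers and reference graphs
# -----------------------------------------------------------------------------

def gen_brownian(
    n_particles: int,
    D: float,
    dt: float,
    n_steps: int,
    seed: int = 0,
) -> np.ndarray:
    """Unwrapped Brownian tracer trajectory, (n_steps + 1, n_particles, 3) nm.

    Per-axis displacement variance is 2 D dt (D in nm^2/ns, dt in ns).
    """
    if D < 0 or dt <= 0:
        raise ValueError("D must be >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_steps, n_particles, 3))
    coords = np.zeros((n_steps + 1, n_particles, 3))
    coords[1:] = np.cumsum(steps, axis=0)
    return coords


def gen_reference_graphs(kind: str, params: dict, seed: int | None = None) -> nx.Graph:
    """Standard reference graph constructions with recorded parameters."""
    if kind == "erdos-renyi":
        g = nx.gnm_random_graph(params["n"], params["m"], seed=seed)
    elif kind == "watts-strogatz":
        g = nx.connected_watts_strogatz_graph(
            params["n"], params["k"], params["p"], tries=1000, seed=seed
        )
    elif kind == "complete":
        g = nx.complete_graph(params["n"])
    elif kind == "path":
        g = nx.path_graph(params["n"])
    else:
        raise ValueError(f"unknown graph kind {kind!r}")
    g.graph.update(kind=kind, seed=seed, **params)
    return g
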