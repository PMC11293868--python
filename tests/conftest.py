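"""Shared fixtures: small hand-built bead systems and synthetic droplets."""

from __future__ import annotations

import numpy as np
import pytest

from dropletkit.model_io import BeadSystem
from dropletkit.synthdata import SynthSpec, gen_droplet_system


def make_system(
    chain_coords: list[np.ndarray],
    box_edge: float = 10.0,
    n_frames: int | None = None,
    masses: np.ndarray | None = None,
    times: np.ndarray | None = None,
    wrapped: bool = False,
) -> BeadSystem:
    """Build a BeadSystem from per-chain coordinate arrays.

    Each entry of ``chain_coords`` is (n_beads, 3) for a single frame, or
    (n_frames, n_beads, 3) for a multi-frame chain.
    """
    arrays = [
        np.asarray(c, dtype=float)[None] if np.asarray(c).ndim == 2 else np.asarray(c, dtype=float)
        for c in chain_coords
    ]
    nf = arrays[0].shape[0] if n_frames is None else n_frames
    coords = np.concatenate([a for a in arrays], axis=1)
    chain_id = np.concatenate(
        [np.full(a.shape[1], i, dtype=int) for i, a in enumerate(arrays)]
    )
    residue_index = np.concatenate(
        [np.arange(1, a.shape[1] + 1) for a in arrays]
    )
    n_beads = coords.shape[1]
    if masses is None:
        masses = np.full(n_beads, 72.0)
    return BeadSystem(
        coords=coords,
        chain_id=chain_id,
        residue_index=residue_index,
        mass=masses,
        box=np.full((nf, 3), box_edge),
        time=np.arange(nf, dtype=float) if times is None else np.asarray(times, dtype=float),
        wrapped=wrapped,
    )


@pytest.fixture(scope="session")
def droplet_fixture():
    """10 dense + 5 dilute chains: one connected droplet by construction."""
    spec = SynthSpec(n_chains_dense=10, n_chains_dilute=5, seed=42)
    return gen_droplet_system(spec)


def random_chain_system(
    rng: np.random.Generator,
    n_chains: int,
    n_beads: int,
    box_edge: float,
    spread: float = 1.0,
) -> BeadSystem:
    """Chains as random blobs at random positions in a periodic box."""
    chains = []
    for _ in range(n_chains):
        center = rng.random(3) * box_edge
        chains.append(center + rng.normal(0.0, spread, size=(n_beads, 3)))
    return make_system(chains, box_edge=box_edge)
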