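"""Exact system-setup arithmetic and force-field parameter transforms.

Box sizing from a target protein concentration, crowder and ion counts with
exact electroneutrality, the lambda-scaled water-protein Lennard-Jones
transform used to tune coarse-grained IDP solvation, and the purely
repulsive crowder potential.

Rounding conventions: the crowder count rounds to the nearest integer; ion
counts floor the salt term and then add the exact integer neutralization.
Volumes are the analytic a^3 = N / (N_A C) value, not a printed or
post-equilibration box edge.
"""

from __future__ import annotations

import datetime
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

from .constants import N_AVOGADRO, NM3_TO_LITRE
from .seqprop import SequenceRecord

LITRE_TO_NM3 = 1.0 / NM3_TO_LITRE

#: volume of one fullerene-based crowder bead cluster, nm^3
CROWDER_VOLUME_NM3 = 0.55


def box_volume_nm3(n_chains: int, conc_molar: float) -> float:
    """Cubic box volume holding ``n_chains`` at a molar concentration, nm^3."""
    if n_chains <= 0 or conc_molar <= 0:
        raise ValueError("chain count and concentration must be positive")
    return n_chains / (N_AVOGADRO * conc_molar) * LITRE_TO_NM3


def box_edge(n_chains: int, conc_molar: float) -> float:
    """Cubic box edge a = (N / (N_A C))^{1/3}, nm."""
    return box_volume_nm3(n_chains, conc_molar) ** (1.0 / 3.0)


def crowder_count(
    volume_fraction: float,
    box_volume: float,
    crowder_volume: float = CROWDER_VOLUME_NM3,
) -> int:
    """Number of crowders filling a volume fraction of the box (nearest int)."""
    if not 0 <= volume_fraction < 1:
        raise ValueError("volume fraction must be in [0, 1)")
    return round(volume_fraction * box_volume / crowder_volume)


def ion_counts(
    salt_conc_molar: float,
    box_volume: float,
    n_chains: int,
    net_charge_per_chain: int,
) -> tuple[int, int]:
    """(n_na, n_cl): floor(salt) ion pairs plus exact neutralization.

    The total charge n_na - n_cl + n_chains * net_charge_per_chain is zero.
    """
    if salt_conc_molar < 0:
        raise ValueError("salt concentration must be non-negative")
    n_salt = math.floor(salt_conc_molar * N_AVOGADRO * box_volume * NM3_TO_LITRE)
    total_charge = n_chains * net_charge_per_chain
    n_na = n_salt + max(0, -total_charge)
    n_cl = n_salt + max(0, total_charge)
    return n_na, n_cl


def net_charge(seq: SequenceRecord | str, ph_model: str = "neutral-His") -> int:
    """Integer net charge (#K + #R) - (#D + #E); His neutral, termini cancel."""
    if ph_model != "neutral-His":
        raise ValueError(f"unknown pH model {ph_model!r}")
    if isinstance(seq, str):
        seq = SequenceRecord(id="query", sequence=seq)
    s = seq.sequence
    return (s.count("K") + s.count("R")) - (s.count("D") + s.count("E"))


@dataclass(frozen=True)
class SystemPlan:
    """Complete setup arithmetic for one multi-chain simulation box."""

    n_chains: int
    conc_protein_uM: float
    box_edge_nm: float
    box_volume_nm3: float
    n_crowders: int
    crowder_volume_nm3: float
    n_na: int
    n_cl: int
    salt_conc_mM: float
    net_charge_per_chain: int

    def __post_init__(self) -> None:
        if self.n_na - self.n_cl + self.n_chains * self.net_charge_per_chain != 0:
            raise ValueError("system plan violates electroneutrality")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_system_plan(
    n_chains: int,
    conc_protein_uM: float,
    salt_conc_mM: float = 0.0,
    crowder_volume_fraction: float = 0.0,
    sequence: SequenceRecord | str | None = None,
    net_charge_per_chain: int | None = None,
    crowder_volume: float = CROWDER_VOLUME_NM3,
) -> SystemPlan:
    """Assemble a SystemPlan from concentration targets and the chain sequence."""
    if net_charge_per_chain is None:
        if sequence is None:
            raise ValueError("provide either a sequence or net_charge_per_chain")
        net_charge_per_chain = net_charge(sequence)
    volume = box_volume_nm3(n_chains, conc_protein_uM * 1e-6)
    n_na, n_cl = ion_counts(salt_conc_mM * 1e-3, volume, n_chains, net_charge_per_chain)
    return SystemPlan(
        n_chains=n_chains,
        conc_protein_uM=conc_protein_uM,
        box_edge_nm=volume ** (1.0 / 3.0),
        box_volume_nm3=volume,
        n_crowders=crowder_count(crowder_volume_fraction, volume, crowder_volume),
        crowder_volume_nm3=crowder_volume,
        n_na=n_na,
        n_cl=n_cl,
        salt_conc_mM=salt_conc_mM,
        net_charge_per_chain=net_charge_per_chain,
    )


# -----------------------------------------------------------------------------
# Lennard-Jones transforms
# -----------------------------------------------------------------------------

@dataclass(frozen=True)
class LJParams:
    sigma: float                 # nm
    epsilon: float               # kJ/mol
    lambda_scale: float = 1.0
    gamma_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")


def scale_lj(params: LJParams, lambda_scale: float) -> LJParams:
    """Scale both sigma and epsilon by lambda (water-protein interaction tune)."""
    if lambda_scale <= 0:
        raise ValueError("lambda must be positive")
    return replace(
        params,
        sigma=params.sigma * lambda_scale,
        epsilon=params.epsilon * lambda_scale,
        lambda_scale=params.lambda_scale * lambda_scale,
    )


def repulsive_potential(
    r: float,
    sigma: float,
    epsilon: float,
    gamma_scale: float = 1.0,
) -> float:
    """Purely repulsive crowder-crowder potential V(r) = 4 gamma eps (sigma/r)^12."""
    if r <= 0:
        raise ValueError("r must be positive")
    return 4.0 * gamma_scale * epsilon * (sigma / r) ** 12


# -----------------------------------------------------------------------------
# parameter-table rescaling
# -----------------------------------------------------------------------------

class ParameterTableError(ValueError):
    """Malformed nonbonded parameter table."""


_NB_LINE = re.compile(
    r"^(\s*)(\S+)(\s+)(\S+)(\s+)(\d+)(\s+)([0-9.eE+-]+)(\s+)([0-9.eE+-]+)(\s*)$"
)


def scale_param_table(
    table_path: str | Path,
    out_path: str | Path,
    lambda_scale: float,
    selection: Callable[[str, str], bool],
) -> None:
    """Rescale selected rows of a nonbonded parameter table by lambda.

    The table is the standard coarse-grained force-field text layout:
    ``bead_i bead_j func sigma epsilon`` per row, with ``;`` comments and
    ``[ section ]`` headers. Only rows for which ``selection(bead_i, bead_j)``
    is true have sigma and epsilon multiplied by lambda; every other line is
    copied byte-identically. A header comment records lambda and the date.
    """
    table_path = Path(table_path)
    out_lines = [
        f"; rescaled by dropletkit: lambda={lambda_scale} date={datetime.date.today().isoformat()}\n"
    ]
    for lineno, line in enumerate(table_path.read_text().splitlines(keepends=True), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith((";", "#", "[")):
            out_lines.append(line)
            continue
        match = _NB_LINE.match(line.rstrip("\n"))
        if match is None:
            raise ParameterTableError(f"{table_path}:{lineno}: unparseable row: {stripped!r}")
        g = list(match.groups())
        bead_i, bead_j = g[1], g[3]
        if selection(bead_i, bead_j):
            try:
                sigma, epsilon = float(g[7]), float(g[9])
            except ValueError as exc:
                raise ParameterTableError(f"{table_path}:{lineno}: bad numbers") from exc
            g[7] = f"{sigma * lambda_scale:.6e}"
            g[9] = f"{epsilon * lambda_scale:.6e}"
            out_lines.append("".join(g) + "\n")
        else:
            out_lines.append(line if line.endswith("\n") else line + "\n")
    Path(out_path).write_text("".join(out_lines))


def water_protein_selection(water_beads: set[str]) -> Callable[[str, str], bool]:
    """Selection picking rows that pair a water bead with a non-water bead."""

    def _select(bead_i: str, bead_j: str) -> bool:
        return (bead_i in water_beads) != (bead_j in water_beads)

    return _select
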