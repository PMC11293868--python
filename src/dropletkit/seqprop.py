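"""Sequence-only LLPS propensity indicators.

Shannon entropy of the residue composition (low-complexity sequences score
low; uniform usage of all 20 amino acids scores ln 20) and mean
Kyte-Doolittle hydropathy (optionally min-max normalized from the raw scale
range [-4.5, 4.5] to [0, 1]) are simple primary-sequence correlates of
phase-separation propensity. A comparison harness ranks a query sequence
against user-supplied sets (e.g. high-propensity LLPS+, low-propensity
LLPS-, and folded PDB* datasets), optionally alongside externally computed
score columns such as PLAAC NLLR or catGRANULE, which are not reimplemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
KD_MIN, KD_MAX = -4.5, 4.5


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-canonical letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences from a FASTA file (uppercased)."""
    from Bio import SeqIO

    return [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def alpha_synuclein() -> SequenceRecord:
    """The packaged wild-type human alpha-synuclein sequence (140 residues)."""
    with resources.files("dropletkit.data").joinpath("alpha_synuclein.fasta").open() as fh:
        lines = fh.read().splitlines()
    return SequenceRecord(id=lines[0].lstrip(">").split()[0],
                          sequence="".join(lines[1:]).upper())


def shannon_entropy(seq: SequenceRecord | str, base: str = "e") -> float:
    """Shannon entropy H = -sum_i p_i log p_i of the residue composition.

    Positive by the standard convention; natural log by default, ``base="2"``
    for bits.
    """
    if isinstance(seq, str):
        seq = SequenceRecord(id="query", sequence=seq)
    _, counts = np.unique(list(seq.sequence), return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        h /= np.log(2.0)
    elif base != "e":
        raise ValueError(f"base must be 'e' or '2', got {base!r}")
    return h


def kd_hydropathy(seq: SequenceRecord | str, normalize: bool = True) -> float:
    """Mean Kyte-Doolittle hydropathy; min-max scaled to [0, 1] if requested."""
    if isinstance(seq, str):
        seq = SequenceRecord(id="query", sequence=seq)
    raw = float(np.mean([KYTE_DOOLITTLE[a] for a in seq.sequence]))
    if not normalize:
        return raw
    return (raw - KD_MIN) / (KD_MAX - KD_MIN)


DEFAULT_METRICS: dict[str, Callable] = {
    "shannon_entropy": shannon_entropy,
    "kd_hydropathy": kd_hydropathy,
}


def percentile_of(value: float, values: Sequence[float]) -> float:
    """Midrank percentile of a value within a set (ties count half)."""
    values = np.asarray(values, dtype=float)
    less = np.count_nonzero(values < value)
    equal = np.count_nonzero(values == value)
    return 100.0 * (less + 0.5 * equal) / len(values)


def compare_sets(
    query: SequenceRecord,
    sets: Mapping[str, Sequence[SequenceRecord]],
    metrics: Mapping[str, Callable] | None = None,
    external_scores: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    external_query: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Rank a query sequence against named sequence sets, per metric.

    ``external_scores`` may supply precomputed per-set score lists for
    metrics that are not computed here (e.g. PLAAC NLLR), with the query's
    value in ``external_query``.
    """
    if metrics is None:
        metrics = DEFAULT_METRICS
    rows = []
    for metric_name, fn in metrics.items():
        qval = fn(query)
        for set_name, records in sets.items():
            if not records:
                raise ValueError(f"sequence set {set_name!r} is empty")
            values = np.array([fn(r) for r in records])
            rows.append(_summary_row(metric_name, set_name, qval, values))
    for metric_name, per_set in (external_scores or {}).items():
        qval = (external_query or {}).get(metric_name, np.nan)
        for set_name, values in per_set.items():
            rows.append(_summary_row(metric_name, set_name, qval, np.asarray(values, dtype=float)))
    return pd.DataFrame(rows)


def _summary_row(metric: str, set_name: str, query_value: float, values: np.ndarray) -> dict:
    return {
        "metric": metric,
        "set": set_name,
        "n": len(values),
        "q25": float(np.quantile(values, 0.25)),
        "median": float(np.quantile(values, 0.5)),
        "q75": float(np.quantile(values, 0.75)),
        "query_value": float(query_value),
        "query_percentile": percentile_of(query_value, values) if np.isfinite(query_value) else np.nan,
    }
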