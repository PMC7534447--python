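"""Assembly summary statistics.

Computes the statistic bundle genome reports tabulate for each assembly:
total sequence, largest scaffold, scaffold count, N50, number of N bases,
number of gaps (maximal N-runs) and the soft-masked repeat fraction
(lowercase characters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import SequenceSet

__all__ = ["AssemblyStats", "nx", "compute_stats", "stats_table"]

_N_RUN = re.compile(r"[Nn]+")


@dataclass
class AssemblyStats:
    """Summary statistics for one assembly.

    repeat_fraction is the fraction of lowercase (soft-masked) characters;
    by convention the denominator includes N bases unless stats were
    computed with ``include_n_in_repeat_denominator=False``.
    """

    total_length: int
    largest: int
    n_scaffolds: int
    n50: int
    n_count: int
    gap_count: int
    repeat_fraction: float

    def as_dict(self) -> dict:
        return asdict(self)


def nx(lengths, x: float = 50) -> int:
    """Nx statistic: the largest length L in `lengths` such that sequences of
    length >= L together cover at least x% of the total.

    With lengths sorted descending and cumulated, Nx is the first length at
    which the running sum reaches x% of the total (the standard
    sorted-cumulative definition; N50 is x=50).
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("nx of an empty length list is undefined")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    threshold = x / 100.0 * sum(srt)
    cum = 0
    for length in srt:
        cum += length
        if cum >= threshold:
            return length
    return srt[-1]  # unreachable: cum == total >= threshold


def _char_counts(seq: str) -> tuple[int, int]:
    """(n_count, lowercase_count) via a byte scan."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_count = int(((arr == ord("N")) | (arr == ord("n"))).sum())
    lower = int(((arr >= ord("a")) & (arr <= ord("z"))).sum())
    return n_count, lower


def compute_stats(
    assembly: SequenceSet,
    min_gap_run: int = 1,
    include_n_in_repeat_denominator: bool = True,
) -> AssemblyStats:
    """Compute AssemblyStats for a SequenceSet.

    A gap is a maximal run of >= `min_gap_run` consecutive N/n characters
    (default 1; submission pipelines sometimes count only runs >= 10, so
    the threshold is a parameter).  repeat_fraction is lowercase characters
    over total characters; set ``include_n_in_repeat_denominator=False`` to
    exclude N bases from the denominator.
    """
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    if min_gap_run < 1:
        raise ValueError("min_gap_run must be >= 1")
    lengths = assembly.lengths
    total = sum(lengths)
    n_count = 0
    lower = 0
    gap_count = 0
    for _, seq in assembly:
        nc, lc = _char_counts(seq)
        n_count += nc
        lower += lc
        gap_count += sum(
            1 for m in _N_RUN.finditer(seq) if m.end() - m.start() >= min_gap_run
        )
    denom = total if include_n_in_repeat_denominator else total - n_count
    repeat_fraction = lower / denom if denom > 0 else 0.0
    return AssemblyStats(
        total_length=total,
        largest=max(lengths),
        n_scaffolds=len(assembly),
        n50=nx(lengths, 50),
        n_count=n_count,
        gap_count=gap_count,
        repeat_fraction=repeat_fraction,
    )


def stats_table(
    assemblies: list[tuple[str, SequenceSet]],
    min_gap_run: int = 1,
) -> pd.DataFrame:
    """One row of AssemblyStats per named assembly, in the order given."""
    if not assemblies:
        raise ValueError("need at least one assembly")
    names = [name for name, _ in assemblies]
    if len(set(names)) != len(names):
        raise ValueError("duplicate assembly names")
    rows = []
    for name, seqs in assemblies:
        row = compute_stats(seqs, min_gap_run=min_gap_run).as_dict()
        row = {"assembly": name, **row}
        rows.append(row)
    return pd.DataFrame(rows).set_index("assembly")
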