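"""Orthogroup sharing summaries and pan/core-genome rarefaction.

An orthogroup is "present" in a species when that species contributes at
least one gene to it.  The core genome of a set of species is the number
of orthogroups present in every member; the pan genome is the number
present in at least one.  Rarefaction evaluates core and pan over species
subsets of every size k; when the number of subsets C(n,k) exceeds a cap,
a seeded sample of distinct subsets is drawn without replacement.
Genes not assigned to any orthogroup take no part in these counts; they
enter only the gene-total denominators of the per-species summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import OrthogroupTable

__all__ = [
    "species_summary",
    "shared_orthogroups",
    "venn3_counts",
    "PanCoreCurve",
    "pan_core_curve",
]


def _check_species(table: OrthogroupTable, names: Sequence[str]) -> list[int]:
    cols = list(table.counts.columns)
    idx = []
    for name in names:
        if name not in cols:
            raise KeyError(f"unknown species {name!r}")
        idx.append(cols.index(name))
    return idx


def species_summary(table: OrthogroupTable) -> pd.DataFrame:
    """Per-species gene and orthogroup representation summary.

    Columns: gene_total, genes_in_orthogroups, orthogroups_represented,
    orthogroups_represented_pct, species_specific_orthogroups,
    genes_in_specific_pct.  gene_total and genes_in_specific_pct require
    the table's ``unassigned`` counts and are NaN when those are absent.
    """
    counts = table.counts
    pres = counts.to_numpy() > 0
    n_og = len(counts)
    rows = []
    for j, sp in enumerate(table.species):
        in_sp = pres[:, j]
        others = np.delete(pres, j, axis=1)
        specific = in_sp & ~others.any(axis=1)
        genes_in_og = int(counts.iloc[:, j].sum())
        genes_in_specific = int(counts.iloc[:, j].to_numpy()[specific].sum())
        if table.unassigned is not None and sp in table.unassigned:
            gene_total: Optional[int] = genes_in_og + table.unassigned[sp]
            specific_pct: Optional[float] = (
                100.0 * genes_in_specific / gene_total if gene_total else np.nan
            )
        else:
            gene_total = np.nan
            specific_pct = np.nan
        rows.append(
            {
                "species": sp,
                "gene_total": gene_total,
                "genes_in_orthogroups": genes_in_og,
                "orthogroups_represented": int(in_sp.sum()),
                "orthogroups_represented_pct": 100.0 * in_sp.sum() / n_og,
                "species_specific_orthogroups": int(specific.sum()),
                "genes_in_specific_pct": specific_pct,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def shared_orthogroups(table: OrthogroupTable, species_subset) -> int:
    """Number of orthogroups present in EVERY species of the subset
    (presence in other species is unrestricted)."""
    subset = list(species_subset)
    if len(set(subset)) < 2:
        raise ValueError("need at least two distinct species")
    idx = _check_species(table, subset)
    pres = table.counts.to_numpy() > 0
    return int(pres[:, idx].all(axis=1).sum())


def venn3_counts(table: OrthogroupTable, species: Sequence[str]) -> dict[str, int]:
    """Counts of orthogroups in the 7 presence/absence regions of three
    species (presence in any other species is ignored).

    Keys are '100', '010', '001', '110', '101', '011', '111' in the order
    of the species tuple given; the 7 regions partition the orthogroups
    present in at least one of the three.
    """
    species = list(species)
    if len(species) != 3 or len(set(species)) != 3:
        raise ValueError("need exactly three distinct species")
    idx = _check_species(table, species)
    pres = table.counts.to_numpy()[:, idx] > 0
    out: dict[str, int] = {}
    for a in (1, 0):
        for b in (1, 0):
            for c in (1, 0):
                if a == b == c == 0:
                    continue
                mask = (
                    (pres[:, 0] == bool(a))
                    & (pres[:, 1] == bool(b))
                    & (pres[:, 2] == bool(c))
                )
                out[f"{a}{b}{c}"] = int(mask.sum())
    return out


@dataclass
class PanCoreCurve:
    """Core/pan evaluations over species subsets of every size.

    ``samples[k]`` is a list of (subset_members, core, pan) tuples; the
    full per-subset distribution is retained so the rarefaction scatter
    can be reproduced, not just its means.
    """

    samples: dict[int, list[tuple[tuple[str, ...], int, int]]]
    exhaustive: dict[int, bool]
    cap: int
    seed: int

    def mean_core(self, k: int) -> float:
        return float(np.mean([c for _, c, _ in self.samples[k]]))

    def mean_pan(self, k: int) -> float:
        return float(np.mean([p for _, _, p in self.samples[k]]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.samples):
            for i, (members, core, pan) in enumerate(self.samples[k]):
                rows.append(
                    {
                        "k": k,
                        "subset_index": i,
                        "subset_members": ",".join(members),
                        "core": core,
                        "pan": pan,
                        "exhaustive": self.exhaustive[k],
                    }
                )
        return pd.DataFrame(rows)

    def closure_gap(self) -> float:
        """Pan-genome growth from k = n-1 to n (a small value indicates a
        closed pan genome; reported as a diagnostic, not a claim)."""
        n = max(self.samples)
        if n < 2:
            raise ValueError("need at least two species")
        return self.mean_pan(n) - self.mean_pan(n - 1)


def pan_core_curve(
    table: OrthogroupTable,
    cap: int = 1000,
    seed: int = 0,
) -> PanCoreCurve:
    """Pan/core rarefaction over all subset sizes k = 1..n_species.

    For each k, all C(n,k) subsets are enumerated when C(n,k) <= cap;
    otherwise `cap` DISTINCT subsets are sampled uniformly without
    replacement from a generator seeded with `seed` (rejection sampling
    with a seen-set).  Per subset: core = orthogroups present in all k
    members, pan = present in at least one.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    species = table.species
    n = len(species)
    if n < 2:
        raise ValueError("need at least two species")
    pres = table.counts.to_numpy() > 0
    rng = np.random.default_rng(seed)

    samples: dict[int, list[tuple[tuple[str, ...], int, int]]] = {}
    exhaustive: dict[int, bool] = {}
    for k in range(1, n + 1):
        total = comb(n, k)
        if total <= cap:
            subsets = [tuple(c) for c in combinations(range(n), k)]
            exhaustive[k] = True
        else:
            seen: set[tuple[int, ...]] = set()
            subsets = []
            while len(subsets) < cap:
                cand = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
                if cand in seen:
                    continue
                seen.add(cand)
                subsets.append(cand)
            exhaustive[k] = False
        evaluated = []
        for cols in subsets:
            sub = pres[:, list(cols)]
            core = int(sub.all(axis=1).sum())
            pan = int(sub.any(axis=1).sum())
            evaluated.append((tuple(species[j] for j in cols), core, pan))
        samples[k] = evaluated
    return PanCoreCurve(samples=samples, exhaustive=exhaustive, cap=cap, seed=seed)
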