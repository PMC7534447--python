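"""Rule-based contig decontamination and chromosome/scaffold renaming.

The contamination filter is a single non-iterative pass with strict rule
precedence:

1. a contig with at least one taxonomy hit is kept iff any hit description
   contains a keep keyword (case-insensitive substring by default),
   otherwise discarded;
2. a contig with no hits is kept if at least one of its predicted genes
   was assigned to an orthogroup of the reference clade;
3. the remaining contigs (no hits, no rescue) are kept iff their GC
   fraction falls inside mean +/- m*SD, where mean and SD are computed
   over the contigs kept by rules 1-2 and never updated afterwards.

Renaming mirrors the common chromosome-scale convention: the largest
`n_chromosomes` records become Chr1..ChrN in descending length order and
the remainder become four-digit-numbered scaffolds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import SequenceSet, TaxonomyEvidence

__all__ = [
    "ContigEvidence",
    "CurationParams",
    "CurationReport",
    "NamingMap",
    "gc_fraction",
    "build_evidence",
    "classify_contigs",
    "apply_curation",
    "assign_names",
    "apply_naming",
]

DEFAULT_KEEP_KEYWORDS = ("Polistes", "Vespula", "wasp")


def gc_fraction(sequence: str) -> Optional[float]:
    """(G+C) / (A+C+G+T), case-insensitive; ambiguity codes and N are
    excluded from numerator and denominator.  None when no unambiguous base."""
    up = sequence.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    denom = gc + at
    if denom == 0:
        return None
    return gc / denom


@dataclass
class ContigEvidence:
    """Everything the filter knows about one contig."""

    contig_id: str
    taxonomy_descriptions: list[str] = field(default_factory=list)
    rescued_gene_count: int = 0
    gc_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rescued_gene_count < 0:
            raise ValueError(f"{self.contig_id}: rescued_gene_count < 0")
        if self.gc_fraction is not None and not 0 <= self.gc_fraction <= 1:
            raise ValueError(f"{self.contig_id}: gc_fraction outside [0,1]")


@dataclass
class CurationParams:
    keep_keywords: tuple[str, ...] = DEFAULT_KEEP_KEYWORDS
    gc_sd_multiplier: float = 2.0
    case_sensitive_keywords: bool = False
    whole_word: bool = False

    def __post_init__(self) -> None:
        if not self.keep_keywords:
            raise ValueError("keep_keywords must be non-empty")
        if self.gc_sd_multiplier <= 0:
            raise ValueError("gc_sd_multiplier must be > 0")


@dataclass
class CurationReport:
    """Per-contig verdicts, one rule per contig, plus the GC band used."""

    decisions: dict[str, tuple[str, str]]  # contig_id -> (verdict, rule)
    gc_mean: Optional[float]
    gc_sd: Optional[float]

    def kept_ids(self) -> list[str]:
        return [c for c, (v, _) in self.decisions.items() if v == "keep"]

    def discarded_ids(self) -> list[str]:
        return [c for c, (v, _) in self.decisions.items() if v == "discard"]

    def to_dataframe(self, evidence: Optional[dict] = None) -> pd.DataFrame:
        rows = []
        for cid, (verdict, rule) in self.decisions.items():
            gc = None
            if evidence is not None and cid in evidence:
                gc = evidence[cid].gc_fraction
            rows.append(
                {"contig_id": cid, "verdict": verdict, "rule": rule, "gc": gc}
            )
        return pd.DataFrame(rows).set_index("contig_id")


def build_evidence(
    assembly: SequenceSet,
    taxonomy: TaxonomyEvidence,
    rescue_counts: Optional[dict[str, int]] = None,
) -> dict[str, ContigEvidence]:
    """Assemble per-contig evidence, computing GC from the sequences."""
    rescue_counts = rescue_counts or {}
    return {
        cid: ContigEvidence(
            contig_id=cid,
            taxonomy_descriptions=list(taxonomy.descriptions_for(cid)),
            rescued_gene_count=rescue_counts.get(cid, 0),
            gc_fraction=gc_fraction(seq),
        )
        for cid, seq in assembly
    }


def _matches(description: str, params: CurationParams) -> bool:
    hay = description if params.case_sensitive_keywords else description.lower()
    for kw in params.keep_keywords:
        needle = kw if params.case_sensitive_keywords else kw.lower()
        if params.whole_word:
            import re

            if re.search(rf"\b{re.escape(needle)}\b", hay):
                return True
        elif needle in hay:
            return True
    return False


def classify_contigs(
    assembly: SequenceSet,
    evidence: dict[str, ContigEvidence],
    params: Optional[CurationParams] = None,
) -> CurationReport:
    """Apply the three-rule contamination filter (see module docstring).

    Every assembly contig must have an evidence entry (an empty taxonomy
    list and zero rescued genes are valid evidence).  The GC band is
    computed with the sample standard deviation (ddof=1) over rules-1-2
    keepers and band bounds are inclusive.
    """
    params = params or CurationParams()
    missing = [cid for cid in assembly.ids if cid not in evidence]
    if missing:
        raise KeyError(f"contigs without evidence: {missing[:5]}")

    decisions: dict[str, tuple[str, str]] = {}
    pending: list[str] = []
    band_gc: list[float] = []
    for cid in assembly.ids:
        ev = evidence[cid]
        if ev.taxonomy_descriptions:
            if any(_matches(d, params) for d in ev.taxonomy_descriptions):
                decisions[cid] = ("keep", "taxonomy_keyword")
                if ev.gc_fraction is not None:
                    band_gc.append(ev.gc_fraction)
            else:
                decisions[cid] = ("discard", "taxonomy_mismatch")
        elif ev.rescued_gene_count >= 1:
            decisions[cid] = ("keep", "orthogroup_rescue")
            if ev.gc_fraction is not None:
                band_gc.append(ev.gc_fraction)
        else:
            pending.append(cid)

    if pending and not band_gc:
        raise ValueError(
            "no contig kept by the taxonomy or orthogroup rules: the GC band "
            "is undefined; relax keep_keywords or provide rescue evidence"
        )
    gc_mean: Optional[float] = None
    gc_sd: Optional[float] = None
    if band_gc:
        gc_mean = float(np.mean(band_gc))
        if len(band_gc) >= 2:
            gc_sd = float(np.std(band_gc, ddof=1))
        else:
            warnings.warn(
                "only one contig defines the GC band; using SD = 0.0"
            )
            gc_sd = 0.0
        lo = gc_mean - params.gc_sd_multiplier * gc_sd
        hi = gc_mean + params.gc_sd_multiplier * gc_sd
        for cid in pending:
            gc = evidence[cid].gc_fraction
            if gc is None:
                warnings.warn(
                    f"contig {cid} has undefined GC (no unambiguous base); "
                    "discarded"
                )
                decisions[cid] = ("discard", "gc_outside_band")
            elif lo <= gc <= hi:
                decisions[cid] = ("keep", "gc_within_band")
            else:
                decisions[cid] = ("discard", "gc_outside_band")

    # deterministic order regardless of evidence dict iteration order
    ordered = {cid: decisions[cid] for cid in assembly.ids}
    return CurationReport(decisions=ordered, gc_mean=gc_mean, gc_sd=gc_sd)


def apply_curation(assembly: SequenceSet, report: CurationReport) -> SequenceSet:
    """Return the kept contigs only, original order and case preserved."""
    if set(report.decisions) != set(assembly.ids):
        raise ValueError("curation report does not match assembly contigs")
    kept = [cid for cid in assembly.ids if report.decisions[cid][0] == "keep"]
    if not kept:
        raise ValueError("empty assembly after curation")
    return assembly.subset(kept)


@dataclass
class NamingMap:
    """Bijective old-id -> new-id mapping with length/rank metadata."""

    mapping: dict[str, str]
    table: pd.DataFrame  # columns: old_id, new_id, length, rank

    def __getitem__(self, old_id: str) -> str:
        return self.mapping[old_id]


def assign_names(
    assembly: SequenceSet,
    n_chromosomes: int = 25,
    chromosome_prefix: str = "Chr",
    scaffold_prefix: str = "Scaffold",
) -> NamingMap:
    """Rank records by length (descending, ties broken by input order);
    the first `n_chromosomes` ranks become chromosomes, the remainder
    scaffolds numbered with four digits in order of size."""
    if n_chromosomes < 0:
        raise ValueError("n_chromosomes must be >= 0")
    order = sorted(
        range(len(assembly)),
        key=lambda i: (-len(assembly.records[i][1]), i),
    )
    if len(assembly) < n_chromosomes:
        warnings.warn(
            f"assembly has {len(assembly)} records, fewer than "
            f"{n_chromosomes} chromosomes requested; all become chromosomes"
        )
    mapping: dict[str, str] = {}
    rows = []
    for rank, idx in enumerate(order, start=1):
        old_id, seq = assembly.records[idx]
        if rank <= n_chromosomes:
            new_id = f"{chromosome_prefix}{rank}"
        else:
            new_id = f"{scaffold_prefix}{rank - n_chromosomes:04d}"
        mapping[old_id] = new_id
        rows.append(
            {"old_id": old_id, "new_id": new_id, "length": len(seq), "rank": rank}
        )
    return NamingMap(mapping=mapping, table=pd.DataFrame(rows))


def apply_naming(
    assembly: SequenceSet,
    naming: NamingMap,
    reorder: bool = True,
) -> SequenceSet:
    """Rename (and by default reorder by rank) the assembly records."""
    missing = set(assembly.ids) - set(naming.mapping)
    if missing:
        raise KeyError(f"naming map missing contigs: {sorted(missing)[:5]}")
    records = [(naming.mapping[cid], seq) for cid, seq in assembly]
    if reorder:
        rank = {
            row.new_id: row.rank for row in naming.table.itertuples(index=False)
        }
        records.sort(key=lambda r: rank[r[0]])
    return SequenceSet(records)
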