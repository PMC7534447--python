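"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its spec (seed included): the same
spec yields byte-identical output, and every generator returns a
machine-readable truth table sufficient to score the corresponding
pipeline stage without re-deriving ground truth.

What is emulated — and what is not: contigs are i.i.d. base draws at a
target GC with planted soft-mask tracts and N-gap runs (no repeat-family
structure, no coverage artefacts); gene sequences are i.i.d. uniform
ACGT with CpG sites thinned to a target observed/expected level (no codon
structure or composition heterogeneity); orthogroup tables have clean
core/accessory/species-specific strata (no gene-tree discordance).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from math import log

import dendropy
import numpy as np
import pandas as pd

from .io import OrthogroupTable, SequenceSet, TaxonomyEvidence

__all__ = [
    "AssemblySimSpec",
    "CpGSimSpec",
    "OrthoSimSpec",
    "simulate_assembly",
    "simulate_cpg_genes",
    "simulate_orthogroup_table",
    "simulate_ultrametric_tree",
]

_HOST_DESCRIPTIONS = (
    "Vespula vulgaris hypothetical protein, partial",
    "Polistes dominula uncharacterized locus",
    "paper wasp venom allergen 5 precursor",
)
_CONTAMINANT_DESCRIPTIONS = (
    "Serratia marcescens chromosome, complete genome",
    "Pseudomonas fluorescens plasmid sequence",
    "Saccharomyces cerevisiae chromosome IV",
)


def _spawn(seed: int, tag: str) -> np.random.Generator:
    """Derive an independent, deterministic stream for a purpose tag.

    Uses a stable (CRC32) hash of the tag so streams are reproducible
    across processes and platforms.
    """
    key = zlib.crc32(tag.encode("ascii"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    )


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs
    )


@dataclass
class AssemblySimSpec:
    """Host contigs plus planted contaminants with shifted GC.

    Defaults give a small wasp-like assembly: ~32% GC host contigs with
    ~18% soft-masked repeat content and occasional N gaps, and bacterial-
    or fungal-like contaminants offset +0.15 GC — far outside any 2-SD
    band of the host contigs, so filter recall/precision tests are
    unambiguous.
    """

    n_host_contigs: int = 50
    n_contaminant_contigs: int = 10
    host_gc: float = 0.32
    contaminant_gc: float = 0.47
    length_log_mean: float = log(20_000)
    length_log_sd: float = 0.4
    repeat_fraction: float = 0.18
    gap_rate: float = 2.0  # expected N-runs per contig
    gap_run_mean: float = 50.0  # mean gap run length (geometric)
    taxonomy_miss_rate: float = 0.1
    contaminant_hit_rate: float = 0.5
    rescue_genes_mean: float = 4.0  # predicted genes in clade orthogroups, per host contig
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("host_gc", "contaminant_gc", "repeat_fraction",
                     "taxonomy_miss_rate", "contaminant_hit_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_host_contigs < 1:
            raise ValueError("need at least one host contig")


def simulate_assembly(
    spec: AssemblySimSpec,
) -> tuple[SequenceSet, pd.DataFrame, TaxonomyEvidence, dict[str, int]]:
    """Simulate an assembly with known contaminants.

    Returns (assembly, truth table, taxonomy evidence, rescue counts).
    Host contigs carry a keyword-bearing taxonomy description except for a
    `taxonomy_miss_rate` fraction, which instead rely on their predicted
    genes being in reference-clade orthogroups (the rescue table).
    Contaminants carry a non-matching description with probability
    `contaminant_hit_rate`, otherwise no hit, and never any rescue genes.
    The truth table records class, realized GC, mask fraction and gap runs
    per contig.
    """
    rng_seq = _spawn(spec.seed, "sequence")
    rng_meta = _spawn(spec.seed, "metadata")

    records: list[tuple[str, str]] = []
    hits: dict[str, list[str]] = {}
    rescue: dict[str, int] = {}
    truth_rows = []

    n_total = spec.n_host_contigs + spec.n_contaminant_contigs
    classes = ["host"] * spec.n_host_contigs + [
        "contaminant"
    ] * spec.n_contaminant_contigs
    for i in range(n_total):
        cls = classes[i]
        cid = f"contig_{i + 1:04d}"
        gc = spec.host_gc if cls == "host" else spec.contaminant_gc
        length = max(
            200, int(rng_seq.lognormal(spec.length_log_mean, spec.length_log_sd))
        )
        arr = _random_bases(rng_seq, length, gc)

        # soft-mask tracts to the target repeat fraction
        masked = 0
        target_masked = int(spec.repeat_fraction * length)
        while masked < target_masked:
            tract = int(rng_seq.geometric(1.0 / 500.0))
            tract = min(tract, target_masked - masked, length)
            start = int(rng_seq.integers(0, max(length - tract, 1)))
            arr[start : start + tract] |= 0x20  # ASCII lowercase
            masked = int(((arr >= 97) & (arr <= 122)).sum())

        # N-gap runs (overwrite, uppercase N)
        n_runs = int(rng_seq.poisson(spec.gap_rate))
        planted_runs = 0
        for _ in range(n_runs):
            run = int(rng_seq.geometric(1.0 / spec.gap_run_mean))
            run = min(run, length)
            start = int(rng_seq.integers(0, max(length - run, 1)))
            arr[start : start + run] = ord("N")
            planted_runs += 1

        seq = arr.tobytes().decode("ascii")
        records.append((cid, seq))

        if cls == "host":
            miss = rng_meta.random() < spec.taxonomy_miss_rate
            if not miss:
                hits[cid] = [str(rng_meta.choice(_HOST_DESCRIPTIONS))]
            # all host contigs carry predicted genes in clade orthogroups
            rescue[cid] = 1 + int(rng_meta.poisson(spec.rescue_genes_mean))
        else:
            if rng_meta.random() < spec.contaminant_hit_rate:
                hits[cid] = [str(rng_meta.choice(_CONTAMINANT_DESCRIPTIONS))]

        up = seq.upper()
        g = up.count("G") + up.count("C")
        at = up.count("A") + up.count("T")
        truth_rows.append(
            {
                "contig_id": cid,
                "class": cls,
                "target_gc": gc,
                "realized_gc": g / (g + at) if g + at else np.nan,
                "length": length,
                "mask_fraction": sum(c.islower() for c in seq) / length,
                "n_gap_runs": planted_runs,
                "has_taxonomy_hit": cid in hits,
                "rescued_gene_count": rescue.get(cid, 0),
            }
        )

    assembly = SequenceSet(records)
    truth = pd.DataFrame(truth_rows).set_index("contig_id")
    return assembly, truth, TaxonomyEvidence(hits=hits), rescue


@dataclass
class CpGSimSpec:
    """Gene sets whose CpG[o/e] values follow a k-component mixture.

    Each component is (weight, target_oe_mean, oe_sd): a gene drawn from
    the component gets a per-gene depletion level ~ Normal(mean, sd)
    truncated to [0, 2]; its CG dinucleotides are then retained with
    probability min(depletion, 1) (thinning cannot enrich above the
    i.i.d. expectation, so realizable modes lie at or below ~1).  Defaults
    mirror a trimodal insect-like profile with a methylation-depleted low
    mode.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (1 / 3, 0.4, 0.08),
        (1 / 3, 0.7, 0.08),
        (1 / 3, 1.0, 0.08),
    )
    n_genes: int = 200
    gene_length_law: tuple = ("lognormal", log(2000), 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        w = [c[0] for c in self.components]
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("target o/e means must be > 0")
        if self.gene_length_law[0] not in ("lognormal", "constant"):
            raise ValueError("gene_length_law must be lognormal or constant")


def _gene_length(rng: np.random.Generator, law: tuple) -> int:
    if law[0] == "constant":
        return int(law[1])
    return max(100, int(rng.lognormal(law[1], law[2])))


def simulate_cpg_genes(spec: CpGSimSpec) -> tuple[SequenceSet, pd.DataFrame]:
    """Simulate gene sequences with component-structured CpG depletion.

    Returns (genes, truth) where truth records each gene's component index
    and realized depletion level.  Substitutions are chosen so they cannot
    re-create a CG with the following base, keeping the realized o/e close
    to the drawn depletion level.
    """
    rng = _spawn(spec.seed, "cpg-genes")
    weights = np.array([c[0] for c in spec.components])
    records = []
    truth_rows = []
    non_g = np.frombuffer(b"ACT", dtype=np.uint8)
    for i in range(spec.n_genes):
        comp = int(rng.choice(len(weights), p=weights))
        _, mean, sd = spec.components[comp]
        depletion = float(np.clip(rng.normal(mean, sd), 0.0, 2.0))
        length = _gene_length(rng, spec.gene_length_law)
        arr = _random_bases(rng, length, 0.5)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        cg_pos = np.where(is_c[:-1] & is_g[1:])[0]
        keep_p = min(depletion, 1.0)
        drop = cg_pos[rng.random(len(cg_pos)) >= keep_p]
        if len(drop):
            sub = rng.choice(non_g, size=len(drop))
            # a C substitution directly before a G would re-create a CpG;
            # fall back to A/T there so thinning reaches the target level
            next_g = np.zeros(len(drop), dtype=bool)
            inner = drop + 2 < length
            next_g[inner] = arr[drop[inner] + 2] == ord("G")
            clash = next_g & (sub == ord("C"))
            if clash.any():
                sub[clash] = rng.choice(
                    np.frombuffer(b"AT", dtype=np.uint8), size=int(clash.sum())
                )
            arr[drop + 1] = sub
        gid = f"gene_{i + 1:05d}"
        records.append((gid, arr.tobytes().decode("ascii")))
        truth_rows.append(
            {
                "gene_id": gid,
                "component": comp,
                "depletion": depletion,
                "length": length,
            }
        )
    return (
        SequenceSet(records),
        pd.DataFrame(truth_rows).set_index("gene_id"),
    )


@dataclass
class OrthoSimSpec:
    """Orthogroup presence matrix with core/accessory/specific strata."""

    n_species: int = 10
    n_core: int = 3000
    n_accessory: int = 2000
    accessory_presence_prob: float = 0.5
    n_specific_per_species: int = 20
    gene_count_mean: float = 2.0  # mean genes per present orthogroup (>= 1)
    unassigned_gene_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if not 0 <= self.accessory_presence_prob <= 1:
            raise ValueError("accessory_presence_prob must be in [0,1]")
        if not 0 <= self.unassigned_gene_rate < 1:
            raise ValueError("unassigned_gene_rate must be in [0,1)")
        if self.gene_count_mean < 1:
            raise ValueError("gene_count_mean must be >= 1")


def simulate_orthogroup_table(
    spec: OrthoSimSpec,
) -> tuple[OrthogroupTable, pd.DataFrame]:
    """Simulate an orthogroup gene-count table with known strata.

    Core orthogroups are present in every species; accessory orthogroups
    are present per species with probability p (rows with fewer than two
    presences are redrawn, keeping the stratum distinct from the
    species-specific one); specific orthogroups are present in exactly one
    species.
    Gene counts for a present orthogroup are 1 + Poisson(mean - 1).
    Unassigned gene counts per species are set so that unassigned genes
    make up `unassigned_gene_rate` of each species' total.
    """
    rng = _spawn(spec.seed, "orthogroups")
    species = [f"species_{i + 1:02d}" for i in range(spec.n_species)]

    def counts(shape) -> np.ndarray:
        return 1 + rng.poisson(spec.gene_count_mean - 1.0, size=shape)

    blocks = []
    strata = []
    ids = []
    core = counts((spec.n_core, spec.n_species))
    blocks.append(core)
    strata += ["core"] * spec.n_core
    ids += [f"OG_core_{i:05d}" for i in range(spec.n_core)]

    if spec.n_accessory:
        # accessory = present in >= 2 species but not necessarily all;
        # rows with < 2 presences are redrawn (they would be indistinguishable
        # from the species-specific stratum)
        pres = rng.random((spec.n_accessory, spec.n_species)) < spec.accessory_presence_prob
        bad = pres.sum(axis=1) < 2
        while bad.any():
            pres[bad] = (
                rng.random((int(bad.sum()), spec.n_species))
                < spec.accessory_presence_prob
            )
            bad = pres.sum(axis=1) < 2
        acc = counts((spec.n_accessory, spec.n_species)) * pres
        blocks.append(acc)
        strata += ["accessory"] * spec.n_accessory
        ids += [f"OG_acc_{i:05d}" for i in range(spec.n_accessory)]

    for j in range(spec.n_species):
        if spec.n_specific_per_species:
            block = np.zeros((spec.n_specific_per_species, spec.n_species), int)
            block[:, j] = counts(spec.n_specific_per_species)
            blocks.append(block)
            strata += [f"specific:{species[j]}"] * spec.n_specific_per_species
            ids += [
                f"OG_spec_{species[j]}_{i:04d}"
                for i in range(spec.n_specific_per_species)
            ]

    matrix = np.vstack(blocks)
    counts_df = pd.DataFrame(matrix, index=ids, columns=species)
    assigned = counts_df.sum(axis=0)
    r = spec.unassigned_gene_rate
    unassigned = {
        sp: int(round(assigned[sp] * r / (1 - r))) for sp in species
    }
    truth = pd.DataFrame({"orthogroup_id": ids, "stratum": strata}).set_index(
        "orthogroup_id"
    )
    return OrthogroupTable(counts_df, unassigned=unassigned), truth


def simulate_ultrametric_tree(
    n_taxa: int,
    root_height: float = 1.0,
    seed: int = 0,
    taxon_prefix: str = "t",
) -> dendropy.Tree:
    """Random coalescent-style ultrametric binary tree.

    Node ages are uniform draws on (0, root_height) sorted ascending, with
    the last merge pinned at exactly root_height; at each age two random
    active lineages merge.  Every root-to-tip distance equals root_height
    by construction.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if root_height <= 0:
        raise ValueError("root_height must be > 0")
    rng = _spawn(seed, "tree")
    taxa = dendropy.TaxonNamespace(
        [f"{taxon_prefix}{i + 1}" for i in range(n_taxa)]
    )
    active: list[tuple[dendropy.Node, float]] = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        active.append((node, 0.0))
    ages = sorted(rng.uniform(0, root_height, size=n_taxa - 2).tolist())
    ages.append(root_height)
    for age in ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False).tolist())
        (n2, a2) = active.pop(j)
        (n1, a1) = active.pop(i)
        parent = dendropy.Node()
        parent.add_child(n1)
        parent.add_child(n2)
        n1.edge.length = age - a1
        n2.edge.length = age - a2
        active.append((parent, age))
    root, _ = active[0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree
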