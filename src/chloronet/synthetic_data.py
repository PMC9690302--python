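"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (including the RNG
seed) and returns planted ground truth alongside the data, so recovery can
be asserted exactly:

* :func:`simulate_genomes` — a six-sample set of annotated quadripartite
  chloroplast genomes (LSC + IRa + SSC + IRb with IRb the reverse
  complement of IRa) with planted presence/absence structure: an island
  sample carrying private tRNAs and a private CDS, a hinterland-shared gene
  set absent from the island sample, and a single discriminating gene
  (psbM) shared by two hinterland samples.
* :func:`simulate_alignments` — per-gene alignments whose sample partitions
  are planted; the default plan reproduces the published partition patterns
  of the 19 polymorphic genes (2 CZ, 10 TW, 2 TW2, 4 ELSE, plus the
  hinterland-only ycf2).
* :func:`simulate_expression` — a modular linear-Gaussian expression matrix:
  regulator rows are iid standard normal and each target is the sum of its
  module's regulators scaled by a coefficient plus Gaussian noise.
* :func:`simulate_annotation` — GMT term sets with one planted enriched term
  against uniform decoys.

Scale defaults are desk-sized (tens of kilobases, hundreds of genes) rather
than full plastome/transcriptome scale; the structure, not the size, is
what the downstream methods key on.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_features import GeneAnnotation, GenomeRecord, reverse_complement
from .grn import ExpressionMatrix
from .polymorphism import (
    GeneAlignment,
    GroupLabel,
    SamplePartition,
    classify_partition,
    load_published_partitions,
)

__all__ = [
    "SIX_SAMPLES",
    "SynthGenomeConfig",
    "GenomeTruth",
    "simulate_genomes",
    "SynthAlignmentConfig",
    "simulate_alignments",
    "SynthExprConfig",
    "simulate_expression",
    "simulate_annotation",
]

SIX_SAMPLES = ("CBTY1", "CBTY2", "CBRY2", "JPL", "SMP", "TW")
HINTERLAND = ("CBTY1", "CBTY2", "CBRY2", "JPL", "SMP")

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Genomes


def _default_core_genes() -> list[tuple[str, str]]:
    """(name, category) for the shared core: 70 CDS, 20 tRNA, 4 rRNA."""
    cds = [
        "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI", "psbJ",
        "psbK", "psbL", "psbT", "psbZ", "psaA", "psaB", "psaC", "psaI", "psaJ",
        "petA", "petB", "petD", "petG", "petL", "petN", "atpA", "atpB", "atpE",
        "atpF", "atpH", "atpI", "rbcL", "matK", "cemA", "ccsA", "chlB", "chlL",
        "chlN", "rpoA", "rpoB", "rpoC1", "rpoC2", "rps2", "rps3", "rps4",
        "rps8", "rps11", "rps12", "rps14", "rps15", "rps18", "rps19", "rpl2",
        "rpl5", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32", "rpl33",
        "rpl36", "ndhB", "infA", "accD", "pafI", "pafII", "ycf1", "ycf2",
        "ycf12", "pbf1",
    ]
    trna = [f"trn{aa}-{ac}" for aa, ac in [
        ("A", "UGC"), ("F", "GAA"), ("G", "GCC"), ("H", "GUG"), ("M", "CAU"),
        ("N", "GUU"), ("P", "UGG"), ("Q", "UUG"), ("R", "ACG"), ("S", "GCU"),
        ("T", "GGU"), ("V", "GAC"), ("W", "CCA"), ("Y", "GUA"), ("S", "UGA"),
        ("L", "CAA"), ("R", "UCU"), ("T", "UGU"), ("V", "UAC"), ("I", "GAU"),
    ]]
    rrna = ["rrn16", "rrn23", "rrn4.5", "rrn5"]
    assert len(cds) == 70 and len(trna) == 20
    return [(g, "CDS") for g in cds] + [(g, "tRNA") for g in trna] + [(g, "rRNA") for g in rrna]


def _fake_trna_names(aa: str, count: int) -> list[str]:
    """Distinct synthetic tRNA names in the canonical trnX-NNN form (stable
    under gene-name normalization)."""
    codons = ["".join((a, b, c)) for a in "ACGU" for b in "ACGU" for c in "ACGU"]
    return [f"trn{aa}-{codon}" for codon in codons[:count]]


def _default_tw_private() -> list[tuple[str, str]]:
    """21 island-private tRNAs plus one private CDS (clpP)."""
    return [(n, "tRNA") for n in _fake_trna_names("X", 21)] + [("clpP", "CDS")]


def _default_hinterland_private() -> list[tuple[str, str]]:
    """31 hinterland-shared tRNAs plus one shared CDS (rps7), all absent
    from the island sample."""
    return [(n, "tRNA") for n in _fake_trna_names("Z", 31)] + [("rps7", "CDS")]


@dataclass
class SynthGenomeConfig:
    sample_names: Sequence[str] = SIX_SAMPLES
    core_genes: list[tuple[str, str]] = field(default_factory=_default_core_genes)
    # gene -> samples carrying it, for presence/absence structure beyond the core
    private_genes: dict[str, tuple[str, Sequence[str]]] = field(default_factory=dict)
    ir_length: int = 850
    lsc_length: int = 20000
    ssc_length: int = 12000
    gene_length: int = 120
    gene_spacer: int = 30
    focal_single: str = "TW"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ir_length, self.lsc_length, self.ssc_length) <= 0:
            raise ValueError("region lengths must be positive")
        if not self.private_genes:
            self.private_genes = self._default_private()

    def _default_private(self) -> dict[str, tuple[str, Sequence[str]]]:
        out: dict[str, tuple[str, Sequence[str]]] = {}
        island = [self.focal_single] if self.focal_single in self.sample_names else []
        hinter = [s for s in self.sample_names if s != self.focal_single]
        if island:
            for name, cat in _default_tw_private():
                out[name] = (cat, tuple(island))
            for name, cat in _default_hinterland_private():
                out[name] = (cat, tuple(hinter))
        if {"CBRY2", "CBTY1"} <= set(self.sample_names):
            out["psbM"] = ("CDS", ("CBRY2", "CBTY1"))
        return out


@dataclass
class GenomeTruth:
    presence: pd.DataFrame  # samples x genes, bool
    region_lengths: dict[str, dict[str, int]]  # sample -> {lsc, ssc, ir, total}


def simulate_genomes(config: SynthGenomeConfig | None = None) -> tuple[list[GenomeRecord], GenomeTruth]:
    """Generate annotated quadripartite genomes with planted gene presence.

    Genes are tiled left-to-right through the LSC and then the SSC at
    non-overlapping positions; the IRs carry no annotations. Deterministic
    for a given config.
    """
    config = config or SynthGenomeConfig()
    rng = np.random.default_rng(config.rng_seed)
    records: list[GenomeRecord] = []
    presence_rows: dict[str, set[str]] = {}
    region_lengths: dict[str, dict[str, int]] = {}
    for sample in config.sample_names:
        gene_plan = list(config.core_genes)
        for name, (cat, carriers) in config.private_genes.items():
            if sample in carriers:
                gene_plan.append((name, cat))
        lsc = _random_seq(rng, config.lsc_length)
        ira = _random_seq(rng, config.ir_length)
        ssc = _random_seq(rng, config.ssc_length)
        # break reverse-complement pairing at the repeat flanks so the
        # planted IR is exactly maximal (cannot chance-extend into LSC/SSC)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if ssc[0] == comp[ssc[-1]]:
            ssc = ("A" if ssc[-1] != "T" else "C") + ssc[1:]
        if lsc[0] == comp[lsc[-1]]:
            lsc = ("A" if lsc[-1] != "T" else "C") + lsc[1:]
        seq = lsc + ira + ssc + reverse_complement(ira)
        genes = _tile_genes(
            gene_plan,
            regions=[(0, config.lsc_length), (config.lsc_length + config.ir_length,
                                              config.lsc_length + config.ir_length + config.ssc_length)],
            gene_length=config.gene_length,
            spacer=config.gene_spacer,
            rng=rng,
        )
        records.append(GenomeRecord(sample_id=sample, sequence=seq, genes=genes))
        presence_rows[sample] = {g.name for g in genes}
        region_lengths[sample] = {
            "lsc": config.lsc_length,
            "ssc": config.ssc_length,
            "ir": config.ir_length,
            "total": len(seq),
        }
    all_genes = sorted(set().union(*presence_rows.values()))
    presence = pd.DataFrame(
        [[g in presence_rows[s] for g in all_genes] for s in config.sample_names],
        index=list(config.sample_names),
        columns=all_genes,
    )
    return records, GenomeTruth(presence=presence, region_lengths=region_lengths)


def _tile_genes(gene_plan, regions, gene_length, spacer, rng) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    region_iter = iter(regions)
    start, end = next(region_iter)
    pos = start + spacer
    for name, cat in gene_plan:
        if pos + gene_length > end:
            nxt = next(region_iter, None)
            if nxt is None:
                raise ValueError("gene plan does not fit in the single-copy regions")
            start, end = nxt
            pos = start + spacer
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(name=name, category=cat, start=pos, end=pos + gene_length, strand=strand))
        pos += gene_length + spacer
    return genes


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class SynthAlignmentConfig:
    sample_names: Sequence[str] = SIX_SAMPLES
    # gene -> partition to plant; None = the published 19-gene plan
    plan: Mapping[str, SamplePartition] | None = None
    n_monomorphic: int = 3
    alignment_length: int = 300
    variant_columns_per_class: int = 1
    focal_single: str = "TW"
    focal_pair: frozenset = frozenset({"JPL", "SMP"})
    rng_seed: int = 0


@dataclass
class AlignmentTruth:
    partitions: dict[str, SamplePartition]
    labels: dict[str, GroupLabel]
    variant_columns: dict[str, list[int]]


def simulate_alignments(
    config: SynthAlignmentConfig | None = None,
) -> tuple[dict[str, GeneAlignment], AlignmentTruth]:
    """Emit per-gene alignments realizing the planted sample partitions.

    One reference class keeps the base sequence; every other class receives
    its own substitutions at dedicated columns, so samples within a class
    are identical and samples across classes differ. Genes outside the plan
    are monomorphic.
    """
    config = config or SynthAlignmentConfig()
    plan = dict(config.plan) if config.plan is not None else load_published_partitions()
    rng = np.random.default_rng(config.rng_seed)
    alignments: dict[str, GeneAlignment] = {}
    truth = AlignmentTruth(partitions={}, labels={}, variant_columns={})
    for gene, partition in plan.items():
        aln, cols = _plant_alignment(gene, partition, config, rng)
        alignments[gene] = aln
        truth.partitions[gene] = partition
        truth.labels[gene] = classify_partition(partition, config.focal_single, config.focal_pair)
        truth.variant_columns[gene] = cols
    for i in range(config.n_monomorphic):
        gene = f"mono{i + 1:02d}"
        base = _random_seq(rng, config.alignment_length)
        alignments[gene] = GeneAlignment(gene=gene, rows={s: base for s in config.sample_names})
        truth.partitions[gene] = SamplePartition.of(config.sample_names)
        truth.labels[gene] = GroupLabel.MONOMORPHIC
        truth.variant_columns[gene] = []
    return alignments, truth


def _plant_alignment(gene, partition, config, rng) -> tuple[GeneAlignment, list[int]]:
    samples = sorted(partition.samples)
    base = _random_seq(rng, config.alignment_length)
    rows = {s: list(base) for s in samples}
    classes = sorted((sorted(c) for c in partition.classes), key=lambda c: (len(c), c))
    n_variant = max(0, (len(classes) - 1) * config.variant_columns_per_class)
    cols = sorted(rng.choice(config.alignment_length, size=n_variant, replace=False).tolist())
    used = iter(cols)
    for cls in classes[1:]:
        for _ in range(config.variant_columns_per_class):
            col = next(used)
            alt = rng.choice([b for b in "ACGT" if b != base[col]])
            for s in cls:
                rows[s][col] = alt
    return GeneAlignment(gene=gene, rows={s: "".join(r) for s, r in rows.items()}), cols


# ---------------------------------------------------------------------------
# Expression


@dataclass
class SynthExprConfig:
    n_regulators: int = 10
    n_modules: int = 5
    targets_per_module: int = 40
    regulators_per_module: int = 2
    coefficient: float = 1.0
    noise_sd: float = 0.1
    n_samples: int = 200
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_regulators, self.n_modules, self.targets_per_module,
               self.regulators_per_module, self.n_samples) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.regulators_per_module * self.n_modules > self.n_regulators * self.n_modules:
            raise ValueError("module regulator demand exceeds the regulator pool")


@dataclass
class ExpressionTruth:
    edges: set[tuple[str, str]]
    modules: dict[str, int]  # target -> module id
    module_regulators: dict[int, list[str]]


def simulate_expression(
    config: SynthExprConfig | None = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Modular linear-Gaussian expression data with planted regulator edges.

    Regulator rows are iid N(0, 1); module ``m`` is driven by
    ``regulators_per_module`` regulators assigned round-robin, and each of
    its targets is ``coefficient * sum(module regulators) + N(0, noise_sd^2)``.
    """
    config = config or SynthExprConfig()
    rng = np.random.default_rng(config.rng_seed)
    regs = [f"R{i + 1:02d}" for i in range(config.n_regulators)]
    reg_data = rng.standard_normal((config.n_regulators, config.n_samples))
    module_regulators: dict[int, list[str]] = {}
    for m in range(config.n_modules):
        idx = [(m * config.regulators_per_module + j) % config.n_regulators
               for j in range(config.regulators_per_module)]
        module_regulators[m + 1] = [regs[i] for i in sorted(set(idx))]
    rows = {r: reg_data[i] for i, r in enumerate(regs)}
    edges: set[tuple[str, str]] = set()
    modules: dict[str, int] = {}
    t = 0
    for m in range(1, config.n_modules + 1):
        driver_idx = [regs.index(r) for r in module_regulators[m]]
        signal = config.coefficient * reg_data[driver_idx].sum(axis=0)
        for _ in range(config.targets_per_module):
            t += 1
            name = f"T{t:03d}"
            rows[name] = signal + rng.normal(0.0, config.noise_sd, size=config.n_samples)
            modules[name] = m
            edges.update((r, name) for r in module_regulators[m])
    values = pd.DataFrame(
        rows, index=[f"S{j + 1:03d}" for j in range(config.n_samples)]
    ).T
    matrix = ExpressionMatrix(values=values, regulators=regs)
    return matrix, ExpressionTruth(edges=edges, modules=modules, module_regulators=module_regulators)


# ---------------------------------------------------------------------------
# Annotation term sets


def simulate_annotation(
    background: Iterable[str],
    target_set: Iterable[str],
    enrichment_strength: float = 0.8,
    base_rate: float = 0.1,
    n_decoys: int = 20,
    rng_seed: int = 0,
) -> tuple[dict[str, set[str]], str]:
    """GMT-style term sets with one planted enriched term.

    The planted term samples target-set members at ``enrichment_strength``
    and non-target background at ``base_rate``; decoy terms sample the whole
    background uniformly at ``base_rate``. Returns (term -> members, name of
    the planted term).
    """
    bg = sorted(set(background))
    targets = sorted(set(target_set))
    if not set(targets) <= set(bg):
        raise ValueError("target set must be contained in the background")
    rng = np.random.default_rng(rng_seed)
    non_targets = [g for g in bg if g not in set(targets)]
    planted = {g for g in targets if rng.random() < enrichment_strength}
    planted |= {g for g in non_targets if rng.random() < base_rate}
    terms: dict[str, set[str]] = {"planted_term": planted}
    decoy_size = max(1, int(round(base_rate * len(bg))))
    for i in range(n_decoys):
        members = rng.choice(bg, size=min(decoy_size, len(bg)), replace=False)
        terms[f"decoy_{i + 1:02d}"] = set(members.tolist())
    return terms, "planted_term"
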