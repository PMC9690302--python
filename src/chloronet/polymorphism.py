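"""Polymorphic-site extraction, sample-partition classification, supergenes.

For each shared protein-coding gene, the samples are partitioned into
allele-identity classes: two samples fall in the same class iff they carry
identical symbols at every polymorphic alignment column of that gene. The
resulting partition pattern is then classified against a focal layout:

* ``MONOMORPHIC`` — a single class (no polymorphic sites);
* ``TW``   — the focal single sample (default ``TW``, the island
  population) is isolated and all remaining samples are mutually identical;
* ``CZ``   — the focal pair (default ``{JPL, SMP}``, the Chenzhou
  populations) forms exactly one class, and the focal single is not
  isolated;
* ``TW2``  — the focal single is isolated but the remaining samples split
  further;
* ``ELSE`` — any other pattern.

When the focal single sample is absent from a gene's sample set, the
isolation rules are skipped and only the focal-pair rule applies.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "GeneAlignment",
    "PolymorphicSite",
    "SamplePartition",
    "GroupLabel",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "polymorphic_sites",
    "sample_partition",
    "parse_partition_string",
    "classify_partition",
    "select_polymorphic_genes",
    "group_counts",
    "concatenate_supergene",
    "write_supergene_nexus",
    "load_published_partitions",
]

DEFAULT_FOCAL_SINGLE = "TW"
DEFAULT_FOCAL_PAIR = frozenset({"JPL", "SMP"})


class GroupLabel(str, Enum):
    CZ = "CZ"
    TW = "TW"
    TW2 = "TW2"
    ELSE = "ELSE"
    MONOMORPHIC = "MONOMORPHIC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GeneAlignment:
    """A per-gene multiple alignment: sample id -> aligned sequence."""

    gene: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"alignment for {self.gene!r} needs >= 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment for {self.gene!r}: row lengths {sorted(lengths)}")
        self.rows = {k: v.upper() for k, v in self.rows.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def samples(self) -> list[str]:
        return list(self.rows)


@dataclass(frozen=True)
class PolymorphicSite:
    """One variable alignment column (0-based); gaps count as an allele."""

    column: int
    alleles: Mapping[str, str]


@dataclass(frozen=True)
class SamplePartition:
    """Disjoint sample classes covering the sample set.

    The string form is ``"A, B|C, D"``: classes separated by ``|``, members
    by commas; ordering is not significant.
    """

    classes: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        all_members: list[str] = [s for cls in self.classes for s in cls]
        if len(all_members) != len(set(all_members)):
            raise ValueError("partition classes are not disjoint")
        if any(not cls for cls in self.classes):
            raise ValueError("partition contains an empty class")

    @property
    def samples(self) -> frozenset[str]:
        return frozenset().union(*self.classes) if self.classes else frozenset()

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def __str__(self) -> str:
        parts = sorted((sorted(cls) for cls in self.classes), key=lambda c: (-len(c), c))
        return "|".join(", ".join(cls) for cls in parts)

    @classmethod
    def of(cls, *groups: Iterable[str]) -> "SamplePartition":
        return cls(frozenset(frozenset(g) for g in groups))


def read_alignment_fasta(path, gene: str | None = None) -> GeneAlignment:
    """Read an aligned FASTA; the gene name defaults to the file stem."""
    path = Path(path)
    rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GeneAlignment(gene=gene or path.stem, rows=rows)


def write_alignment_fasta(alignment: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in alignment.rows.items():
            fh.write(f">{sid}\n{seq}\n")


def polymorphic_sites(alignment: GeneAlignment) -> list[PolymorphicSite]:
    """Columns with >= 2 distinct symbols among ``{A, C, G, T, -}``.

    Indel columns are kept with ``-`` as an allele; columns where any sample
    carries ``N`` (or another ambiguity code) are skipped entirely.
    """
    sites = []
    samples = alignment.samples
    seqs = [alignment.rows[s] for s in samples]
    for col in range(alignment.length):
        symbols = [seq[col] for seq in seqs]
        if any(sym not in "ACGT-" for sym in symbols):
            continue
        if len(set(symbols)) >= 2:
            sites.append(PolymorphicSite(column=col, alleles=dict(zip(samples, symbols))))
    return sites


def sample_partition(alignment: GeneAlignment) -> SamplePartition:
    """Group samples that agree at every polymorphic site of this gene."""
    sites = polymorphic_sites(alignment)
    if not sites:
        return SamplePartition.of(alignment.samples)
    keys: dict[tuple[str, ...], set[str]] = {}
    for sid in alignment.samples:
        key = tuple(site.alleles[sid] for site in sites)
        keys.setdefault(key, set()).add(sid)
    return SamplePartition(frozenset(frozenset(v) for v in keys.values()))


def parse_partition_string(text: str, sample_set: Iterable[str]) -> SamplePartition:
    """Parse the ``"A, B|C, D"`` form, validating members against ``sample_set``."""
    known = set(sample_set)
    if not text.strip():
        raise ValueError("empty partition string")
    classes: list[frozenset[str]] = []
    seen: set[str] = set()
    for chunk in text.split("|"):
        members = [m.strip() for m in re.split(r"[,;]", chunk) if m.strip()]
        if not members:
            raise ValueError(f"empty class in partition string {text!r}")
        for m in members:
            if m not in known:
                raise ValueError(f"unknown sample {m!r} in partition string")
            if m in seen:
                raise ValueError(f"sample {m!r} appears twice in partition string")
            seen.add(m)
        classes.append(frozenset(members))
    return SamplePartition(frozenset(classes))


def classify_partition(
    partition: SamplePartition,
    focal_single: str = DEFAULT_FOCAL_SINGLE,
    focal_pair: Iterable[str] = DEFAULT_FOCAL_PAIR,
) -> GroupLabel:
    """Classify a sample partition into MONOMORPHIC/TW/CZ/TW2/ELSE.

    Rule order: (i) one class -> MONOMORPHIC; (ii) focal single isolated and
    the rest one class -> TW; (iii) focal pair exactly one class while the
    focal single is not isolated -> CZ; (iv) focal single isolated with the
    rest split -> TW2; (v) otherwise ELSE. Rules (ii)/(iv) are skipped when
    the focal single is absent from the partition's sample set.
    """
    pair = frozenset(focal_pair)
    samples = partition.samples
    if not pair <= samples:
        raise ValueError(f"focal pair {sorted(pair)} not contained in sample set {sorted(samples)}")
    if partition.n_classes == 1:
        return GroupLabel.MONOMORPHIC
    has_single = focal_single in samples
    single_isolated = has_single and frozenset({focal_single}) in partition.classes
    if single_isolated and partition.n_classes == 2:
        return GroupLabel.TW
    if pair in partition.classes and not single_isolated:
        return GroupLabel.CZ
    if single_isolated:
        return GroupLabel.TW2
    return GroupLabel.ELSE


def select_polymorphic_genes(
    alignments: Mapping[str, GeneAlignment] | Sequence[GeneAlignment],
    exclude: Iterable[str] = (),
    focal_single: str = DEFAULT_FOCAL_SINGLE,
    focal_pair: Iterable[str] = DEFAULT_FOCAL_PAIR,
) -> dict[str, GroupLabel]:
    """Label every gene with >= 1 polymorphic site, minus the exclude list."""
    if not isinstance(alignments, Mapping):
        alignments = {a.gene: a for a in alignments}
    excluded = set(exclude)
    labels: dict[str, GroupLabel] = {}
    for gene, aln in alignments.items():
        if gene in excluded:
            continue
        part = sample_partition(aln)
        label = classify_partition(part, focal_single, focal_pair)
        if label is not GroupLabel.MONOMORPHIC:
            labels[gene] = label
    return labels


def group_counts(labels: Mapping[str, GroupLabel]) -> dict[GroupLabel, int]:
    counts = {g: 0 for g in (GroupLabel.CZ, GroupLabel.TW, GroupLabel.TW2, GroupLabel.ELSE)}
    for label in labels.values():
        counts[label] = counts.get(label, 0) + 1
    return counts


@dataclass
class Supergene:
    """End-to-end concatenation of per-gene alignments for tree software."""

    alignment: GeneAlignment
    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)  # gene -> [start, end)


def concatenate_supergene(
    alignments: Sequence[GeneAlignment], gene_order: Sequence[str] | None = None
) -> Supergene:
    """Concatenate per-gene alignments in the given order (input order by
    default); every gene must cover the same sample set."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    by_gene = {a.gene: a for a in alignments}
    order = list(gene_order) if gene_order is not None else list(by_gene)
    samples = set(alignments[0].samples)
    for a in alignments:
        if set(a.samples) != samples:
            missing = samples.symmetric_difference(a.samples)
            raise ValueError(f"sample set mismatch at gene {a.gene!r}: {sorted(missing)}")
    parts: dict[str, list[str]] = {s: [] for s in sorted(samples)}
    ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in order:
        aln = by_gene[gene]
        for s in parts:
            parts[s].append(aln.rows[s])
        ranges[gene] = (offset, offset + aln.length)
        offset += aln.length
    rows = {s: "".join(chunks) for s, chunks in parts.items()}
    return Supergene(alignment=GeneAlignment(gene="supergene", rows=rows), ranges=ranges)


SIX_SAMPLES = ("CBTY1", "CBTY2", "CBRY2", "JPL", "SMP", "TW")


def load_published_partitions(path=None) -> dict[str, SamplePartition]:
    """Load the published per-gene sample-partition patterns of the 19
    polymorphic *C. argyrophylla* chloroplast protein-coding genes.

    Each row gives a gene and its partition string over the six population
    samples; ycf2 is restricted to the five hinterland samples because its
    Taiwan sequence carries large assembly-artifact deletions.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "polymorphic_gene_partitions.tsv"
    partitions: dict[str, SamplePartition] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            sample_set = SIX_SAMPLES if row["location"] == "all" else tuple(
                s for s in SIX_SAMPLES if s != "TW"
            )
            partitions[row["gene"]] = parse_partition_string(row["partition"], sample_set)
    return partitions


def write_supergene_nexus(supergene: Supergene, path) -> None:
    """Write the supergene as NEXUS with a charset block marking gene ranges."""
    aln = supergene.alignment
    ntax, nchar = len(aln.rows), aln.length
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={ntax} nchar={nchar};\n")
        fh.write("  format datatype=dna missing=N gap=-;\n  matrix\n")
        for sid, seq in aln.rows.items():
            fh.write(f"    {sid}  {seq}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for gene, (start, end) in supergene.ranges.items():
            fh.write(f"  charset {gene} = {start + 1}-{end};\n")
        fh.write("end;\n")
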