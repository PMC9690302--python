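"""Chloroplast genome parsing, quadripartite partition, and feature summaries.

A land-plant chloroplast genome is a circular molecule with a quadripartite
layout: a large and a small single-copy region (LSC, SSC) separated by a
pair of inverted repeats (IRa/IRb, reverse-complement copies of each other).
In Pinaceae-adjacent conifers such as *Cathaya argyrophylla* the IRs are
unusually short (on the order of 850 bp), so they are located here by exact
seed-and-extend matching rather than by the long-IR heuristics used for
typical angiosperm plastomes.

All coordinates are 0-based half-open internally; GenBank I/O converts to
and from the 1-based inclusive convention of the flat-file format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneAnnotation",
    "GenomeRecord",
    "RegionPartition",
    "FeatureSummary",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "gc_content",
    "reverse_complement",
    "detect_inverted_repeats",
    "partition_regions",
    "summarize_features",
]

GENE_CATEGORIES = ("CDS", "tRNA", "rRNA", "other")

# Synonym groups mapping alternative published symbols to one canonical
# symbol. Older plastome annotations use ycf3/ycf4 where newer ones use
# pafI/pafII; both must land on the same name for cross-sample comparison.
_SYNONYMS = {
    "ycf3": "pafI",
    "ycf4": "pafII",
    "psbn": "pbf1",
    "acd1": "psbZ",
    "lhba": "psbZ",
}

_CANONICAL_CASE = {
    "pafi": "pafI",
    "pafii": "pafII",
    "pbf1": "pbf1",
}

_TRN_RE = re.compile(
    r"^trn(?P<aa>[a-z])[\s_\-]*\(?(?P<anticodon>[acgtu]{3})?\)?(?:[\s_\-]*(?P<copy>\d+))?$",
    re.IGNORECASE,
)


def normalize_gene_name(name: str) -> str:
    """Map a raw annotation symbol to the canonical symbol used throughout.

    tRNA names are unified to the ``trnX-NNN`` form (single-letter amino
    acid, uppercase anticodon written with U); known synonyms collapse to
    one symbol; anything else passes through with locus/copy suffixes
    (``_1``, ``-2``) stripped.
    """
    raw = name.strip()
    m = _TRN_RE.match(raw)
    if m:
        aa = m.group("aa").upper()
        anticodon = m.group("anticodon")
        if anticodon:
            return f"trn{aa}-{anticodon.upper().replace('T', 'U')}"
        return f"trn{aa}"
    stem = re.sub(r"[_\-]\d+$", "", raw)
    key = stem.lower()
    if key in _SYNONYMS:
        key = _SYNONYMS[key]
        if key.lower() in _CANONICAL_CASE:
            return _CANONICAL_CASE[key.lower()]
        return key
    if key in _CANONICAL_CASE:
        return _CANONICAL_CASE[key]
    return stem


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: normalized symbol, category, span, strand."""

    name: str
    category: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for gene {self.name!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """An annotated chloroplast genome for one sample."""

    sample_id: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    accession: str | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"gene {g.name!r} [{g.start}, {g.end}) outside sequence "
                    f"of length {len(self.sequence)}"
                )

    def gene_names(self) -> set[str]:
        """Distinct gene symbols (IR-duplicated copies collapsed)."""
        return {g.name for g in self.genes}


Interval = tuple[int, int]


def _interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


@dataclass(frozen=True)
class RegionPartition:
    """LSC/SSC/IRa/IRb intervals tiling the circular genome.

    Intervals are 0-based half-open; an interval with ``end > genome_length``
    wraps around the origin.
    """

    lsc: Interval
    ssc: Interval
    ira: Interval
    irb: Interval
    genome_length: int

    def __post_init__(self) -> None:
        if _interval_len(self.ira) != _interval_len(self.irb):
            raise ValueError("IRa and IRb lengths differ")
        total = (
            _interval_len(self.lsc)
            + _interval_len(self.ssc)
            + 2 * _interval_len(self.ira)
        )
        if total != self.genome_length:
            raise ValueError(
                f"regions do not tile the genome: {total} != {self.genome_length}"
            )

    @property
    def ir_length(self) -> int:
        return _interval_len(self.ira)


@dataclass(frozen=True)
class FeatureSummary:
    """Per-sample genome feature summary (lengths, GC by region, gene counts).

    ``n_genes`` counts each annotated occurrence; ``n_unique_genes`` collapses
    IR-duplicated copies to one.
    """

    sample_id: str
    total_length: int
    lsc_length: int
    ssc_length: int
    ir_length: int
    gc_total: int
    gc_lsc: int
    gc_ssc: int
    gc_ir: int
    n_genes: int
    n_unique_genes: int
    n_cds: int
    n_trna: int
    n_rrna: int


# ---------------------------------------------------------------------------
# GenBank I/O


def _category_for_feature(ftype: str) -> str | None:
    if ftype in ("CDS", "tRNA", "rRNA"):
        return ftype
    return None


def read_genbank(path, sample_id: str | None = None) -> GenomeRecord:
    """Read a single-record GenBank flat file into a :class:`GenomeRecord`.

    ``CDS``/``tRNA``/``rRNA`` features become gene annotations with their
    type as category; ``gene`` features with no same-named typed feature are
    kept with category ``other``. Compound (``join``) locations are flattened
    to their min-start..max-end span.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one GenBank record in {path}, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"GenBank record in {path} has no usable sequence")

    genes: list[GeneAnnotation] = []
    typed_names: set[str] = set()
    gene_feats = []
    for feat in rec.features:
        cat = _category_for_feature(feat.type)
        if cat is None:
            if feat.type == "gene":
                gene_feats.append(feat)
            continue
        genes.append(_annotation_from_feature(feat, cat, len(seq)))
        typed_names.add(genes[-1].name)
    for feat in gene_feats:
        ann = _annotation_from_feature(feat, "other", len(seq))
        if ann.name not in typed_names:
            genes.append(ann)
    genes.sort(key=lambda g: (g.start, g.end, g.name))

    circular = rec.annotations.get("topology", "circular") == "circular"
    return GenomeRecord(
        sample_id=sample_id or rec.name or rec.id,
        sequence=seq,
        genes=genes,
        accession=rec.id if rec.id and rec.id != "<unknown id>" else None,
        circular=circular,
    )


def _annotation_from_feature(feat, category: str, seq_len: int) -> GeneAnnotation:
    name = None
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            name = feat.qualifiers[key][0]
            break
    if name is None:
        name = f"{feat.type}_{int(feat.location.start)}"
    start = int(min(p.start for p in feat.location.parts))
    end = int(max(p.end for p in feat.location.parts))
    if not 0 <= start < end <= seq_len:
        raise ValueError(
            f"feature {name!r} spans [{start}, {end}) outside sequence of length {seq_len}"
        )
    strand = "-" if feat.location.strand == -1 else "+"
    return GeneAnnotation(
        name=normalize_gene_name(name), category=category, start=start, end=end, strand=strand
    )


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file (round-trips with
    :func:`read_genbank`)."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.accession or record.sample_id,
        name=record.sample_id[:16],
        description=f"{record.sample_id} chloroplast genome",
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    rec.annotations["date"] = "01-JAN-2022"  # fixed so equal records serialize identically
    for g in record.genes:
        loc = FeatureLocation(g.start, g.end, strand=-1 if g.strand == "-" else 1)
        ftype = g.category if g.category != "other" else "gene"
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [g.name]}))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Sequence arithmetic

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str, interval: Interval | None = None) -> float:
    """GC percentage over the interval (whole sequence if omitted).

    ``N`` is excluded from the denominator; for an interval with
    ``end > len(sequence)`` the slice wraps around the origin (circular
    topology).
    """
    seq = sequence.upper()
    n = len(seq)
    if interval is not None:
        start, end = interval
        if not 0 <= start <= end <= 2 * n:
            raise ValueError(f"interval {interval} outside sequence bounds")
        if end <= n:
            seq = seq[start:end]
        else:  # wraps the origin
            seq = seq[start:] + seq[: end - n]
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases in interval")
    return 100.0 * (seq.count("G") + seq.count("C")) / denom


# ---------------------------------------------------------------------------
# Inverted-repeat detection


def detect_inverted_repeats(
    sequence: str,
    min_len: int = 100,
    k: int = 21,
    circular: bool = False,
) -> tuple[Interval, Interval] | None:
    """Locate the longest pair of non-overlapping reverse-complement repeats.

    Seed-and-extend over exact ``k``-mer matches between the sequence and its
    reverse complement, with ungapped extension. Returns ``(ira, irb)`` with
    ``ira`` the leftmost interval, or ``None`` if no pair of length
    ``min_len`` or more exists. With ``circular=True`` the search runs on the
    doubled sequence so repeats spanning the origin are found; reported
    coordinates stay within ``[0, 2n)`` with ``end > n`` meaning wrap-around.
    """
    seq = sequence.upper()
    n = len(seq)
    if min_len < k:
        k = max(4, min_len)
    search = seq + seq if circular else seq
    rc = reverse_complement(search)
    m = len(search)
    if m < 2 * min_len:
        return None

    seeds: dict[str, list[int]] = {}
    for i in range(m - k + 1):
        seeds.setdefault(search[i : i + k], []).append(i)

    best: tuple[int, int, int] | None = None  # (length, a_start, b_start)
    # anti-diagonal id -> list of already-extended A intervals on it, so the
    # many seeds inside one long repeat extend only once
    done: dict[int, list[Interval]] = {}
    for j in range(m - k + 1):
        kmer = rc[j : j + k]
        hits = seeds.get(kmer)
        if not hits:
            continue
        for i in hits:
            # rc[j:j+k] corresponds to search[m-j-k : m-j] on the forward strand
            b_start = m - j - k
            if b_start <= i:
                continue  # keep (left, right) ordering; symmetric pair found once
            left, right = i, i + k
            b_left, b_right = b_start, b_start + k
            diag = left + b_right  # invariant under ungapped extension
            if any(lo <= i and i + k <= hi for lo, hi in done.get(diag, ())):
                continue
            # ungapped extension on both flanks
            while left > 0 and b_right < m and search[left - 1] == _comp(search[b_right]):
                left -= 1
                b_right += 1
            while right < b_left and search[right] == _comp(search[b_left - 1]):
                right += 1
                b_left -= 1
            done.setdefault(diag, []).append((left, right))
            length = right - left
            if length < min_len or length != b_right - b_left:
                continue
            if right > b_left:  # overlapping arms (palindrome center); trim is ambiguous
                continue
            cand = (length, left, b_left)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand

    if best is None:
        return None
    length, a, b = best
    if circular:
        a %= n
        b %= n
        if a > b:
            a, b = b, a
    return (a, a + length), (b, b + length)


def _comp(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(base, "?")


# ---------------------------------------------------------------------------
# Region partition and summary


def partition_regions(record: GenomeRecord, irs: tuple[Interval, Interval]) -> RegionPartition:
    """Assign the two arcs between the IRs to LSC (longer) and SSC (shorter)."""
    (a1, a2), (b1, b2) = sorted(irs)
    n = len(record.sequence)
    if a2 > b1:
        raise ValueError(f"inverted repeats overlap: {irs}")
    if b2 > n:
        raise ValueError("IR interval extends past the sequence end")
    inner = (a2, b1)  # arc between IRa end and IRb start
    outer = (b2, a1 + n)  # arc wrapping the origin
    lsc, ssc = sorted((inner, outer), key=_interval_len, reverse=True)
    return RegionPartition(lsc=lsc, ssc=ssc, ira=(a1, a2), irb=(b1, b2), genome_length=n)


def summarize_features(record: GenomeRecord, partition: RegionPartition | None = None) -> FeatureSummary:
    """Compute the per-sample feature summary (region lengths, integer-percent
    GC, gene counts per category).

    Gene counts are per annotated occurrence; ``n_unique_genes`` additionally
    reports the collapsed count. GC values are rounded to integer percent
    for reporting; use :func:`gc_content` directly for full precision.
    """
    seq = record.sequence
    counts = {"CDS": 0, "tRNA": 0, "rRNA": 0, "other": 0}
    for g in record.genes:
        counts[g.category] += 1
    gc_region = lambda iv: round(gc_content(seq, iv)) if iv is not None else 0
    if partition is not None:
        lsc_len, ssc_len, ir_len = (
            _interval_len(partition.lsc),
            _interval_len(partition.ssc),
            partition.ir_length,
        )
        gc_lsc = gc_region(partition.lsc) if lsc_len else 0
        gc_ssc = gc_region(partition.ssc) if ssc_len else 0
        gc_ir = gc_region(partition.ira) if ir_len else 0
    else:
        lsc_len = ssc_len = ir_len = 0
        gc_lsc = gc_ssc = gc_ir = 0
    return FeatureSummary(
        sample_id=record.sample_id,
        total_length=len(seq),
        lsc_length=lsc_len,
        ssc_length=ssc_len,
        ir_length=ir_len,
        gc_total=round(gc_content(seq)),
        gc_lsc=gc_lsc,
        gc_ssc=gc_ssc,
        gc_ir=gc_ir,
        n_genes=len(record.genes),
        n_unique_genes=len(record.gene_names()),
        n_cds=counts["CDS"],
        n_trna=counts["tRNA"],
        n_rrna=counts["rRNA"],
    )
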