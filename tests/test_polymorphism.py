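"""Polymorphic sites, sample partitions, group classification, supergenes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chloronet.polymorphism import (
    GeneAlignment,
    GroupLabel,
    SamplePartition,
    classify_partition,
    concatenate_supergene,
    group_counts,
    load_published_partitions,
    parse_partition_string,
    polymorphic_sites,
    sample_partition,
    select_polymorphic_genes,
    write_supergene_nexus,
)
from chloronet.synthetic_data import SIX_SAMPLES, SynthAlignmentConfig, simulate_alignments


def test_polymorphic_sites_basic():
    assert polymorphic_sites(GeneAlignment("g", {"a": "ACGT", "b": "ACGT"})) == []
    sites = polymorphic_sites(GeneAlignment("g", {"a": "ACGT", "b": "ACCT"}))
    assert [s.column for s in sites] == [2]
    assert sites[0].alleles == {"a": "G", "b": "C"}


def test_gap_is_an_allele_and_n_columns_skipped():
    sites = polymorphic_sites(GeneAlignment("g", {"a": "A-GN", "b": "ACGA"}))
    assert [s.column for s in sites] == [1]
    assert sites[0].alleles["a"] == "-"


def test_ragged_alignment_rejected():
    with pytest.raises(ValueError):
        GeneAlignment("g", {"a": "ACGT", "b": "ACG"})


def test_sample_partition_patterns():
    # focal-pair pattern: JPL and SMP share a private allele
    rows = {s: "AAAA" for s in SIX_SAMPLES}
    rows["JPL"] = rows["SMP"] = "AATA"
    part = sample_partition(GeneAlignment("g", rows))
    assert part == SamplePartition.of(["JPL", "SMP"], [s for s in SIX_SAMPLES if s not in ("JPL", "SMP")])

    mono = sample_partition(GeneAlignment("g", {s: "ACGT" for s in SIX_SAMPLES}))
    assert mono.n_classes == 1

    distinct = {s: "A" * i + "T" + "A" * (5 - i) for i, s in enumerate(SIX_SAMPLES)}
    assert sample_partition(GeneAlignment("g", distinct)).n_classes == 6


def test_sample_partition_invariance():
    rows = {"a": "ACGTAC", "b": "ACCTAC", "c": "ACGTAC"}
    base = sample_partition(GeneAlignment("g", rows))
    reordered = sample_partition(GeneAlignment("g", dict(reversed(list(rows.items())))))
    assert base == reordered
    padded = sample_partition(GeneAlignment("g", {k: v + "GGG" for k, v in rows.items()}))
    assert base == padded


def test_parse_partition_string_roundtrip():
    samples = SIX_SAMPLES
    part = parse_partition_string("JPL, SMP|TW, CBTY2, CBRY2, CBTY1", samples)
    assert sorted(len(c) for c in part.classes) == [2, 4]
    assert parse_partition_string(str(part), samples) == part


def test_parse_partition_string_errors():
    with pytest.raises(ValueError):
        parse_partition_string("A|A,B", {"A", "B"})
    with pytest.raises(ValueError):
        parse_partition_string("A|C", {"A", "B"})
    with pytest.raises(ValueError):
        parse_partition_string("  ", {"A", "B"})
    assert parse_partition_string("A|B", {"A", "B"}).n_classes == 2


@pytest.mark.parametrize(
    "text,samples,expected",
    [
        ("JPL, SMP|TW, CBTY2, CBRY2, CBTY1", SIX_SAMPLES, GroupLabel.CZ),
        ("TW|JPL, CBTY2, CBRY2, CBTY1, SMP", SIX_SAMPLES, GroupLabel.TW),
        ("TW|JPL, CBTY2|CBRY2, CBTY1, SMP", SIX_SAMPLES, GroupLabel.TW2),
        ("CBRY2, JPL, SMP, TW, CBTY2|CBTY1", SIX_SAMPLES, GroupLabel.ELSE),
        # focal single absent: isolation rules are skipped, pair rule applies
        ("CBRY2|JPL, SMP|CBTY2, CBTY1", tuple(s for s in SIX_SAMPLES if s != "TW"), GroupLabel.CZ),
        # precedence: focal single isolated AND pair isolated -> isolation wins
        ("TW|JPL, SMP|CBRY2, CBTY1, CBTY2", SIX_SAMPLES, GroupLabel.TW2),
    ],
)
def test_classify_partition_rules(text, samples, expected):
    part = parse_partition_string(text, samples)
    assert classify_partition(part) is expected


def test_classify_partition_monomorphic_and_errors():
    part = SamplePartition.of(SIX_SAMPLES)
    assert classify_partition(part) is GroupLabel.MONOMORPHIC
    with pytest.raises(ValueError):
        classify_partition(SamplePartition.of(["A"], ["B"]))


def test_published_partitions_reproduce_printed_groups():
    """The 19 published per-gene partition patterns classify to their
    printed CZ/TW/TW2/ELSE groups, and the 18-gene counts are 2/10/2/4."""
    partitions = load_published_partitions()
    assert len(partitions) == 19
    labels = {g: classify_partition(p) for g, p in partitions.items()}
    assert labels["psbD"] is GroupLabel.CZ
    assert labels["ycf2"] is GroupLabel.CZ
    assert labels["cemA"] is GroupLabel.TW
    assert labels["psbI"] is GroupLabel.TW2
    assert labels["psbA"] is GroupLabel.ELSE
    counts = group_counts({g: l for g, l in labels.items() if g != "ycf2"})
    assert counts == {
        GroupLabel.CZ: 2,
        GroupLabel.TW: 10,
        GroupLabel.TW2: 2,
        GroupLabel.ELSE: 4,
    }


def test_select_polymorphic_genes_planted_labels():
    alignments, truth = simulate_alignments()
    labels = select_polymorphic_genes(alignments, exclude=["ycf2"])
    expected = {
        g: l
        for g, l in truth.labels.items()
        if g != "ycf2" and l is not GroupLabel.MONOMORPHIC
    }
    assert labels == expected
    counts = group_counts(labels)
    assert counts[GroupLabel.CZ] == 2
    assert counts[GroupLabel.TW] == 10


def test_select_polymorphic_genes_all_monomorphic():
    base = "ACGTACGT"
    alignments = {
        f"g{i}": GeneAlignment(f"g{i}", {s: base for s in SIX_SAMPLES}) for i in range(3)
    }
    assert select_polymorphic_genes(alignments) == {}


@given(st.data())
def test_planted_partition_recovered_for_random_plans(data):
    labels = data.draw(
        st.lists(st.integers(min_value=0, max_value=3), min_size=6, max_size=6)
    )
    classes: dict[int, set[str]] = {}
    for s, lab in zip(SIX_SAMPLES, labels):
        classes.setdefault(lab, set()).add(s)
    partition = SamplePartition.of(*classes.values())
    seed = data.draw(st.integers(min_value=0, max_value=2**20))
    config = SynthAlignmentConfig(
        plan={"gene": partition}, n_monomorphic=0, rng_seed=seed
    )
    alignments, truth = simulate_alignments(config)
    assert sample_partition(alignments["gene"]) == partition


def test_concatenate_supergene_ranges_and_identity():
    a = GeneAlignment("a", {"x": "ACGTACGTAC", "y": "ACGTACGTAC"})
    b = GeneAlignment("b", {"x": "T" * 20, "y": "T" * 19 + "C"})
    sg = concatenate_supergene([a, b])
    assert sg.alignment.length == 30
    assert sg.ranges == {"a": (0, 10), "b": (10, 30)}
    solo = concatenate_supergene([a])
    assert solo.alignment.rows == a.rows


def test_supergene_sites_are_shifted_union():
    rng = np.random.default_rng(2)
    genes = []
    for k, length in enumerate([12, 20, 9]):
        rows = {}
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        for s in ("x", "y", "z"):
            row = list(base)
            for col in rng.choice(length, size=2, replace=False):
                if rng.random() < 0.5:
                    row[col] = "ACGT"[rng.integers(0, 4)]
            rows[s] = "".join(row)
        genes.append(GeneAlignment(f"g{k}", rows))
    sg = concatenate_supergene(genes)
    expected = []
    for g in genes:
        start = sg.ranges[g.gene][0]
        expected.extend(start + s.column for s in polymorphic_sites(g))
    observed = [s.column for s in polymorphic_sites(sg.alignment)]
    assert observed == sorted(expected)


def test_concatenate_rejects_sample_mismatch():
    a = GeneAlignment("a", {"x": "AC", "y": "AC"})
    b = GeneAlignment("b", {"x": "GT", "z": "GT"})
    with pytest.raises(ValueError):
        concatenate_supergene([a, b])


def test_nexus_export_charsets(tmp_path):
    a = GeneAlignment("a", {"x": "ACGTACGTAC", "y": "ACGTACGTAC"})
    b = GeneAlignment("b", {"x": "TTTTT", "y": "TTTTC"})
    sg = concatenate_supergene([a, b])
    path = tmp_path / "sg.nex"
    write_supergene_nexus(sg, path)
    text = path.read_text()
    assert "charset a = 1-10;" in text
    assert "charset b = 11-15;" in text
    assert "dimensions ntax=2 nchar=15;" in text
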