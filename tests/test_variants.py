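"""Variant screen: HGVS parsing, LoF classes, the prevalence filter, exports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from civa.variants import (
    CIVaCandidate,
    Consequence,
    HgvsParseError,
    LofClass,
    VariantRecord,
    allele_frequency,
    civa_db_export,
    civa_db_import,
    civa_filter,
    classify_lof,
    format_hgvs_p,
    lollipop_export,
    merge_databases,
    parse_hgvs_p,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize(
    "notation,cls,pos,retained,tail,total",
    [
        ("Q1012*", Consequence.stop_gain, 1012, 1011, 0, 1011),
        ("L7Qfs*21", Consequence.frameshift, 7, 6, 20, 26),
        ("R27*", Consequence.stop_gain, 27, 26, 0, 26),
        ("Q70Kfs*7", Consequence.frameshift, 70, 69, 6, 75),
        ("p.(Q1012*)", Consequence.stop_gain, 1012, 1011, 0, 1011),
        ("Gln1012Ter", Consequence.stop_gain, 1012, 1011, 0, 1011),
        ("Leu7Glnfs*21", Consequence.frameshift, 7, 6, 20, 26),
    ],
)
def test_truncation_arithmetic(notation, cls, pos, retained, tail, total):
    c = parse_hgvs_p(notation)
    assert c.consequence is cls
    assert c.first_affected_residue == pos
    assert c.retained_wt_length == retained
    assert c.novel_tail_length == tail
    assert c.truncated_total_length == total


@pytest.mark.parametrize(
    "notation,cls",
    [
        ("M1?", Consequence.start_loss),
        ("Met1?", Consequence.start_loss),
        ("V5M", Consequence.missense),
        ("K10=", Consequence.synonymous),
        ("M1V", Consequence.start_loss),  # substitution of the initiator
    ],
)
def test_non_truncating_classes(notation, cls):
    assert parse_hgvs_p(notation).consequence is cls


@pytest.mark.parametrize("bad", ["", "Q0*", "*12", "Zz9*", "Q1012"])
def test_unparseable_notation_raises(bad):
    with pytest.raises(HgvsParseError):
        parse_hgvs_p(bad)


def test_unsupported_form_is_other_with_warning():
    with pytest.warns(UserWarning):
        c = parse_hgvs_p("Q10_L12del")
    assert c.consequence is Consequence.other


@given(
    st.sampled_from(AA),
    st.integers(2, 5000),
    st.sampled_from(AA),
    st.integers(1, 100),
    st.sampled_from(["stop", "fs", "mis", "syn"]),
)
@settings(derandomize=True, max_examples=200)
def test_parse_format_round_trip(ref, pos, alt, n, kind):
    """parse -> format -> parse is the identity on the supported dialect."""
    if kind == "stop":
        s = f"{ref}{pos}*"
    elif kind == "fs":
        s = f"{ref}{pos}{alt}fs*{n}"
    elif kind == "mis":
        s = f"{ref}{pos}{alt}"
    else:
        s = f"{ref}{pos}="
    c1 = parse_hgvs_p(s)
    c2 = parse_hgvs_p(format_hgvs_p(c1))
    assert c1 == c2


def test_classify_lof():
    assert classify_lof(parse_hgvs_p("Q1012*")) is LofClass.truncating
    assert classify_lof(parse_hgvs_p("L7Qfs*21")) is LofClass.truncating
    assert classify_lof(parse_hgvs_p("M1?")) is LofClass.start_loss
    assert classify_lof(parse_hgvs_p("V5M")) is LofClass.non_lof
    assert classify_lof(parse_hgvs_p("K10=")) is LofClass.non_lof


def _rec(gene, hgvs, src="GH", het=0, hom=0):
    return VariantRecord(gene_symbol=gene, hgvs_p=hgvs, counts={src: (het, hom)})


class TestCivaFilter:
    def test_hand_enumerated_example(self):
        records = [
            _rec("A", "Q10*", het=3),
            _rec("A", "R20*", het=1),
            _rec("B", "V5M", het=10),
            _rec("B", "L6P", het=10),
            _rec("C", "K9N", het=10),
        ]
        cands = civa_filter(records)
        assert len(cands) == 1
        assert cands[0].variant.hgvs_p == "Q10*"
        assert cands[0].n_individuals == 3

    def test_high_frequency_frameshift_with_homozygotes(self):
        # SKA3-like frameshift carried by 1906 het and 2 hom individuals
        cands = civa_filter([_rec("SKA3", "Q70Kfs*7", het=1906, hom=2)])
        assert len(cands) == 1
        assert cands[0].n_individuals == 1908
        assert cands[0].homozygous_observed is True

    def test_singleton_excluded_at_default_threshold(self):
        assert civa_filter([_rec("A", "Q10*", het=1)]) == []

    def test_brute_force_oracle_random_tables(self):
        """Filter equals a record-by-record scan of the two predicates."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            records = []
            for i in range(rng.integers(1, 200)):
                kind = rng.choice(["stop", "fs", "mis"])
                pos = int(rng.integers(2, 999))
                ref, alt = (AA[rng.integers(20)] for _ in range(2))
                hgvs = {"stop": f"{ref}{pos}*", "fs": f"{ref}{pos}{alt}fs*5",
                        "mis": f"{ref}{pos}{alt if alt != ref else 'G'}"}[kind]
                records.append(_rec(f"G{i % 7}", hgvs,
                                    het=int(rng.integers(0, 5)),
                                    hom=int(rng.integers(0, 2))))
            got = {(c.variant.gene_symbol, c.variant.hgvs_p, c.n_individuals,
                    c.homozygous_observed) for c in civa_filter(records)}
            expected = set()
            for r in records:
                truncating = r.consequence in (Consequence.stop_gain, Consequence.frameshift)
                het, hom = r.counts["GH"]
                if truncating and het + hom >= 2:
                    expected.add((r.gene_symbol, format_hgvs_p(r.parsed),
                                  het + hom, hom >= 1))
            assert got == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        records = [_rec("G", f"Q{10 + i}*", het=int(rng.integers(0, 5))) for i in range(30)]
        base = [(c.variant.hgvs_p, c.n_individuals) for c in civa_filter(records)]
        for _ in range(5):
            rng.shuffle(records)
            assert [(c.variant.hgvs_p, c.n_individuals) for c in civa_filter(records)] == base

    def test_candidate_invariants(self):
        recs = [_rec("A", "Q10*", het=5, hom=0), _rec("A", "R20*", het=0, hom=3)]
        for c in civa_filter(recs):
            assert isinstance(c, CIVaCandidate)
            assert c.n_individuals >= 2
            assert c.homozygous_observed == (c.variant.total_hom() >= 1)


class TestMergeDatabases:
    def test_same_variant_two_sources(self):
        merged = merge_databases([
            ("GH", [_rec("SPAG5", "L7Qfs*21", "GH", 134, 1)]),
            ("gnomAD", [_rec("SPAG5", "L7Qfs*21", "gnomAD", 320, 6)]),
        ])
        assert len(merged) == 1
        assert merged[0].counts == {"GH": (134, 1), "gnomAD": (320, 6)}

    def test_disjoint_concatenation(self):
        merged = merge_databases([
            ("GH", [_rec("A", "Q10*", "GH", 2, 0)]),
            ("gnomAD", [_rec("B", "R5*", "gnomAD", 3, 0)]),
        ])
        assert len(merged) == 2

    def test_counts_never_summed_across_sources(self):
        merged = merge_databases([
            ("GH", [_rec("A", "Q10*", "GH", 1, 0)]),
            ("gnomAD", [_rec("A", "Q10*", "gnomAD", 1, 0)]),
        ])
        # default carrier count = max single source, not pooled
        assert merged[0].carriers() == 1
        assert merged[0].carriers(sum_sources=True) == 2
        assert civa_filter(merged) == []
        assert len(civa_filter(merged, sum_sources=True)) == 1

    def test_spelling_dialects_unify(self):
        merged = merge_databases([
            ("GH", [_rec("A", "p.(Gln10Ter)", "GH", 2, 0)]),
            ("gnomAD", [_rec("A", "Q10*", "gnomAD", 3, 0)]),
        ])
        assert len(merged) == 1

    def test_conflicting_class_raises(self):
        # a stated class contradicting the notation is rejected at the record
        with pytest.raises(ValueError, match="contradicts"):
            VariantRecord("A", "Q10*", {"GH": (2, 0)}, consequence=Consequence.missense)
        # same source listed twice for the same variant is rejected at merge
        with pytest.raises(ValueError, match="duplicate source"):
            merge_databases([
                ("GH", [VariantRecord("A", "Q10*", {"GH": (2, 0)}),
                        VariantRecord("A", "p.(Gln10Ter)", {"GH": (3, 0)})]),
            ])

    def test_permutation_invariance(self):
        t1 = ("GH", [_rec("A", "Q10*", "GH", 2, 0), _rec("B", "R5*", "GH", 1, 0)])
        t2 = ("gnomAD", [_rec("A", "Q10*", "gnomAD", 4, 1)])
        a = merge_databases([t1, t2])
        b = merge_databases([t2, t1])
        assert [(r.gene_symbol, r.hgvs_p, r.counts) for r in a] == \
               [(r.gene_symbol, r.hgvs_p, r.counts) for r in b]


class TestAlleleFrequency:
    def test_values(self):
        assert allele_frequency(0, 0, 500) == 0.0
        assert allele_frequency(2, 1, 100) == pytest.approx(0.02)
        assert allele_frequency(0, 50, 50) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            allele_frequency(1, 0, 0)
        with pytest.raises(ValueError):
            allele_frequency(60, 50, 100)

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(derandomize=True, max_examples=60)
    def test_monotone(self, het, hom):
        n = 200
        af = allele_frequency(het, hom, n)
        assert 0 <= af <= 1
        assert (af == 0) == (het == 0 and hom == 0)
        assert allele_frequency(het + 1, hom, n) >= af
        assert allele_frequency(het, hom + 1, n) >= af


def test_lollipop_export_tabulation():
    records = [
        _rec("SPAG5", "Q1012*", het=2),
        _rec("SPAG5", "V5M", het=3),
    ]
    table = lollipop_export("SPAG5", records)
    assert table.values.tolist() == [
        [5, "missense", 3, 0],
        [1012, "truncating", 2, 0],
    ]
    assert lollipop_export("SPAG5", []).empty
    with pytest.raises(ValueError):
        lollipop_export("SPAG5", [_rec("OTHER", "Q10*", het=2)])


def test_lollipop_homozygous_column():
    table = lollipop_export("G", [_rec("G", "Q10*", het=0, hom=1)])
    assert table.iloc[0]["hom_count"] == 1


class TestCivaDb:
    def test_both_query_keys_resolve(self):
        doc = civa_db_export([("SPAG5", "Q96R06", [_rec("SPAG5", "Q1012*", het=2)])])
        assert doc["genes"]["SPAG5"]["symbol"] == "SPAG5"
        assert doc["by_uniprot"]["Q96R06"] == "SPAG5"
        assert doc["genes"][doc["by_uniprot"]["Q96R06"]]["variants"][0]["hgvs_p"] == "Q1012*"

    def test_round_trip_identity(self):
        rng = np.random.default_rng(2)
        genes = []
        for g in range(10):
            recs = [_rec(f"G{g}", f"Q{int(p)}*", het=int(rng.integers(1, 9)))
                    for p in rng.choice(np.arange(10, 500), 3, replace=False)]
            genes.append((f"G{g}", f"P{g:05d}", recs))
        doc = civa_db_export(genes)
        assert json.loads(json.dumps(doc)) == doc
        assert civa_db_export(civa_db_import(doc)) == doc

    def test_many_gene_export_count(self):
        genes = [(f"G{i}", None, [_rec(f"G{i}", "Q10*", het=2)]) for i in range(135)]
        assert len(civa_db_export(genes)["genes"]) == 135

    def test_duplicate_symbol_raises(self):
        g = ("A", None, [_rec("A", "Q10*", het=2)])
        with pytest.raises(ValueError, match="duplicate"):
            civa_db_export([g, g])
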