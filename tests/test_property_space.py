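"""Property-space unit tests: AAindex parsing, normalization, distances."""

import itertools
import math

import numpy as np
import pytest

from pase import (
    ALPHABET,
    PACKAGED_ACCESSIONS,
    ALPHA_HELIX_ALTERNATIVE,
    PropertyTable,
    Substitution,
    distance_matrix,
    load_packaged_table,
    normalize,
    parse_aaindex,
    pase_score,
    raw_distance,
    table_from_tsv,
)
from pase.property_space import (
    AAindexParseError,
    PropertySpaceError,
    packaged_aaindex_text,
)


def brute_force_distance(table, a, b, normalized=None):
    """Independent oracle: plain-Python square/sum/root over the 7 values."""
    total = 0.0
    for acc in table.accessions:
        if normalized is None:
            va, vb = table.values[(acc, a)], table.values[(acc, b)]
        else:
            va, vb = normalized[(acc, a)], normalized[(acc, b)]
        total += (va - vb) ** 2
    return math.sqrt(total)


class TestParseAAindex:
    def test_packaged_file_contains_the_seven_entries(self, table):
        assert table.accessions == PACKAGED_ACCESSIONS
        for acc in PACKAGED_ACCESSIONS:
            for res in ALPHABET:
                assert math.isfinite(table.values[(acc, res)])

    def test_known_entry_values(self, table):
        # spot values straight from the AAindex database
        assert table.values[("RADA880102", "W")] == pytest.approx(2.51)
        assert table.values[("GRAR740102", "D")] == pytest.approx(13.0)
        assert table.values[("ZIMJ680104", "R")] == pytest.approx(10.76)

    def test_empty_text_reports_missing_accession(self):
        with pytest.raises(AAindexParseError, match="accession not found"):
            parse_aaindex("", list(PACKAGED_ACCESSIONS))

    def test_truncated_i_record_names_the_accession(self):
        broken = "H RADA880102\nD x\nI  A/L\n    0.52   -1.32\n//\n"
        with pytest.raises(AAindexParseError, match="RADA880102"):
            parse_aaindex(broken, ["RADA880102"])

    def test_duplicate_entry_rejected(self):
        text = packaged_aaindex_text()
        entry = text.split("//")[0] + "//\n"
        with pytest.raises(AAindexParseError, match="duplicate"):
            parse_aaindex(entry + entry, ["RADA880102"])

    def test_serialization_round_trip(self, table):
        text = table.to_aaindex_text()
        again = parse_aaindex(text, list(table.accessions))
        assert again.accessions == table.accessions
        for key, val in table.values.items():
            assert again.values[key] == pytest.approx(val, abs=5e-4)

    def test_tsv_round_trip(self, table):
        header = "accession\t" + "\t".join(ALPHABET)
        lines = [header]
        for acc in table.accessions:
            lines.append(acc + "\t" + "\t".join(
                repr(table.values[(acc, r)]) for r in ALPHABET))
        again = table_from_tsv("\n".join(lines) + "\n")
        assert again.accessions == table.accessions
        assert all(again.values[k] == pytest.approx(v) for k, v in table.values.items())

    def test_alpha_helix_alternative_is_vendored(self):
        alt = load_packaged_table(seventh_accession=ALPHA_HELIX_ALTERNATIVE)
        assert ALPHA_HELIX_ALTERNATIVE in alt.accessions
        assert "DAWD720101" not in alt.accessions

    def test_wrong_accession_count_rejected(self, table):
        with pytest.raises(PropertySpaceError, match="exactly 7"):
            PropertyTable(table.accessions[:6], table.values)


class TestNormalize:
    def test_each_property_spans_unit_interval(self, table):
        for scheme in ("raw-global-max", "minmax-global-max", "minmax-sqrt7"):
            nt = normalize(table, scheme)
            for acc in table.accessions:
                vals = [nt.norm_values[(acc, r)] for r in ALPHABET]
                assert min(vals) == 0.0
                assert max(vals) == 1.0

    def test_already_scaled_property_unchanged(self, table):
        # replace one property by values already spanning [0, 1]
        values = dict(table.values)
        spread = [i / 19 for i in range(20)]
        for i, res in enumerate(ALPHABET):
            values[("DAWD720101", res)] = spread[i]
        nt = normalize(PropertyTable(table.accessions, values), "minmax-global-max")
        for i, res in enumerate(ALPHABET):
            assert nt.norm_values[("DAWD720101", res)] == pytest.approx(spread[i])

    def test_constant_property_rejected(self, table):
        values = dict(table.values)
        for res in ALPHABET:
            values[("GRAR740102", res)] = 4.2
        with pytest.raises(PropertySpaceError, match="GRAR740102"):
            normalize(PropertyTable(table.accessions, values))

    @pytest.mark.parametrize("scheme", ["raw-global-max", "minmax-global-max"])
    def test_scale_factor_is_exhaustive_pairwise_maximum(self, table, scheme):
        nt = normalize(table, scheme)
        norm = None if scheme == "raw-global-max" else nt.norm_values
        best = max(
            brute_force_distance(table, a, b, norm)
            for a, b in itertools.combinations(ALPHABET, 2)
        )
        assert nt.scale_factor == pytest.approx(best, rel=1e-12)
        assert nt.scale_factor > 0

    def test_unknown_scheme_rejected(self, table):
        with pytest.raises(PropertySpaceError, match="scheme"):
            normalize(table, "zscore")


class TestDistances:
    def test_identity_is_zero_and_symmetry_everywhere(self, ntable):
        for a in ALPHABET:
            assert raw_distance(a, a, ntable) == 0.0
        for a, b in itertools.combinations(ALPHABET, 2):
            assert raw_distance(a, b, ntable) == raw_distance(b, a, ntable)

    def test_matches_brute_force_oracle_on_all_ordered_pairs(self, table, ntable):
        for a, b in itertools.product(ALPHABET, repeat=2):
            expected = brute_force_distance(table, a, b)
            assert raw_distance(a, b, ntable) == pytest.approx(expected, abs=1e-9)

    def test_minmax_scheme_matches_oracle_too(self, table, ntable_minmax):
        for a, b in itertools.product(ALPHABET, repeat=2):
            expected = brute_force_distance(table, a, b, ntable_minmax.norm_values)
            assert raw_distance(a, b, ntable_minmax) == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality_over_all_triples(self, ntable):
        d = distance_matrix(ntable).to_numpy()
        n = len(ALPHABET)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_non_canonical_residue_identified_in_error(self, ntable):
        for bad in "XBZU*":
            with pytest.raises(PropertySpaceError, match=repr(bad)):
                raw_distance(bad, "A", ntable)


class TestPaseScore:
    @pytest.mark.parametrize(
        "ref,alt,display",
        [("W", "S", "0.80"), ("G", "V", "0.56"), ("I", "V", "0.14"), ("R", "Q", "0.54")],
    )
    def test_worked_examples_reproduce_published_scores(self, ntable, ref, alt, display):
        from pase import format_score
        score = pase_score(Substitution(1, ref, alt), ntable)
        assert format_score(score) == display

    def test_self_substitution_scores_zero(self, ntable):
        for res in ALPHABET:
            assert pase_score(Substitution(3, res, res), ntable) == 0.0

    def test_scores_bounded_by_one(self, ntable):
        m = distance_matrix(ntable).to_numpy()
        assert m.max() <= 1.0

    def test_affine_rescaling_invariance_under_minmax(self, table):
        # multiplying a raw property by 3 and adding 7 must not change
        # min-max scheme scores (shift and positive scale are absorbed)
        values = dict(table.values)
        for res in ALPHABET:
            values[("CHAM820102", res)] = 3.0 * values[("CHAM820102", res)] + 7.0
        shifted = normalize(PropertyTable(table.accessions, values), "minmax-global-max")
        base = normalize(table, "minmax-global-max")
        for a, b in itertools.combinations(ALPHABET, 2):
            assert shifted.score(a, b) == pytest.approx(base.score(a, b), abs=1e-12)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal_unit_maximum(self, ntable):
        m = distance_matrix(ntable).to_numpy()
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 0.0)
        assert np.all((m >= 0.0) & (m <= 1.0))
        assert m.max() == 1.0  # exactly, by the scale-factor definition

    def test_sqrt7_scheme_maximum_below_one(self, table):
        m = distance_matrix(normalize(table, "minmax-sqrt7")).to_numpy()
        assert 0.0 < m.max() < 1.0


class TestSubstitutionType:
    def test_rejects_zero_position_and_bad_residues(self):
        with pytest.raises(PropertySpaceError):
            Substitution(0, "W", "S")
        with pytest.raises(PropertySpaceError):
            Substitution(5, "J", "S")

    def test_token_form(self):
        assert str(Substitution(45, "W", "S")) == "W45S"
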