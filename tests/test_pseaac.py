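"""Type I / Type II pseudo-amino-acid composition vs the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_record
from pseaac.errors import ArgumentError, SequenceLengthError
from pseaac.io import PropertyTable
from pseaac.pseaac_core import (
    CLASSIC_PAIR,
    PseAACParams,
    correlation_theta,
    type1_pseaac,
    type2_pseaac,
)
from pseaac.synthetic import synth_proteins


class TestTheta:
    def test_zero_on_identical_residues(self, classic_table):
        props = [classic_table.normalized(a) for a in classic_table.ids()]
        for a in "ACDWY":
            assert correlation_theta(a, a, props) == 0.0

    def test_symmetric(self, classic_table):
        props = [classic_table.normalized(a) for a in classic_table.ids()]
        assert correlation_theta("A", "W", props) == pytest.approx(
            correlation_theta("W", "A", props), abs=1e-15
        )

    def test_single_property_squared_difference(self):
        prop = np.zeros(20)
        prop[0], prop[1] = 1.0, -1.0  # A=1, C=-1
        assert correlation_theta("A", "C", prop) == 4.0

    def test_unknown_residue(self, classic_table):
        props = [classic_table.normalized(a) for a in classic_table.ids()]
        with pytest.raises(ArgumentError):
            correlation_theta("A", "X", props)


class TestType1:
    def test_homopolymer_reduces_to_aac(self, classic_table):
        rec = make_record("A" * 50)
        v = type1_pseaac(rec, PseAACParams(lam=5), classic_table)
        assert len(v) == 25
        assert v.values[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(v.values[1:], 0.0, atol=1e-12)

    def test_matches_oracle_on_reference_sequence(
        self, classic_table, classic_raw_props
    ):
        rec = make_record("ACDEFGHIKL")
        v = type1_pseaac(rec, PseAACParams(lam=2, w=0.05), classic_table)
        expected = oracles.type1(
            rec.seq, 2, 0.05, list(classic_raw_props.values())
        )
        assert np.allclose(v.values, expected, atol=1e-12)

    def test_matches_oracle_fuzzed(self, classic_table, classic_raw_props, random_records):
        raw = list(classic_raw_props.values())
        for rec in random_records[:40]:
            v = type1_pseaac(rec, PseAACParams(lam=6, w=0.15), classic_table)
            expected = oracles.type1(rec.seq, 6, 0.15, raw)
            assert np.allclose(v.values, expected, atol=1e-12)

    @given(st.text(alphabet="ACD", min_size=4, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_small_sequences(
        self, classic_table, classic_raw_props, seq
    ):
        rec = make_record(seq)
        lam = min(3, rec.length - 1)
        v = type1_pseaac(rec, PseAACParams(lam=lam, w=0.05), classic_table)
        expected = oracles.type1(
            seq, lam, 0.05, list(classic_raw_props.values())
        )
        assert np.allclose(v.values, expected, atol=1e-12)

    def test_components_nonnegative_sum_to_one(self, classic_table, random_records):
        for rec in random_records[:20]:
            v = type1_pseaac(rec, PseAACParams(lam=10), classic_table)
            assert np.all(v.values >= 0)
            assert abs(v.values.sum() - 1) < 1e-12

    def test_too_short_names_lambda_and_length(self, classic_table):
        with pytest.raises(SequenceLengthError, match="31"):
            type1_pseaac(make_record("A" * 30), PseAACParams(lam=30), classic_table)

    def test_w_to_zero_limit_is_aac(self, classic_table, random_records):
        from pseaac.composition import aac

        rec = random_records[0]
        v = type1_pseaac(rec, PseAACParams(lam=8, w=1e-12), classic_table)
        assert np.max(np.abs(v.values[:20] - aac(rec).values)) <= 1e-9

    def test_tier_expectation_flat_over_lags(self, classic_table):
        """For i.i.d. residues E[tau_j] does not depend on j: empirical
        tier means across 200 seeded sequences agree within 3 SE."""
        from pseaac.pseaac_core import _property_matrix, _tier_thetas

        prop_mat = _property_matrix(classic_table, classic_table.ids())
        taus = np.array(
            [
                _tier_thetas(rec, prop_mat, 8)
                for rec in synth_proteins(seed=99, n=200, length_range=(80, 120))
            ]
        )  # (200, 8)
        means = taus.mean(axis=0)
        se = taus.std(axis=0, ddof=1) / np.sqrt(taus.shape[0])
        grand = means.mean()
        assert np.all(np.abs(means - grand) < 3 * se)


class TestType2:
    def test_dimensionality(self, classic_table):
        rec = make_record("ACDEFGHIKLMNPQRSTVWY" * 3)
        v = type2_pseaac(
            rec, PseAACParams(lam=4, properties=CLASSIC_PAIR), classic_table
        )
        assert len(v) == 28

    def test_zero_property_sequence_reduces_to_aac(self):
        """Residues whose standardized H1/H2 are 0 give all tau = 0."""
        table = PropertyTable()
        # A and C carry 0 after standardization (values at the mean)
        h = np.zeros(20)
        h[2], h[3] = 1.0, -1.0  # D, E carry the variance
        table.add("h1", h)
        table.add("h2", h * 2)
        rec = make_record("ACAC" * 5)
        v = type2_pseaac(
            rec, PseAACParams(lam=3, properties=("h1", "h2")), table
        )
        from pseaac.composition import aac

        assert np.allclose(v.values[:20], aac(rec).values, atol=1e-12)
        assert np.allclose(v.values[20:], 0.0, atol=1e-12)

    def test_matches_oracle(self, classic_table, classic_raw_props):
        rec = make_record("ACDEFGHIKL")
        v = type2_pseaac(
            rec, PseAACParams(lam=2, w=0.05, properties=CLASSIC_PAIR),
            classic_table,
        )
        expected = oracles.type2(
            rec.seq, 2, 0.05,
            classic_raw_props["hydrophobicity"],
            classic_raw_props["hydrophilicity"],
        )
        assert np.allclose(v.values, expected, atol=1e-12)

    def test_matches_oracle_fuzzed(self, classic_table, classic_raw_props, random_records):
        h1 = classic_raw_props["hydrophobicity"]
        h2 = classic_raw_props["hydrophilicity"]
        for rec in random_records[:40]:
            v = type2_pseaac(
                rec, PseAACParams(lam=5, w=0.1, properties=CLASSIC_PAIR),
                classic_table,
            )
            assert np.allclose(
                v.values, oracles.type2(rec.seq, 5, 0.1, h1, h2), atol=1e-12
            )

    def test_requires_exactly_two_properties(self, classic_table):
        with pytest.raises(ArgumentError, match="two"):
            type2_pseaac(
                make_record("ACDEFGHIKL"), PseAACParams(lam=2), classic_table
            )

    def test_w_to_zero_limit_is_aac(self, classic_table, random_records):
        from pseaac.composition import aac

        rec = random_records[1]
        v = type2_pseaac(
            rec, PseAACParams(lam=8, w=1e-12, properties=CLASSIC_PAIR),
            classic_table,
        )
        assert np.max(np.abs(v.values[:20] - aac(rec).values)) <= 1e-9
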