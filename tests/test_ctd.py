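import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzyph import (ALPHABET, DEFAULT_GROUPINGS, CTD188Extractor,
                    PropertyGrouping, aac_features,
                    bivalent_frequency_features, composition_features,
                    distribution_features, extract_188d, feature_names_188)

from _naive import (naive_aac, naive_bivalent, naive_composition,
                    naive_distribution)
from conftest import HYDRO, random_sequences

sequences = st.text(alphabet=ALPHABET, min_size=2, max_size=60)


class TestGroupingValidation:
    def test_defaults_partition_alphabet(self):
        for g in DEFAULT_GROUPINGS:
            assert sorted("".join(g.groups)) == sorted(ALPHABET)

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError):
            PropertyGrouping("bad", ("ACDEF", "GHIKL", "MNPQR"))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            PropertyGrouping("bad", ("ACDEFG", "GHIKLMN", "PQRSTVWY"))


class TestAAC:
    def test_simple_counts(self):
        v = aac_features("AAAC")
        assert v[0] == 0.75 and v[1] == 0.25 and v[2:].sum() == 0

    def test_uniform_sequence(self):
        assert np.allclose(aac_features(ALPHABET), 0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aac_features("")


class TestComposition:
    def test_hand_counted_example(self):
        # R,K -> group1; G,A -> group2; C,V -> group3
        assert np.allclose(composition_features("RKGACV", HYDRO), [1/3, 1/3, 1/3])

    def test_single_group_sequence(self):
        assert np.allclose(composition_features("RRRR", HYDRO), [1, 0, 0])


class TestDistribution:
    def test_hand_computed_mixed_sequence(self):
        v = distribution_features("RGRGR", HYDRO)
        assert np.allclose(v[:5], [0.2, 0.2, 0.6, 1.0, 1.0])     # R at 1,3,5
        assert np.allclose(v[5:10], [0.4, 0.4, 0.4, 0.8, 0.8])   # G at 2,4
        assert np.allclose(v[10:], 0)                            # empty group

    def test_hand_computed_single_group(self):
        v = distribution_features("RRRR", HYDRO)
        assert np.allclose(v[:5], [0.25, 0.25, 0.5, 0.75, 1.0])
        assert np.allclose(v[5:], 0)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing_within_group(self, seq):
        v = distribution_features(seq, HYDRO)
        for g in range(3):
            block = v[5 * g: 5 * g + 5]
            if block.any():
                assert np.all(np.diff(block) >= 0)
                assert 0 < block[0] and block[-1] <= 1


class TestBivalentFrequency:
    def test_single_cross_pair(self):
        assert np.allclose(bivalent_frequency_features("RG", HYDRO), [1, 0, 0])

    def test_no_cross_pairs(self):
        assert np.allclose(bivalent_frequency_features("RRRR", HYDRO), 0)

    def test_length_one_raises(self):
        with pytest.raises(ValueError):
            bivalent_frequency_features("R", HYDRO)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_sum_at_most_one(self, seq):
        assert bivalent_frequency_features(seq, HYDRO).sum() <= 1 + 1e-12


class TestOracleEquivalence:
    """Every 188D block matches a naive per-character/per-pair reference."""

    def test_all_blocks_on_random_sequences(self, rng):
        for seq in random_sequences(rng, 100):
            assert np.allclose(aac_features(seq), naive_aac(seq), atol=1e-12)
            for grouping in DEFAULT_GROUPINGS:
                g = grouping.groups
                assert np.allclose(composition_features(seq, grouping),
                                   naive_composition(seq, g), atol=1e-12)
                assert np.allclose(distribution_features(seq, grouping),
                                   naive_distribution(seq, g), atol=1e-12)
                assert np.allclose(bivalent_frequency_features(seq, grouping),
                                   naive_bivalent(seq, g), atol=1e-12)


class TestFullVector:
    def test_length_is_188(self):
        assert extract_188d("MKVLAGRSTEDQNHPYWCFI").shape == (188,)

    def test_name_at_index_43_is_medium_vdw_composition(self):
        names = feature_names_188()
        assert names[42] == "normalized_vdw_volume.composition.2"

    def test_block_layout_via_name_registry(self):
        # 1-based index of composition feature g of property k: 20 + 21(k-1) + g
        names = feature_names_188()
        for k, grouping in enumerate(DEFAULT_GROUPINGS, start=1):
            for g in (1, 2, 3):
                idx = 20 + 21 * (k - 1) + g
                assert names[idx - 1] == f"{grouping.name}.composition.{g}"

    def test_deterministic(self):
        seq = "MKVLAGRSTEDQNH"
        assert np.array_equal(extract_188d(seq), extract_188d(seq))

    def test_wrong_grouping_count_raises(self):
        with pytest.raises(ValueError, match="8"):
            extract_188d("MKVL", DEFAULT_GROUPINGS[:3])

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_invariants(self, seq):
        v = extract_188d(seq)
        assert np.all(v >= 0) and np.all(v <= 1 + 1e-12)
        assert abs(v[:20].sum() - 1) < 1e-9
        for k in range(8):
            comp = v[20 + 21 * k: 23 + 21 * k]
            assert abs(comp.sum() - 1) < 1e-9


class TestExtractorAPI:
    def test_transform_shape_and_names(self):
        ext = CTD188Extractor().fit(["MKVL"])
        X = ext.transform(["MKVL", "GGACD"])
        assert X.shape == (2, 188)
        assert list(ext.get_feature_names_out()) == feature_names_188()

    def test_accepts_records_with_sequence_attribute(self):
        from enzyph import ProteinRecord
        X = CTD188Extractor().fit_transform([ProteinRecord("a", "MKVL")])
        assert np.allclose(X[0], extract_188d("MKVL"))
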