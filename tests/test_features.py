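"""Feature encoding: normalization, signal sampling, one-hot, matrices, join."""

import itertools

import numpy as np
import pytest

from m6aduet.features import (
    DegenerateSignalError,
    FeatureConfig,
    SiteCoverageError,
    build_error_feature,
    build_raw_signal_feature,
    encode_fivemer_onehot,
    extract_site_read_features,
    load_features,
    normalize_read_signals,
    sample_base_signals,
    save_features,
)
from m6aduet.io import BaseAlignmentRecord, CandidateSite, Event, EventAlignedRead
from tests.conftest import random_read


class TestNormalization:
    def test_hand_computed_median_mad(self):
        read = EventAlignedRead("r", "t", [Event(0, "A", (1.0, 2.0, 3.0, 4.0, 5.0))])
        norm = normalize_read_signals(read)
        assert norm.events[0].signals == (-2.0, -1.0, 0.0, 1.0, 2.0)

    def test_already_normalized_fixed_point(self):
        read = EventAlignedRead("r", "t", [Event(0, "A", (-1.0, 0.0, 1.0))])
        norm = normalize_read_signals(read)
        assert norm.events[0].signals == read.events[0].signals

    def test_post_normalization_statistics(self, rng):
        for _ in range(20):
            read = random_read(rng, n_events=int(rng.integers(3, 20)))
            norm = normalize_read_signals(read)
            sig = norm.all_signals()
            assert abs(np.median(sig)) < 1e-9
            assert abs(np.median(np.abs(sig - np.median(sig))) - 1.0) < 1e-9

    def test_constant_signal_rejected(self):
        read = EventAlignedRead("r", "t", [Event(0, "A", (2.0, 2.0, 2.0))])
        with pytest.raises(DegenerateSignalError):
            normalize_read_signals(read)


class TestSampleBaseSignals:
    def test_short_base_zero_padded(self, rng):
        out = sample_base_signals([1.0, 2.0, 3.0], 65, rng)
        assert out.shape == (65,)
        assert list(out[:3]) == [1.0, 2.0, 3.0]
        assert np.count_nonzero(out[3:]) == 0 and out[3:].size == 62

    def test_exact_length_identity(self, rng):
        sig = np.arange(65, dtype=float)
        assert np.array_equal(sample_base_signals(sig, 65, rng), sig)

    def test_subset_preserves_temporal_order(self):
        sig = np.random.default_rng(5).normal(size=200)
        out = sample_base_signals(sig, 65, np.random.default_rng(9))
        assert out.shape == (65,)
        # out must be a subsequence of sig (order preserved, no replacement)
        it = iter(sig.astype(np.float32))
        assert all(any(abs(v - w) == 0 for w in it) for v in out)

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_base_signals([], 5, rng)


class TestOneHot:
    def test_homopolymer(self):
        m = encode_fivemer_onehot("AAAAA")
        assert np.array_equal(m[0], np.ones(5)) and m[1:].sum() == 0

    def test_column_sums_one(self):
        m = encode_fivemer_onehot("ACGTA")
        assert np.array_equal(m.sum(axis=0), np.ones(5))

    def test_exhaustive_round_trip(self):
        for kmer in itertools.product("ACGT", repeat=5):
            s = "".join(kmer)
            m = encode_fivemer_onehot(s)
            assert "".join("ACGT"[i] for i in m.argmax(axis=0)) == s

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            encode_fivemer_onehot("ACGNA")


def _read_over(fivemer: str, signals_per_base, read_id="r", tx="t", start=0):
    events = [
        Event(start + i, b, tuple(signals_per_base[i])) for i, b in enumerate(fivemer)
    ]
    return EventAlignedRead(read_id, tx, events)


class TestRawSignalFeature:
    def test_default_shape(self, rng):
        read = _read_over("GGACT", [rng.normal(size=7) for _ in range(5)])
        site = CandidateSite("t", 2, "GGACT", "RRACH")
        m = build_raw_signal_feature(read, site)
        assert m.shape == (5, 325)

    def test_zero_signals_leave_onehot_untouched(self):
        read = _read_over("GGACT", [[0.0, 0.0] for _ in range(5)])
        site = CandidateSite("t", 2, "GGACT", "RRACH")
        m = build_raw_signal_feature(read, site)
        assert not m[4].any()
        assert np.array_equal(m[:4, ::65], encode_fivemer_onehot("GGACT"))

    def test_onehot_blocks_constant_and_sum_one(self, rng):
        read = _read_over("AGACC", [rng.normal(size=int(rng.integers(1, 120)))
                                    for _ in range(5)])
        site = CandidateSite("t", 2, "AGACC", "DRACH")
        m = build_raw_signal_feature(read, site)
        for b in range(5):
            block = m[:4, b * 65 : (b + 1) * 65]
            assert np.array_equal(block, np.repeat(block[:, :1], 65, axis=1))
            assert np.array_equal(block.sum(axis=0), np.ones(65))

    def test_uncovered_site_raises(self, rng):
        read = _read_over("GGACT", [rng.normal(size=3) for _ in range(5)], start=10)
        site = CandidateSite("t", 2, "GGACT", "RRACH")
        with pytest.raises(SiteCoverageError):
            build_raw_signal_feature(read, site)

    def test_deterministic_per_read_site_seed(self, rng):
        sigs = [rng.normal(size=100) for _ in range(5)]
        read = _read_over("GGACT", sigs)
        site = CandidateSite("t", 2, "GGACT", "RRACH")
        a = build_raw_signal_feature(read, site, FeatureConfig(seed=3))
        b = build_raw_signal_feature(read, site, FeatureConfig(seed=3))
        assert np.array_equal(a, b)
        c = build_raw_signal_feature(read, site, FeatureConfig(seed=4))
        assert not np.array_equal(a, c)

    def test_affine_invariance(self, rng):
        sigs = [rng.normal(90, 10, size=int(rng.integers(2, 90))) for _ in range(5)]
        read = normalize_read_signals(_read_over("GGACT", sigs))
        shifted = normalize_read_signals(
            _read_over("GGACT", [3.5 * s + 120.0 for s in sigs])
        )
        site = CandidateSite("t", 2, "GGACT", "RRACH")
        a = build_raw_signal_feature(read, site, FeatureConfig(seed=0))
        b = build_raw_signal_feature(shifted, site, FeatureConfig(seed=0))
        assert np.allclose(a, b, atol=1e-5)


def _fivemer_records(fivemer, statuses, quals, ins, tx="t", read="r", start=0):
    return [
        BaseAlignmentRecord(read, tx, start + i, fivemer[i], statuses[i], quals[i], ins[i])
        for i in range(5)
    ]


def _oracle_error_matrix(fivemer, statuses, quals, ins, quality_scale=40.0):
    """Straight-line reference encoder, independent of the implementation."""
    m = np.zeros((8, 5))
    for j in range(5):
        m["ACGT".index(fivemer[j]), j] = 1
        if statuses[j] == "deletion":
            m[6, j] = 1
        else:
            m[4, j] = min(max(quals[j] / quality_scale, 0), 1)
            if statuses[j] == "mismatch":
                m[5, j] = 1
        m[7, j] = ins[j]
    return m


class TestErrorFeature:
    SITE = CandidateSite("t", 2, "GGACT", "RRACH")

    def test_error_free_case(self):
        recs = _fivemer_records("GGACT", ["match"] * 5, [40] * 5, [0] * 5)
        m = build_error_feature(recs, self.SITE)
        assert m.shape == (8, 5)
        assert np.array_equal(m[4], np.ones(5))
        assert not m[5:].any()

    def test_central_deletion(self):
        recs = _fivemer_records(
            "GGACT", ["match", "match", "deletion", "match", "match"],
            [30, 30, -1, 30, 30], [0] * 5,
        )
        m = build_error_feature(recs, self.SITE)
        assert m[6, 2] == 1 and m[4, 2] == 0 and m[5, 2] == 0

    def test_matches_independent_oracle(self, rng):
        for _ in range(30):
            statuses = [
                ["match", "mismatch", "deletion", "insertion-adjacent"][rng.integers(4)]
                for _ in range(5)
            ]
            quals = [-1 if s == "deletion" else int(rng.integers(0, 60)) for s in statuses]
            ins = [int(rng.integers(0, 4)) for _ in range(5)]
            recs = _fivemer_records("GGACT", statuses, quals, ins)
            m = build_error_feature(recs, self.SITE)
            assert np.allclose(m, _oracle_error_matrix("GGACT", statuses, quals, ins))

    def test_missing_position_raises(self):
        recs = _fivemer_records("GGACT", ["match"] * 5, [30] * 5, [0] * 5)[:4]
        with pytest.raises(SiteCoverageError):
            build_error_feature(recs, self.SITE)


class TestExtraction:
    def test_counts_match_brute_force_join(self, tiny_dataset, tiny_features):
        ds = tiny_dataset
        aln_keys = {(r.read_id, r.transcript_id, r.ref_position) for r in ds.alignments}
        expected = 0
        for read in ds.reads:
            start, end = read.span
            for site in ds.sites:
                if site.transcript_id != read.transcript_id:
                    continue
                pos = range(site.position - 2, site.position + 3)
                if all(start <= p < end for p in pos) and all(
                    (read.read_id, read.transcript_id, p) in aln_keys for p in pos
                ):
                    expected += 1
        assert len(tiny_features) == expected > 0

    def test_missing_alignment_records_tallied(self, tiny_dataset):
        ds = tiny_dataset
        first_read = ds.reads[0].read_id
        alns = [r for r in ds.alignments if r.read_id != first_read]
        tally = {}
        feats = list(
            extract_site_read_features(ds.reads, alns, ds.sites, FeatureConfig(), tally=tally)
        )
        n_sites_first_tx = sum(
            1 for s in ds.sites if s.transcript_id == ds.reads[0].transcript_id
        )
        assert tally["pairs_skipped"] == n_sites_first_tx
        assert all(f.read_id != first_read for f in feats)

    def test_deterministic_given_seed(self, tiny_dataset):
        ds = tiny_dataset
        cfg = FeatureConfig(seed=11)
        a = list(extract_site_read_features(ds.reads, ds.alignments, ds.sites, cfg))
        b = list(extract_site_read_features(ds.reads, ds.alignments, ds.sites, cfg))
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert fa.key == fb.key
            assert np.array_equal(fa.raw_signal_matrix, fb.raw_signal_matrix)
            assert np.array_equal(fa.error_matrix, fb.error_matrix)

    def test_labels_attached(self, tiny_features, tiny_dataset):
        assert all(f.label in (0, 1) for f in tiny_features)
        truth = tiny_dataset.read_labels
        assert all(truth[f.key] == f.label for f in tiny_features)

    def test_hdf5_round_trip(self, tmp_path, tiny_features):
        path = tmp_path / "feat.h5"
        n = save_features(path, tiny_features)
        back = load_features(path)
        assert n == len(back) == len(tiny_features)
        for a, b in zip(tiny_features, back):
            assert a.key == b.key and a.label == b.label
            assert np.array_equal(a.raw_signal_matrix, b.raw_signal_matrix)
            assert np.array_equal(a.error_matrix, b.error_matrix)
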