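"""Shearing, hybridization capture, PCR bias, and read simulation."""

import numpy as np
import pytest

from capturesim import capture_sim as cs
from capturesim.capture_sim import (
    HybridizationModel,
    PcrModel,
    ReadSimParams,
    SourceSeq,
    amplify,
    best_probe_identity,
    build_libraries,
    community_sources,
    hybridize,
    sequence_reads,
    shear,
    ungapped_overlap_identity,
)
from capturesim.community_sim import CommunitySample, embed_marker_in_genome
from capturesim.marker_db import reverse_complement
from capturesim.probe_design import ProbeDesignParams, design_array, tile_probes

from _helpers import random_dna


@pytest.fixture(scope="module")
def family_probes(small_family):
    return design_array(small_family)


class TestShear:
    def test_fragment_lengths_match_request(self):
        rng = np.random.default_rng(0)
        src = [SourceSeq("g", random_dna(rng, 10_000), 1.0)]
        pool = shear(src, mean_len=500, sd=80, n_fragments=1000, seed=1)
        assert abs(pool.lengths.mean() - 500) < 30

    def test_fragments_never_exceed_source(self):
        rng = np.random.default_rng(1)
        src = [SourceSeq("g", random_dna(rng, 300), 1.0)]
        pool = shear(src, mean_len=500, sd=150, n_fragments=500, seed=2)
        assert (pool.starts >= 0).all()
        assert (pool.ends <= 300).all()
        assert (pool.lengths >= 50).all()

    def test_marker_bearing_fraction_tracks_marker_length(self):
        rng = np.random.default_rng(2)
        L, mlen = 50_000, 5_000
        seq = random_dna(rng, L)
        src = [SourceSeq("g", seq, 1.0, (("m", 20_000, 20_000 + mlen),))]
        pool = shear(src, mean_len=500, sd=50, n_fragments=4000, seed=3)
        # P(overlap) ~ (marker + fragment length) / genome length
        expected = (mlen + 500) / L
        frac = pool.marker_fraction()
        sd = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(frac - expected) < 5 * sd

    def test_empty_sources_rejected(self):
        with pytest.raises(ValueError):
            shear([], 500, 100, 10, seed=0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        src = [SourceSeq("g", random_dna(rng, 5000), 1.0)]
        a = shear(src, 400, 60, 100, seed=5)
        b = shear(src, 400, 60, 100, seed=5)
        assert np.array_equal(a.buffer, b.buffer)
        assert np.array_equal(a.starts, b.starts)


class TestHybridizationModel:
    def test_probability_floor_and_ceiling(self):
        m = HybridizationModel()
        assert m.capture_probability(0.0) == pytest.approx(1e-4)
        assert m.capture_probability(0.54) == pytest.approx(1e-4)
        assert m.capture_probability(1.0) == pytest.approx(0.95)

    def test_probability_monotone_in_identity(self):
        m = HybridizationModel()
        grid = np.linspace(0, 1, 101)
        p = m.capture_probability(grid)
        assert (np.diff(p) >= 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HybridizationModel(p_background=0.99, p_on_max=0.95)
        with pytest.raises(ValueError):
            HybridizationModel(min_identity=0.0)

    def test_ungapped_overlap_identity_definition(self):
        probe = "ACGTACGTACGT"
        frag = "TT" + probe + "GG"
        assert ungapped_overlap_identity(probe, frag, 2, min_overlap=4) == 1.0
        # one mismatch in a 12 nt overlap
        frag2 = "TT" + "ACGTACGTACGA" + "GG"
        assert ungapped_overlap_identity(probe, frag2, 2, 4) == pytest.approx(11 / 12)
        # overlap below the floor scores zero
        assert ungapped_overlap_identity(probe, frag, 14, min_overlap=4) == 0.0


class TestHybridize:
    def test_on_target_fragment_captured_at_p_on_max(self, small_family, family_probes):
        rec = small_family.records[0]
        model = HybridizationModel()
        ident = best_probe_identity(rec.seq[100:500], family_probes, model)
        assert ident == 1.0
        assert model.capture_probability(ident) == pytest.approx(0.95)

    def test_unrelated_fragment_scores_below_threshold(self, family_probes):
        rng = np.random.default_rng(7)
        model = HybridizationModel()
        ident = best_probe_identity(random_dna(rng, 400), family_probes, model)
        assert model.capture_probability(ident) == pytest.approx(model.p_background)

    def test_reverse_strand_fragment_scores_like_forward(self, small_family, family_probes):
        rec = small_family.records[0]
        model = HybridizationModel()
        fwd = best_probe_identity(rec.seq[100:500], family_probes, model)
        rev = best_probe_identity(reverse_complement(rec.seq[100:500]), family_probes, model)
        assert rev == pytest.approx(fwd)

    def test_enrichment_matches_closed_form_expectation(self, small_family, family_probes):
        # marker:background ratio scales by ~ p_on/p_background => ~3-4 logs
        rng = np.random.default_rng(8)
        rec = small_family.records[0]
        sources = [
            SourceSeq(rec.id, rec.seq, 0.02 * len(rec.seq) / 50_000,
                      ((rec.id, 0, len(rec.seq)),)),
            SourceSeq("bg", random_dna(rng, 50_000), 0.98),
        ]
        pool = shear(sources, 500, 100, 60_000, seed=9)
        captured, stats = hybridize(pool, family_probes, HybridizationModel(seed=10))
        model = HybridizationModel()
        expected = np.log10(model.p_on_max / model.p_background)  # 3.98
        assert stats.log10_fold_enrichment == pytest.approx(expected, abs=0.5)
        assert stats.log10_fold_enrichment >= 3.0

    def test_empty_probe_set_rejected(self, small_family, family_probes):
        pool = shear([SourceSeq("g", small_family.records[0].seq, 1.0)], 300, 50, 10, seed=0)
        empty = design_array(small_family)
        empty.probes = []
        with pytest.raises(ValueError):
            hybridize(pool, empty)


class TestAmplify:
    def _templates(self, seqs, markers=None):
        from capturesim.capture_sim import FragmentPool

        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(lens)])
        buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).copy()
        n = len(seqs)
        carries = np.ones(n, dtype=bool) if markers is None else np.asarray(markers)
        return FragmentPool(
            buffer=buf, offsets=offsets,
            source_index=np.arange(n), source_ids=[f"t{i}" for i in range(n)],
            starts=np.zeros(n, dtype=np.int64), ends=lens.copy(),
            carries_marker=carries,
            marker_index=np.where(carries, np.arange(n), -1),
            marker_ids=[f"t{i}" for i in range(n)],
        )

    def test_equal_gc_equal_weights(self):
        rng = np.random.default_rng(1)
        pool = self._templates([random_dna(rng, 400, gc=0.4) for _ in range(2)])
        out = amplify(pool, PcrModel(cycles=30))
        assert out.weights[0] == pytest.approx(out.weights[1], rel=1e-3)

    def test_gc_bias_closed_form(self):
        # weight ratio (1+e(low))^c / (1+e(high))^c, high-GC underrepresented
        hi = "GC" * 200 + "AT" * 104  # GC ~ 0.66
        lo = "AT" * 200 + "GC" * 97   # GC ~ 0.33
        model = PcrModel(cycles=30)
        pool = self._templates([hi + "", lo])
        gc_hi = (hi.count("G") + hi.count("C")) / len(hi)
        gc_lo = (lo.count("G") + lo.count("C")) / len(lo)
        out = amplify(pool, model)
        expected_ratio = (
            (1 + model.efficiency(gc_lo)) ** 30 / (1 + model.efficiency(gc_hi)) ** 30
        )
        assert out.weights[1] / out.weights[0] == pytest.approx(expected_ratio, rel=1e-9)
        assert out.weights[1] > out.weights[0]

    def test_zero_cycles_uniform(self):
        rng = np.random.default_rng(2)
        pool = self._templates(
            [random_dna(rng, 300, gc=g) for g in (0.3, 0.5, 0.7)]
        )
        out = amplify(pool, PcrModel(cycles=0))
        assert np.allclose(out.weights, 1 / 3)

    def test_bias_off_control_uniform(self):
        rng = np.random.default_rng(3)
        pool = self._templates([random_dna(rng, 300, gc=g) for g in (0.3, 0.7)])
        out = amplify(pool, PcrModel(cycles=40, gc_penalty=0.0))
        assert out.weights[0] == pytest.approx(out.weights[1], rel=1e-9)

    def test_nontarget_weight_zero_and_no_target_errors(self):
        rng = np.random.default_rng(4)
        pool = self._templates([random_dna(rng, 300)] * 2, markers=[True, False])
        out = amplify(pool, PcrModel())
        assert out.weights[1] == 0.0
        none = self._templates([random_dna(rng, 300)], markers=[False])
        with pytest.raises(ValueError, match="template"):
            amplify(none, PcrModel())


class TestSequenceReads:
    def _pool(self, seq):
        return shear([SourceSeq("src", seq, 1.0, (("src", 0, len(seq)),))],
                     mean_len=400, sd=0.0, n_fragments=50, seed=1)

    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 3000)
        pool = self._pool(seq)
        reads = sequence_reads(pool, ReadSimParams(n_read_pairs=100,
                                                   substitution_error_rate=0.0, seed=2))
        for i in range(len(reads)):
            _, s1, s2 = reads.pair(i)
            assert s1 in seq
            assert reverse_complement(s2) in seq

    def test_mate2_is_rc_of_fragment_tail(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 2000)
        pool = self._pool(seq)
        reads = sequence_reads(pool, ReadSimParams(n_read_pairs=20,
                                                   substitution_error_rate=0.0, seed=3))
        _, s1, s2 = reads.pair(0)
        # find the fragment the read came from by matching its 5' end
        for frag in pool:
            if frag.seq.startswith(s1):
                assert s2 == reverse_complement(frag.seq[-len(s2):])
                break
        else:
            pytest.fail("read not traceable to a fragment")

    def test_observed_mismatch_rate_matches_request(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 5000)
        pool = self._pool(seq)
        params = ReadSimParams(n_read_pairs=400, substitution_error_rate=0.005, seed=4)
        reads = sequence_reads(pool, params)
        # an error-free run under the same seed draws the same fragments,
        # so differing cells are exactly the injected substitutions
        clean = sequence_reads(pool, ReadSimParams(n_read_pairs=400,
                                                   substitution_error_rate=0.0, seed=4))
        valid = reads.r1 != 0
        mism = int(((reads.r1 != clean.r1) & valid).sum())
        total = int(valid.sum())
        rate = mism / total
        assert abs(rate - 0.005) < 3 * np.sqrt(0.005 / total)

    def test_empty_pool_rejected(self):
        rng = np.random.default_rng(8)
        pool = self._pool(random_dna(rng, 1000)).subset(np.array([], dtype=np.int64))
        with pytest.raises(ValueError):
            sequence_reads(pool, ReadSimParams(n_read_pairs=5))

    def test_fastq_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        pool = self._pool(random_dna(rng, 2000))
        reads = sequence_reads(pool, ReadSimParams(n_read_pairs=30, seed=5))
        reads.to_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        from capturesim.capture_sim import PairedReads

        back = PairedReads.from_fastq(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert len(back) == 30
        assert back.pair(0)[1] == reads.pair(0)[1]
        assert back.pair(29)[2] == reads.pair(29)[2]


@pytest.fixture(scope="module")
def zymo_small():
    from capturesim.bench import zymo_community

    return zymo_community(3)


class TestBuildLibraries:

    def test_capture_enriches_marker_reads_over_shotgun(self, zymo_small):
        db, sample = zymo_small
        probes = design_array(db)
        bundle = build_libraries(
            sample, db, probes,
            read_params=ReadSimParams(n_read_pairs=2000),
            n_fragments=20_000, seed=4,
        )
        cap = bundle.capture.marker_fraction()
        sg = bundle.shotgun.marker_fraction()
        assert cap > 10 * sg
        assert bundle.enrichment.log10_fold_enrichment > 1.0
        assert bundle.amplicon.marker_fraction() == 1.0

    def test_manifest_records_all_seeds_and_params(self, zymo_small):
        db, sample = zymo_small
        probes = design_array(db)
        bundle = build_libraries(sample, db, probes,
                                 read_params=ReadSimParams(n_read_pairs=200),
                                 n_fragments=2000, seed=5)
        m = bundle.manifest
        assert set(m["arm_seeds"]) == {"shear", "shotgun", "hybridize",
                                       "capture_reads", "amplicon_reads"}
        assert m["seed"] == 5
        assert m["hybridization"]["p_on_max"] == 0.95
        assert m["pcr"]["cycles"] == 40

    def test_bit_reproducible_under_seed(self, zymo_small):
        db, sample = zymo_small
        probes = design_array(db)
        kw = dict(read_params=ReadSimParams(n_read_pairs=300), n_fragments=3000, seed=6)
        a = build_libraries(sample, db, probes, **kw)
        b = build_libraries(sample, db, probes, **kw)
        for arm in ("capture", "shotgun", "amplicon"):
            assert np.array_equal(a.arms[arm].r1, b.arms[arm].r1)
            assert np.array_equal(a.arms[arm].r2, b.arms[arm].r2)

    def test_unspiked_sample_has_no_panel_reads(self, ut_only_family):
        rec = ut_only_family.records[-1]
        genome = embed_marker_in_genome(rec, 20_000, gc=0.45, seed=6)
        sample = CommunitySample(
            "unspiked",
            members=[(rid, 0.0) for rid in ut_only_family.ids[:6]],
            abundance_mode="copies",
            background=[(genome, 1e9)],
        )
        probes = design_array(ut_only_family)
        bundle = build_libraries(
            sample, ut_only_family, probes,
            read_params=ReadSimParams(n_read_pairs=500, substitution_error_rate=0.0),
            n_fragments=5000, seed=7,
        )
        panel_ids = set(ut_only_family.ids[:6])
        for arm, reads in bundle.arms.items():
            srcs = {reads.source_ids[i] for i in reads.source_index}
            assert not (srcs & panel_ids), arm
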