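"""mtpt detection, old/new classification, GC statistics, tRNA transfer."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from organelle_dynamics.datasets import COMPARATIVE_MTPT_GC
from organelle_dynamics.quadripartite import QuadripartiteMap
from organelle_dynamics.seqio import (AnnotatedGenome, CircularSequence,
                                      write_fasta)
from organelle_dynamics.synthetic_data import (SimScenario, random_sequence,
                                               simulate_transfer_pair,
                                               simulate_trna_sets)
from organelle_dynamics.transfer import (AlignmentParams, InsertionHit,
                                         classify_age, classify_trnas,
                                         find_cp_derived, pearson_r,
                                         region_of_origin,
                                         summarize_transfer, welch_t)

FIVE_FRAGMENTS = [
    (200, 3000, 1.0, 5000, "+"),
    (4000, 800, 0.95, 12000, "-"),
    (8000, 300, 0.90, 20000, "+"),
    (9000, 150, 0.85, 30000, "+"),
    (11000, 60, 0.92, 40000, "-"),
]


@pytest.fixture(scope="module")
def planted_pair():
    scn = SimScenario(seed=3, length=60_000,
                      planted_insertions=FIVE_FRAGMENTS)
    return simulate_transfer_pair(scn)


def matches_truth(hit, truth, slack=5):
    ts, te = truth.mt_interval
    hs, he = hit.mt_interval
    return abs(hs - ts) <= slack and abs(he - te) <= slack


class TestFindCpDerived:
    def test_all_planted_fragments_recovered(self, planted_pair):
        mt, cp, qmap, truth = planted_pair
        hits = find_cp_derived(mt, cp)
        assert len(hits) == len(truth)
        for t in truth:
            assert any(matches_truth(h, t) for h in hits)

    def test_recovered_identity_and_gc_match_truth(self, planted_pair):
        """Hit identity tracks the planted identity; hit GC tracks the
        planted fragment's GC, with a tolerance that accounts for the few
        mismatching edge bases the maximal-scoring alignment trims."""
        mt, cp, qmap, truth = planted_pair
        hits = find_cp_derived(mt, cp)
        for t in truth:
            h = next(h for h in hits if matches_truth(h, t))
            assert h.identity == pytest.approx(t.identity, abs=0.02)
            gc_tol = 0.01 if t.aligned_length >= 300 else 12 / t.aligned_length
            assert h.gc == pytest.approx(t.gc, abs=gc_tol)

    def test_unrelated_genomes_give_no_hits(self):
        rng = np.random.default_rng(17)
        mt = AnnotatedGenome(CircularSequence("mt", random_sequence(rng, 40_000, 0.43)))
        cp = AnnotatedGenome(CircularSequence("cp", random_sequence(rng, 15_000, 0.43)))
        assert find_cp_derived(mt, cp) == []

    def test_below_identity_threshold_rejected(self):
        """A 60 bp fragment planted at identity 0.70 (min_identity - 0.10)
        must not be reported at the 0.80 screen."""
        scn = SimScenario(seed=21, length=40_000,
                          planted_insertions=[(5000, 60, 0.70, 9000, "+")])
        mt, cp, _, _ = simulate_transfer_pair(scn)
        hits = find_cp_derived(mt, cp)
        assert all(not (8990 <= h.mt_interval[0] <= 9070) for h in hits)

    def test_tiny_genome_returns_empty_with_warning(self, caplog):
        mt = AnnotatedGenome(CircularSequence("mt", "ACGT" * 10))
        cp = AnnotatedGenome(CircularSequence("cp", "ACGT" * 10))
        with caplog.at_level("WARNING"):
            assert find_cp_derived(mt, cp) == []

    def test_indel_robustness_of_chaining(self):
        """A fragment with a small internal deletion is still recovered as
        one merged hit by diagonal chaining."""
        rng = np.random.default_rng(33)
        cp_seq = random_sequence(rng, 12_000, 0.38)
        frag = cp_seq[2000:3200]
        frag = frag[:600] + frag[605:]  # 5 bp deletion
        mt_seq = random_sequence(rng, 30_000, 0.43)
        mt_seq = mt_seq[:8000] + frag + mt_seq[8000 + len(frag):]
        mt = AnnotatedGenome(CircularSequence("mt", mt_seq))
        cp = AnnotatedGenome(CircularSequence("cp", cp_seq))
        hits = find_cp_derived(mt, cp)
        big = [h for h in hits if h.aligned_length > 1000]
        assert len(big) == 1
        assert big[0].identity > 0.99

    def test_blastn_agrees_on_planted_fragments(self, planted_pair, tmp_path):
        """Independent cross-check: NCBI blastn recovers the same mt-side
        loci as the built-in aligner on the planted scenario."""
        if shutil.which("blastn") is None:
            pytest.fail("blastn not on PATH; cross-check cannot run")
        mt, cp, qmap, truth = planted_pair
        mt_fa, cp_fa = tmp_path / "mt.fa", tmp_path / "cp.fa"
        write_fasta(mt, mt_fa)
        write_fasta(cp, cp_fa)
        res = subprocess.run(
            ["blastn", "-task", "blastn", "-query", str(mt_fa),
             "-subject", str(cp_fa), "-evalue", "1e-5",
             "-outfmt", "6 qstart qend pident length"],
            capture_output=True, text=True, check=True)
        blast_hits = []
        for line in res.stdout.strip().split("\n"):
            qs, qe, pid, ln = line.split("\t")
            if float(pid) >= 80 and int(ln) >= 50:
                blast_hits.append((int(qs), int(qe)))
        ours = find_cp_derived(mt, cp)
        assert len(ours) == len(truth)
        for h in ours:
            hs, he = h.mt_interval
            assert any(abs(bs - hs) <= 10 and abs(be - he) <= 10
                       for bs, be in blast_hits)


class TestClassifyAge:
    def test_verbatim_copy_in_panel_is_old(self, planted_pair):
        mt, cp, qmap, truth = planted_pair
        hits = find_cp_derived(mt, cp)
        rng = np.random.default_rng(9)
        panel_seq = random_sequence(rng, 30_000, 0.44)
        h0 = max(hits, key=lambda h: h.aligned_length)
        insert = mt.seq.sequence[h0.mt_interval[0] - 1 : h0.mt_interval[1]]
        panel_seq = panel_seq[:4000] + insert + panel_seq[4000 + len(insert):]
        panel = [AnnotatedGenome(CircularSequence("p1", panel_seq))]
        classify_age(hits, mt, panel)
        assert h0.age == "old"
        assert all(h.age == "new" for h in hits if h is not h0)

    def test_empty_panel_leaves_unclassified(self, planted_pair):
        mt, cp, _, _ = planted_pair
        hits = find_cp_derived(mt, cp)
        classify_age(hits, mt, [])
        assert all(h.age == "unclassified" for h in hits)


class TestRegionOfOrigin:
    @pytest.fixture
    def qmap(self):
        return QuadripartiteMap(ira=(8001, 10_000), irb=(11_501, 13_500),
                                lsc=(1, 8000), ssc=(10_001, 11_500), n=13_500)

    def make_hit(self, cp_iv):
        return InsertionHit(mt_interval=(1, 100), cp_interval=cp_iv,
                            strand="+", identity=1.0, aligned_length=100,
                            score=100, e_value=0.0, gc=0.4)

    def test_interval_inside_ssc(self, qmap):
        assert region_of_origin(self.make_hit((10_100, 10_400)), qmap) == "SSC"

    def test_junction_straddler_assigned_by_midpoint(self, qmap):
        # midpoint 7975 lies in LSC even though the hit enters IRa
        assert region_of_origin(self.make_hit((7900, 8050)), qmap) == "LSC"

    def test_counts_match_direct_arithmetic(self, qmap):
        rng = np.random.default_rng(12)
        counts = {"LSC": 0, "SSC": 0, "IR": 0}
        for _ in range(10):
            s = int(rng.integers(1, 13_000))
            e = min(s + int(rng.integers(50, 400)), 13_500)
            region = region_of_origin(self.make_hit((s, e)), qmap)
            counts[region] += 1
            mid = s + (e - s) // 2
            if mid <= 8000:
                assert region == "LSC"
            elif mid <= 10_000:
                assert region == "IR"
            elif mid <= 11_500:
                assert region == "SSC"
            else:
                assert region == "IR"
        assert sum(counts.values()) == 10


class TestSummarize:
    def make_hit(self, length, gc, age):
        return InsertionHit(mt_interval=(1, length), cp_interval=(1, length),
                            strand="+", identity=1.0, aligned_length=length,
                            score=length, e_value=0.0, gc=gc, age=age)

    def test_two_hit_arithmetic(self):
        hits = [self.make_hit(100, 0.40, "old"), self.make_hit(300, 0.30, "new")]
        s = summarize_transfer(hits, 10_000)
        assert (s.gc_old, s.gc_new) == (40.0, 30.0)
        assert s.total_bp == 400 and s.fraction_of_mt == 0.04
        assert (s.n_old, s.n_new, s.n_unclassified) == (1, 1, 0)

    def test_empty_summary(self):
        s = summarize_transfer([], 1000)
        assert s.n_hits == 0 and s.total_bp == 0 and s.gc_old is None

    def test_totals_additive_under_concatenation(self):
        a = [self.make_hit(100, 0.5, "old")]
        b = [self.make_hit(250, 0.3, "new"), self.make_hit(50, 0.2, "old")]
        s_all = summarize_transfer(a + b, 1000)
        s_a = summarize_transfer(a, 1000)
        s_b = summarize_transfer(b, 1000)
        assert s_all.total_bp == s_a.total_bp + s_b.total_bp
        assert s_all.n_old == s_a.n_old + s_b.n_old

    def test_simulator_truth_summary(self, planted_pair):
        mt, cp, qmap, truth = planted_pair
        s = summarize_transfer(truth, mt.seq.length)
        assert s.n_hits == 5
        assert s.total_bp == sum(t[1] for t in FIVE_FRAGMENTS)


class TestStatistics:
    def test_perfect_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_matches_closed_form_on_random_points(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        xm, ym = x.mean(), y.mean()
        r_direct = (((x - xm) * (y - ym)).sum()
                    / math.sqrt(((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()))
        assert pearson_r(list(x), list(y)) == pytest.approx(r_direct, abs=1e-12)

    def test_published_gc_correlations(self):
        """Cp-GC vs New-GC over the 8 species with new insertions ~ 0.69;
        Mt-GC vs Old-GC over the 9 seed plants ~ 0.63-0.64."""
        t = COMPARATIVE_MTPT_GC
        r_new = pearson_r(list(t.cp_gc), list(t.new_gc))
        assert round(r_new, 2) == 0.69
        seed = t[t.seed_plant]
        r_old = pearson_r(list(seed.mt_gc), list(seed.old_gc))
        assert abs(r_old - 0.64) <= 0.01

    def test_constant_vector_undefined(self):
        assert pearson_r([1, 1, 1, 1], [1, 2, 3, 4]) is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])

    def test_welch_identical_samples(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0

    def test_welch_separated_samples_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 1, 10)
        y = rng.normal(50, 1, 10)
        t, p = welch_t(x, y)
        assert p < 0.01

    def test_welch_matches_hand_computation(self):
        x = [19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0]
        y = [28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7,
             23.2, 17.5, 20.6, 18.0, 23.9, 21.6, 24.3, 20.4, 24.0, 13.2]
        mx, my = np.mean(x), np.mean(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        expected_t = (mx - my) / math.sqrt(vx / len(x) + vy / len(y))
        t, p = welch_t(x, y)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert 0 < p < 1

    def test_welch_degenerate_variance(self):
        t, p = welch_t([5.0, 5.0], [7.0, 7.0])
        assert math.isinf(t) and p == 0.0


class TestClassifyTrnas:
    def test_identical_trna_is_cp_derived(self):
        seq = "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCA".replace("U", "T")
        result = classify_trnas([("mt-x", seq)], [("cp-x", seq)])
        assert result["mt-x"]["origin"] == "cp-derived"
        assert result["mt-x"]["identity"] == 1.0

    def test_dissimilar_trna_is_native(self):
        rng = np.random.default_rng(4)
        a = random_sequence(rng, 75, 0.5)
        b = random_sequence(rng, 75, 0.5)
        result = classify_trnas([("mt-y", a)], [("cp-y", b)])
        assert result["mt-y"]["origin"] == "native"

    def test_empty_cp_set_all_native(self, caplog):
        with caplog.at_level("WARNING"):
            result = classify_trnas([("mt-z", "ACGT" * 19)], [])
        assert result["mt-z"]["origin"] == "native"

    def test_simulated_mixture_recovers_truth(self):
        scn = SimScenario(seed=5, n_native_trnas=6, n_cp_trnas=4,
                          trna_mutation_rate=0.03)
        mt_trnas, cp_trnas, truth = simulate_trna_sets(scn)
        result = classify_trnas(mt_trnas, cp_trnas)
        assert {k: v["origin"] for k, v in result.items()} == truth
        n_cp = sum(1 for v in result.values() if v["origin"] == "cp-derived")
        assert n_cp == 4 and len(result) == 10
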