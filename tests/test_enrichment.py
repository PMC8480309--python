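import itertools
from math import comb

import numpy as np
import pytest

import germdelay as gd
from germdelay.data_model import GeneRegions, SequenceSet
from germdelay.enrichment import score_distribution


def seqset(d):
    """d: gene -> utr5 string (cds filled with a stub)."""
    return SequenceSet(regions={g: GeneRegions(utr5=s, cds="ATGTAA")
                                for g, s in d.items()})


# ---------------------------------------------------------------------------
# MEME format
# ---------------------------------------------------------------------------

class TestMemeIo:
    def test_consensus_file_width_eight(self, tmp_path):
        pwm = gd.pwm_from_consensus("TCTTCTTC")
        f = tmp_path / "m.meme"
        gd.write_meme_pwm([pwm], f)
        back = gd.load_meme_pwm(f)
        assert len(back) == 1
        assert back[0].width == 8
        assert back[0].consensus == "TCTTCTTC"

    def test_round_trip_probabilities(self, tmp_path):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = gd.PWM("rnd", probs)
        f = tmp_path / "m.meme"
        gd.write_meme_pwm([pwm], f)
        back = gd.load_meme_pwm(f)[0]
        np.testing.assert_allclose(back.probs, probs, atol=1e-8)

    def test_empty_file_raises(self, tmp_path):
        f = tmp_path / "empty.meme"
        f.write_text("MEME version 4\n")
        with pytest.raises(ValueError):
            gd.load_meme_pwm(f)

    def test_bad_row_sum_raises(self, tmp_path):
        f = tmp_path / "bad.meme"
        f.write_text("MEME version 4\n\nMOTIF bad\n"
                     "letter-probability matrix: alength= 4 w= 2\n"
                     "0.9 0.4 0.0 0.0\n0.25 0.25 0.25 0.25\n")
        with pytest.raises(ValueError, match="sum"):
            gd.load_meme_pwm(f)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def brute_force_tail(pwm, granularity):
    """Enumerate all 4^w windows: exact Pr(integer score >= s)."""
    ints = np.rint(pwm.log_odds() / granularity).astype(np.int64)
    w = pwm.width
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=w):
        scores.append(sum(ints[i, c] for i, c in enumerate(word)))
        probs.append(np.prod([pwm.background[c] for c in word]))
    scores = np.asarray(scores)
    probs = np.asarray(probs)

    def tail(s):
        return probs[scores >= s].sum()

    return scores, probs, tail


class TestPwmScan:
    def test_perfect_match_retained(self):
        pwm = gd.pwm_from_consensus("TCTTCTTC")
        seqs = seqset({"g1": "AAAA" + "TCTTCTTC" + "AAAA"})
        hits = gd.pwm_scan(pwm, seqs, "utr5")
        assert len(hits) == 1
        h = hits[0]
        assert (h.gene, h.start, h.matched) == ("g1", 5, "TCTTCTTC")
        assert h.p_raw == pytest.approx(0.25 ** 8, rel=0.05)

    def test_no_high_scoring_window_no_hits(self):
        pwm = gd.pwm_from_consensus("TCTTCTTC")
        seqs = seqset({"g1": "A" * 40})
        assert gd.pwm_scan(pwm, seqs, "utr5") == []

    def test_all_regions_too_short_raises(self):
        pwm = gd.pwm_from_consensus("TCTTCTTC")
        with pytest.raises(ValueError):
            gd.pwm_scan(pwm, seqset({"g1": "ACGT"}), "utr5")

    @pytest.mark.parametrize("width", [5, 8])
    def test_p_raw_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.full(4, 0.7), size=width)
        bg = rng.dirichlet(np.full(4, 5.0))
        pwm = gd.PWM("rnd", probs, background=bg)
        gran = 1e-3
        _, _, tail = brute_force_tail(pwm, gran)
        ints, offset, dp_tail = score_distribution(pwm, gran)
        # check the DP tail at many integer score levels
        for s in range(offset, offset + dp_tail.size, max(1, dp_tail.size // 200)):
            assert dp_tail[s - offset] == pytest.approx(tail(s), abs=1e-12)

    def test_tail_monotone_and_total_mass_one(self):
        pwm = gd.pwm_from_consensus("TCTTC")
        ints, offset, dp_tail = score_distribution(pwm)
        assert (np.diff(dp_tail) <= 1e-15).all()
        assert dp_tail[0] == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_gate_filters_sparse_hits(self):
        """With BH over a long scan, isolated 8-mer matches cannot clear an
        FDR of 1e-3; disabling the adjusted gate keeps them."""
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        d = {f"g{i}": "".join(rng.choice(bases, 200)) for i in range(50)}
        d["g0"] = d["g0"][:50] + "TCTTCTTC" + d["g0"][58:]
        pwm = gd.pwm_from_consensus("TCTTCTTC")
        strict = gd.pwm_scan(pwm, seqset(d), "utr5")
        loose = gd.pwm_scan(pwm, seqset(d), "utr5", alpha_adj=None)
        assert any(h.gene == "g0" for h in loose)
        assert len(strict) <= len(loose)


class TestMotifGeneSets:
    def test_dedup_within_gene(self):
        hits = [gd.MotifHit("g1", "utr5", s, "TCTT", 1.0, 1e-5, 1e-4)
                for s in (1, 9, 17)]
        assert gd.motif_gene_sets(hits) == {"utr5": ["g1"]}

    def test_disjoint_genes(self):
        hits = [gd.MotifHit(f"g{i}", "cds", 1, "TCTT", 1.0, 1e-5, 1e-4)
                for i in range(5)]
        assert len(gd.motif_gene_sets(hits)["cds"]) == 5


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by direct combinatorial enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(a, min(K, n) + 1)) / total


class TestFisherEnrichment:
    def test_hand_computed_table(self):
        set_g = [f"s{i}" for i in range(4)]
        bg = set_g + [f"b{i}" for i in range(4)]
        ann = set_g[:3] + ["b0"]
        res = gd.fisher_enrichment(set_g, bg, ann)
        assert (res.a, res.b, res.c, res.d) == (3, 1, 1, 3)
        assert res.p == pytest.approx(17 / 70)

    def test_empty_overlap_p_one(self):
        res = gd.fisher_enrichment(["s"], ["s", "b1", "b2"], ["b1"])
        assert res.a == 0
        assert res.p == pytest.approx(1.0)
        assert res.zero_corrected

    def test_annotated_outside_background_raises(self):
        with pytest.raises(ValueError):
            gd.fisher_enrichment(["s"], ["s", "b"], ["elsewhere"])

    def test_matches_enumeration_for_small_margins(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b == 0 or a + b + c + d == 0:
                continue
            set_g = [f"s{i}" for i in range(a + b)]
            rest = [f"r{i}" for i in range(c + d)]
            ann = set_g[:a] + rest[:c]
            res = gd.fisher_enrichment(set_g, set_g + rest, ann)
            assert res.p == pytest.approx(hypergeom_tail_oracle(a, b, c, d),
                                          rel=1e-9)


# ---------------------------------------------------------------------------
# k-mer ranking and GO enrichment
# ---------------------------------------------------------------------------

class TestKmerDiscovery:
    def test_planted_motif_ranked_first(self):
        cfg = gd.SimConfig(seed=4, n_genes=1000,
                           class_props={"null": 0.9, "delayed_up": 0.1,
                                        "concordant": 0, "delayed_down": 0,
                                        "protein_only": 0})
        _, _, _, truth = gd.generate_multiomics(cfg)
        seqs = gd.generate_sequences(truth, cfg)  # 40% vs 5% planting
        du = truth.genes_of_class("delayed_up")
        bg = truth.genes_of_class("null")
        tgt = {g: seqs[g].utr5 for g in du}
        back = {g: seqs[g].utr5 for g in bg}
        df = gd.kmer_discovery(tgt, back)
        top = df.iloc[0]
        assert top["kmer"] in cfg.motif  # the motif or an overlapping shift
        assert top["p_adj"] < 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        tgt = ["".join(rng.choice(bases, 60)) for _ in range(20)]
        bg = ["".join(rng.choice(bases, 60)) for _ in range(30)]
        df1 = gd.kmer_discovery(tgt, bg, k_range=(5,))
        df2 = gd.kmer_discovery(tgt, bg, k_range=(5,))
        assert df1.equals(df2)

    def test_null_calibration(self):
        """Target drawn from the background distribution: no k-mer should be
        significant in most seeds."""
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bases = np.array(list("ACGT"))
            tgt = ["".join(rng.choice(bases, 80)) for _ in range(30)]
            bg = ["".join(rng.choice(bases, 80)) for _ in range(200)]
            df = gd.kmer_discovery(tgt, bg, k_range=(6, 7))
            if df["p_adj"].min() > 0.05:
                clean += 1
        assert clean >= 18

    def test_oversized_k_skipped(self):
        df = gd.kmer_discovery(["ACGTAC"], ["ACGTGT", "ACCTGT"],
                               k_range=(5, 50))
        assert set(df["k"]) == {5}
        with pytest.raises(ValueError):
            gd.kmer_discovery(["ACG"], ["ACG"], k_range=(5,))


class TestGoEnrichment:
    def test_strongly_enriched_term(self):
        bg = [f"g{i}" for i in range(1000)]
        set_g = bg[:20]
        go = {g: frozenset({"GO:X"}) for g in set_g}
        for g in bg[20:120]:
            go[g] = frozenset({"GO:Y"})
        ann = gd.AnnotationTable(go_terms=go)
        df = gd.go_enrichment(set_g, bg, ann).set_index("term")
        assert df.loc["GO:X", "p"] < 1e-10
        assert bool(df.loc["GO:X", "significant"])

    def test_proportional_term_not_significant(self):
        rng = np.random.default_rng(6)
        bg = [f"g{i}" for i in range(500)]
        go = {g: frozenset({"GO:Z"}) for g in bg if rng.random() < 0.2}
        ann = gd.AnnotationTable(go_terms=go)
        df = gd.go_enrichment(bg[:50], bg, ann).set_index("term")
        assert not bool(df.loc["GO:Z", "significant"])

    def test_permutation_calibration(self):
        rng = np.random.default_rng(7)
        bg = [f"g{i}" for i in range(400)]
        terms = [f"GO:{i}" for i in range(15)]
        go = {g: frozenset(t for t in terms if rng.random() < 0.1) for g in bg}
        ann = gd.AnnotationTable(go_terms={g: s for g, s in go.items() if s})
        n_sig = 0
        n_tests = 0
        for _ in range(100):
            sub = list(rng.choice(bg, size=40, replace=False))
            df = gd.go_enrichment(sub, bg, ann)
            n_sig += int(df["significant"].sum())
            n_tests += len(df)
        assert n_sig / max(n_tests, 1) <= 0.05

    def test_empty_annotation_raises(self):
        with pytest.raises(ValueError):
            gd.go_enrichment(["a"], ["a", "b"], gd.AnnotationTable())

    def test_planted_go_term_recovered_from_generator(self):
        cfg = gd.SimConfig(seed=8)
        _, _, _, truth = gd.generate_multiomics(cfg)
        ann = gd.generate_annotations(truth, cfg)
        du = truth.genes_of_class("delayed_up")
        df = gd.go_enrichment(du, truth.table.index.tolist(), ann)
        assert df.iloc[0]["term"] == gd.synthetic_data.GO_PLANTED_TERM
        assert df.iloc[0]["p_adj"] < 1e-6
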