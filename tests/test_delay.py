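import numpy as np
import pandas as pd
import pytest

import germdelay as gd
from conftest import make_expression_set, run_scenario_seed


def call_table(per_gene_calls, layer="polysomal_mRNA"):
    calls = np.array(per_gene_calls, dtype=object)
    n, c = calls.shape
    contrasts = [(0, 6), (6, 26), (26, 48), (48, 72)][:c]
    return gd.CallTable(gene_ids=[f"g{i}" for i in range(n)], layer=layer,
                        contrasts=contrasts, calls=calls,
                        untested=np.zeros_like(calls, dtype=bool))


class TestFirstChange:
    def test_first_significant_contrast(self):
        assert gd.first_change(["notsig", "up", "up", "notsig"]) == (2, "up")

    def test_no_change(self):
        assert gd.first_change(["notsig"] * 4) is None

    def test_first_event_wins_regardless_of_direction(self):
        assert gd.first_change(["down", "up", "notsig", "notsig"]) == (1, "down")


class TestClassifyDelay:
    def test_dug_with_shift_two(self):
        poly = call_table([["up", "notsig", "notsig", "notsig"]])
        prot = call_table([["notsig", "notsig", "up", "notsig"]], "protein")
        rec = gd.classify_delay(poly, prot, ["g0"])
        assert rec.loc[0, "klass"] == "DUG"
        assert rec.loc[0, "shift"] == 2

    def test_opposite_directions_discordant(self):
        poly = call_table([["notsig", "up", "notsig", "notsig"]])
        prot = call_table([["notsig", "notsig", "down", "notsig"]], "protein")
        rec = gd.classify_delay(poly, prot, ["g0"])
        assert rec.loc[0, "klass"] == "discordant"

    def test_same_contrast_is_concordant(self):
        poly = call_table([["notsig", "down", "notsig", "notsig"]])
        prot = call_table([["notsig", "down", "notsig", "notsig"]], "protein")
        rec = gd.classify_delay(poly, prot, ["g0"])
        assert rec.loc[0, "klass"] == "concordant"

    def test_protein_only_and_unchanged(self):
        poly = call_table([["notsig"] * 4, ["notsig"] * 4])
        prot = call_table([["notsig", "up", "notsig", "notsig"],
                           ["notsig"] * 4], "protein")
        rec = gd.classify_delay(poly, prot, ["g0", "g1"])
        assert rec.loc[0, "klass"] == "protein_only"
        assert rec.loc[1, "klass"] == "unchanged"

    def test_any_later_change_flag(self):
        # protein's first change precedes the polysomal change, but a later
        # same-direction change exists
        poly = call_table([["notsig", "up", "notsig", "notsig"]])
        prot = call_table([["up", "notsig", "up", "notsig"]], "protein")
        strict = gd.classify_delay(poly, prot, ["g0"])
        relaxed = gd.classify_delay(poly, prot, ["g0"], any_later_change=True)
        assert strict.loc[0, "klass"] != "DUG"
        assert relaxed.loc[0, "klass"] == "DUG"
        assert relaxed.loc[0, "shift"] == 1

    def test_partition(self, scenario_run):
        """Every detected gene receives exactly one class."""
        rec = scenario_run["records"]
        assert len(rec) == len(scenario_run["detected"])
        assert rec["klass"].isin(gd.delay.DELAY_CLASSES).all()
        assert rec["gene"].is_unique

    def test_empty_detected_raises(self):
        poly = call_table([["notsig"] * 4])
        prot = call_table([["notsig"] * 4], "protein")
        with pytest.raises(ValueError):
            gd.classify_delay(poly, prot, [])


class TestDelayedFraction:
    def test_study_arithmetic(self):
        assert gd.delayed_fraction_from_counts(425, 93, 1469) == \
            pytest.approx(0.3526, abs=5e-4)

    def test_no_delayed_genes(self):
        rec = pd.DataFrame({"klass": ["unchanged", "concordant"],
                            "gene": ["a", "b"]})
        assert gd.delayed_fraction(rec, 10) == 0.0

    def test_all_dug(self):
        rec = pd.DataFrame({"klass": ["DUG"] * 5, "gene": list("abcde")})
        assert gd.delayed_fraction(rec, 5) == 1.0

    def test_zero_proteome_raises(self):
        with pytest.raises(ValueError):
            gd.delayed_fraction_from_counts(1, 1, 0)


class TestShiftedProfiles:
    def test_noise_free_alignment(self):
        # poly steps at contrast 1 (t=6), protein at contrast 3 (t=48): shift 2
        times = [0, 6, 26, 48, 72]
        poly_mean = np.array([[0, 2, 2, 2, 2]], float)
        prot_mean = np.array([[0, 0, 0, 2, 2]], float)
        poly = make_expression_set(np.repeat(poly_mean, 3, axis=1), times, 3,
                                   layer="polysomal_mRNA")
        prot = make_expression_set(np.repeat(prot_mean, 3, axis=1), times, 3,
                                   layer="protein")
        rec = pd.DataFrame({"gene": ["g0"], "klass": ["DUG"], "shift": [2.0]})
        prof = gd.shifted_profiles(rec, poly, prot)
        sub = prof.set_index("time_hai")
        # aligned protein step coincides with the polysomal step at t=6
        assert sub.loc[0, "prot_mean_aligned"] == pytest.approx(0.0)
        assert sub.loc[6, "prot_mean_aligned"] == pytest.approx(2.0)
        assert sub.loc[6, "poly_mean"] == pytest.approx(2.0)

    def test_bucket_counts_partition_delayed_sets(self, scenario_run):
        rec = scenario_run["records"]
        prof = gd.shifted_profiles(rec,
                                   scenario_run["poly"].subset_genes(
                                       scenario_run["detected"]),
                                   scenario_run["prot"].subset_genes(
                                       scenario_run["detected"]))
        bucket = prof.drop_duplicates(["klass", "shift"])
        assert bucket["n_genes"].sum() == \
            rec["klass"].isin(["DUG", "DDG"]).sum()


class TestScenarioRecovery:
    def test_recovery_quality(self, scenario_run):
        sc = scenario_run["scores"]
        assert sc["sensitivity"] >= 0.8
        assert sc["fdp"] <= 0.1

    def test_modal_shift_matches_planted_lag(self, scenario_run):
        assert scenario_run["scores"]["modal_shift_by_lag"] == {1: 1, 2: 2, 3: 3}

    def test_recovery_improves_with_effect_size(self):
        """DUG recovery improves with the planted effect size.  Monotonicity
        is checked on the up-regulated class: larger *down*-steps push
        proteins below the abundance-dependent detection limit, so the
        down-regulated class genuinely loses recoverability at large
        effects — a property of LC-MS-like dropout, not of the classifier."""
        by_effect = {e: [] for e in (1.2, 2.0, 3.0)}
        for seed in (3, 5, 7):
            for effect in by_effect:
                cfg = gd.SimConfig(seed=seed, effect=effect, n_genes=1000)
                _, poly, prot, truth = gd.generate_multiomics(cfg)
                det = gd.protein_detection_filter(prot)
                pc = gd.call_de(gd.ebayes_shrink(gd.fit_contrasts(poly)))
                rc = gd.call_de(gd.ebayes_shrink(gd.fit_contrasts(prot)))
                rec = gd.classify_delay(pc, rc, det).set_index("gene")
                t = truth.table
                pos = t.index[(t["klass"] == "delayed_up") & t["observable"]
                              & t.index.isin(rec.index)]
                tp = sum(1 for g in pos if rec.at[g, "klass"] == "DUG")
                by_effect[effect].append(tp / len(pos))
        med = {e: np.median(v) for e, v in by_effect.items()}
        assert med[2.0] > med[1.2] + 0.1
        assert med[3.0] >= med[2.0] - 0.02

    def test_more_lenient_alpha_never_unchanges_delayed(self, scenario_run):
        """Raising alpha only adds significant calls, so a DUG/DDG gene may
        re-classify but never becomes unchanged."""
        poly_calls = gd.call_de(gd.ebayes_shrink(
            gd.fit_contrasts(scenario_run["poly"])), alpha=0.01)
        prot_calls = gd.call_de(gd.ebayes_shrink(
            gd.fit_contrasts(scenario_run["prot"])), alpha=0.01)
        strict = gd.classify_delay(poly_calls, prot_calls,
                                   scenario_run["detected"]).set_index("gene")
        lenient = scenario_run["records"].set_index("gene")  # alpha = 0.05
        moved = strict.index[strict["klass"].isin(["DUG", "DDG"])
                             & (lenient["klass"] == "unchanged")]
        assert len(moved) == 0


class TestDelayCorrelationEnhancement:
    def test_noise_free_lag1_construction(self):
        rng = np.random.default_rng(20)
        base = rng.normal(8, 1, (40, 5))
        times = [0, 6, 26, 48, 72]
        total = make_expression_set(np.repeat(base, 3, axis=1), times, 3,
                                    layer="total_mRNA")
        poly = make_expression_set(np.repeat(base, 3, axis=1), times, 3,
                                   layer="polysomal_mRNA")
        prot_base = np.column_stack([base[:, 0], base[:, :-1]])
        prot = make_expression_set(np.repeat(prot_base, 3, axis=1), times, 3,
                                   layer="protein")
        res = gd.delay_correlation_enhancement(total, poly, prot, lags=(0, 1))
        t = res["tests"][("polysomal_mRNA", 1)]
        assert t["mean_rho"] == pytest.approx(1.0)
        assert t["enhancement"] > 0.1
        assert t["p"] < 1e-10

    def test_delayed_subset_enhancement_positive(self, scenario_run):
        """In the planted scenario, the delayed genes' polysome->protein
        correlation improves at lag 1."""
        det = scenario_run["detected"]
        poly_d = scenario_run["poly"].subset_genes(det)
        prot_d = scenario_run["prot"].subset_genes(det)
        total_d = scenario_run["total"].subset_genes(det)
        res = gd.delay_correlation_enhancement(total_d, poly_d, prot_d,
                                               lags=(0, 1))
        rec = scenario_run["records"]
        rows = rec.index[rec["klass"].isin(["DUG", "DDG"])].to_numpy()
        r0 = res["summaries"][("polysomal_mRNA", 0)].rho[rows]
        r1 = res["summaries"][("polysomal_mRNA", 1)].rho[rows]
        ok = np.isfinite(r0) & np.isfinite(r1)
        assert np.mean(r1[ok]) - np.mean(r0[ok]) > 0.05

    def test_null_shows_no_enhancement(self):
        cfg = gd.SimConfig(seed=21, n_genes=800,
                           class_props={"null": 1.0, "concordant": 0,
                                        "delayed_up": 0, "delayed_down": 0,
                                        "protein_only": 0})
        total, poly, prot, _ = gd.generate_multiomics(cfg)
        det = gd.protein_detection_filter(prot)
        res = gd.delay_correlation_enhancement(total.subset_genes(det),
                                               poly.subset_genes(det),
                                               prot.subset_genes(det),
                                               lags=(0, 1))
        t = res["tests"][("polysomal_mRNA", 1)]
        assert abs(t["enhancement"]) <= 0.05
        assert t["p"] > 0.01
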