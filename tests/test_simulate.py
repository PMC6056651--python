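"""Synthetic-data generators: determinism, construction rules, moments."""

import numpy as np
import pandas as pd
import pytest

from lysdriver.regions import build_partition
from lysdriver.simulate import (
    GroundTruth,
    SimulationConfig,
    make_ground_truth,
    simulate_annotations,
    simulate_mutations,
    simulate_proteome,
)


class TestProteome:
    def test_sites_are_lysines(self):
        cfg = SimulationConfig(n_proteins=10, seed=1)
        proteins, sites = simulate_proteome(cfg)
        assert len(proteins) == 10
        seqs = dict(zip(proteins["protein_id"], proteins["sequence"]))
        for row in sites.itertuples(index=False):
            assert seqs[row.protein_id][row.position - 1] == "K"

    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(n_proteins=10, seed=1)
        p1, s1 = simulate_proteome(cfg)
        p2, s2 = simulate_proteome(SimulationConfig(n_proteins=10, seed=1))
        assert p1.to_csv() == p2.to_csv()
        assert s1.to_csv() == s2.to_csv()

    def test_zero_density_empty_site_table(self):
        _, sites = simulate_proteome(SimulationConfig(n_proteins=5, site_density=0, seed=2))
        assert sites.empty

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_proteome(SimulationConfig(protein_length_range=(0, 10)))


class TestMutations:
    def _setup(self, lam1, lam2, k_positions=1000, n=2000, seed=3):
        cfg = SimulationConfig(n_proteins=1, protein_length_range=(n, n), seed=seed,
                               site_density=0)
        proteome = pd.DataFrame(
            [dict(protein_id="P0000", length=n, sequence="A" * n)]
        )
        part = build_partition("P0000", n, [(1, 0)])
        part.mod_positions = np.arange(1, k_positions + 1)
        truth = GroundTruth(
            rates=pd.DataFrame(
                [dict(protein_id="P0000", lambda1=lam1, lambda2=lam2,
                      true_r=lam1 / max(lam2, 1e-12), enriched=lam1 > lam2)]
            )
        )
        return proteome, {"P0000": part}, truth, cfg

    def test_zero_rates_empty_table(self):
        proteome, parts, truth, cfg = self._setup(0.0, 0.0)
        muts = simulate_mutations(proteome, parts, truth, cfg)
        assert muts.empty

    def test_poisson_moment_check(self):
        """lambda1=2 over 1000 motif positions: total within 3*sqrt(2000) of 2000."""
        proteome, parts, truth, cfg = self._setup(2.0, 0.0)
        muts = simulate_mutations(proteome, parts, truth, cfg)
        assert abs(len(muts) - 2000) <= 3 * np.sqrt(2000)

    def test_negative_rate_rejected(self):
        proteome, parts, truth, cfg = self._setup(-1.0, 0.0)
        with pytest.raises(ValueError):
            simulate_mutations(proteome, parts, truth, cfg)

    def test_deterministic_given_seed(self):
        proteome, parts, truth, cfg = self._setup(0.5, 0.1)
        a = simulate_mutations(proteome, parts, truth, cfg)
        b = simulate_mutations(proteome, parts, truth, cfg)
        assert a.to_csv() == b.to_csv()

    def test_region_moments_over_replicates(self):
        """Motif/background totals match Poisson moments within 3 sigma across
        replicates (pooled counts are Poisson with known mean)."""
        totals_mod, totals_bg = [], []
        for rep in range(100):
            proteome, parts, truth, cfg = self._setup(0.4, 0.2, k_positions=200,
                                                      n=600, seed=100 + rep)
            muts = simulate_mutations(proteome, parts, truth, cfg)
            in_mod = muts["position"] <= 200
            totals_mod.append(int(in_mod.sum()))
            totals_bg.append(int((~in_mod).sum()))
        mean_mod = np.mean(totals_mod)  # expect 80 per replicate
        mean_bg = np.mean(totals_bg)  # expect 80 per replicate
        assert abs(mean_mod - 80) <= 3 * np.sqrt(80 / 100)
        assert abs(mean_bg - 80) <= 3 * np.sqrt(80 / 100)


class TestGroundTruth:
    def test_enriched_flag_consistent_with_ratio(self):
        cfg = SimulationConfig(n_proteins=50, seed=5)
        truth = make_ground_truth(cfg, [f"P{i:04d}" for i in range(50)])
        assert ((truth.rates["true_r"] > 1) == truth.rates["enriched"]).all()

    def test_null_equal_rates(self):
        cfg = SimulationConfig(n_proteins=20, seed=6, null_equal_rates=True)
        truth = make_ground_truth(cfg, [f"P{i:04d}" for i in range(20)])
        assert truth.rates["lambda1"].equals(truth.rates["lambda2"])


class TestAnnotations:
    def _mutations(self, n_mod, n_other):
        rows = []
        for i in range(n_mod + n_other):
            rows.append(
                dict(
                    mutation_id=f"M{i:06d}",
                    sample_id=f"S{i % 10:04d}",
                    cancer_type="PANCAN",
                    protein_id="P0000",
                    position=i + 1,
                    ref_aa="K",
                    alt_aa="R",
                    variant_class="Missense_Mutation",
                    mutation_class="modification-related" if i < n_mod else "other",
                )
            )
        return pd.DataFrame(rows)

    def _proteome(self):
        return pd.DataFrame([dict(protein_id="P0000", length=300, sequence="A" * 300)])

    def test_certain_predictors_give_score_five(self):
        from lysdriver.sitestats import deleterious_score

        cfg = SimulationConfig(predictor_del_prob=(1.0, 1.0), seed=7)
        _, pred, _, _ = simulate_annotations(self._proteome(), self._mutations(5, 5), cfg)
        assert (deleterious_score(pred) == 5).all()

    def test_network_shape_and_drug_degree(self):
        cfg = SimulationConfig(network_size=(5, 2), seed=8)
        _, _, _, edges = simulate_annotations(self._proteome(), self._mutations(2, 2), cfg)
        nodes = set(edges["source"]) | set(edges["target"])
        assert len(nodes) == 7
        for d in ("D000", "D001"):
            assert ((edges["source"] == d) | (edges["target"] == d)).sum() >= 1

    def test_domains_merge_to_nonoverlap(self):
        from lysdriver.domains import merge_intervals

        cfg = SimulationConfig(seed=9)
        domains, _, _, _ = simulate_annotations(self._proteome(), self._mutations(3, 3), cfg)
        merged = merge_intervals(domains)
        for _, grp in merged.groupby("protein_id"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()

    def test_invalid_hazard_rejected(self):
        cfg = SimulationConfig(hazard_ratio=0.0, seed=10)
        with pytest.raises(ValueError):
            simulate_annotations(self._proteome(), self._mutations(2, 2), cfg)

    def test_null_hazard_logrank_calibrated(self):
        """hazard_ratio=1: log-rank p over replicates is consistent with
        Uniform(0,1) (KS not rejected at the 1% level)."""
        from scipy.stats import kstest

        from lysdriver.survival import logrank_test

        pvals = []
        for rep in range(200):
            cfg = SimulationConfig(hazard_ratio=1.0, n_patients=60, seed=2000 + rep)
            muts = self._mutations(30, 30)
            _, _, surv, _ = simulate_annotations(self._proteome(), muts, cfg)
            a = surv[surv["group"] == "mutated"].rename(columns={"patient_id": "patient_id"})
            b = surv[surv["group"] == "non-mutated"]
            if a.empty or b.empty or a["event"].sum() + b["event"].sum() == 0:
                continue
            pvals.append(logrank_test(a, b).p_value)
        assert len(pvals) >= 150
        assert kstest(pvals, "uniform").pvalue > 0.01
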