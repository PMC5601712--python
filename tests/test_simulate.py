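"""The generators are deterministic, respect their configs, and plant
recoverable signal."""

import numpy as np
import pandas as pd
import pytest

from pseudosponge import cerna, simulate
from pseudosponge.annotation import by_class
from pseudosponge.errors import ConfigError, PlacementError


def small_config(**kw):
    defaults = dict(
        seed=11,
        n_pseudogenes=5,
        n_mrnas=30,
        n_mirnas=20,
        n_lincrnas=4,
        n_tumor=20,
        n_normal=8,
        n_planted_pairs=2,
        n_sharing_only_pairs=3,
        shared_mirna_planted=6,
        n_de_pseudogenes=1,
        genome_length=400_000,
        n_chromosomes=2,
    )
    defaults.update(kw)
    return simulate.SimulationConfig(**defaults)


class TestConfigValidation:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ConfigError):
            simulate.SimulationConfig(n_pseudogenes=0).validate()
        with pytest.raises(ConfigError):
            simulate.SimulationConfig(rho_expression=1.0).validate()
        with pytest.raises(ConfigError):
            simulate.SimulationConfig(censoring_rate=1.0).validate()
        with pytest.raises(ConfigError):
            simulate.SimulationConfig(shared_mirna_planted=10_000).validate()


class TestAnnotations:
    def test_deterministic(self):
        a = simulate.generate_annotations(small_config())
        b = simulate.generate_annotations(small_config())
        assert a == b

    def test_class_counts_match_config(self):
        cfg = small_config()
        genes = simulate.generate_annotations(cfg)
        assert len(by_class(genes, "pseudogene")) == cfg.n_pseudogenes
        assert len(by_class(genes, "mRNA")) == cfg.n_mrnas
        assert len(by_class(genes, "lincRNA")) == cfg.n_lincrnas
        assert len(by_class(genes, "miRNA")) == cfg.n_mirnas

    def test_exons_inside_span_and_disjoint(self, dataset):
        for g in dataset["genes"]:
            prev_end = None
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
                if prev_end is not None:
                    assert s >= prev_end
                prev_end = e
            assert g.exonic_length > 0

    def test_spans_never_overlap_within_chromosome(self, dataset):
        by_chrom = {}
        for g in dataset["genes"]:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_placement_error_when_genome_too_small(self):
        with pytest.raises(PlacementError):
            simulate.generate_annotations(small_config(genome_length=5_000))


class TestInteractions:
    def test_no_duplicate_edges(self, dataset):
        edges = dataset["interactions"]
        assert not edges.duplicated(["mirna_id", "target_id"]).any()

    def test_planted_pairs_outscore_background(self, dataset):
        """Planted sharing beats random background pairs on the
        hypergeometric test."""
        triples = cerna.build_triples(dataset["interactions"], dataset["disease"])
        scored = cerna.score_shared_mirnas(triples)
        keyed = scored.set_index(["pseudogene_id", "mrna_id"])
        planted_p = [
            keyed.loc[pair, "p"] for pair in dataset["truth"].true_pairs if pair in keyed.index
        ]
        assert len(planted_p) == len(dataset["truth"].true_pairs)
        planted_keys = set(dataset["truth"].true_pairs)
        background = scored[
            [
                (p, g) not in planted_keys
                for p, g in zip(scored["pseudogene_id"], scored["mrna_id"])
            ]
        ]
        rng = np.random.default_rng(0)
        sample = background.sample(100, random_state=int(rng.integers(2**31)))
        assert max(planted_p) < sample["p"].mean()

    def test_planted_members_survive_disease_filter(self, dataset):
        triples = cerna.build_triples(dataset["interactions"], dataset["disease"])
        keys = set(zip(triples["pseudogene_id"], triples["mrna_id"]))
        for pair in dataset["truth"].true_pairs:
            assert pair in keys

    def test_config_error_when_planted_sharing_impossible(self):
        cfg = small_config(shared_mirna_planted=25)
        with pytest.raises(ConfigError):
            simulate.generate_interactions(simulate.generate_annotations(small_config()), cfg)


class TestExpression:
    def test_deterministic(self, dataset):
        counts2, _ = simulate.generate_expression(
            dataset["genes"], dataset["truth"], dataset["config"]
        )
        pd.testing.assert_frame_equal(dataset["counts"].counts, counts2.counts)

    def test_planted_pair_correlation_in_band(self):
        """Mean log-scale PCC of planted pairs across replicate cohorts
        lands in the sampling band for the rho=0.6 target."""
        rs = []
        for seed in range(12):
            cfg = small_config(seed=seed, n_tumor=70, n_normal=30)
            genes = simulate.generate_annotations(cfg)
            _, _, truth = simulate.generate_interactions(genes, cfg)
            counts, _ = simulate.generate_expression(genes, truth, cfg)
            logv = np.log2(counts.counts + 1.0)
            for p, g in truth.true_pairs:
                a, b = logv.loc[p], logv.loc[g]
                ok = ~(a.isna() | b.isna())
                rs.append(np.corrcoef(a[ok], b[ok])[0, 1])
        assert 0.40 <= np.mean(rs) <= 0.78

    def test_noise_free_limit_gives_near_perfect_correlation(self):
        cfg = small_config(rho_expression=0.999, nb_dispersion=0.0, nb_mean=50_000.0, missing_rate=0.0)
        genes = simulate.generate_annotations(cfg)
        _, _, truth = simulate.generate_interactions(genes, cfg)
        counts, _ = simulate.generate_expression(genes, truth, cfg)
        logv = np.log2(counts.counts + 1.0)
        # pair 0's pseudogene carries the DE shift, which is signal, not
        # noise — judge the noise-free limit on an undisturbed pair
        p, g = truth.true_pairs[1]
        assert np.corrcoef(logv.loc[p], logv.loc[g])[0, 1] > 0.95

    def test_de_pseudogenes_shifted_in_tumor(self, dataset):
        counts = dataset["counts"].counts
        labels = dataset["labels"]
        t = labels.index[labels == "tumor"]
        n = labels.index[labels == "normal"]
        for gid in dataset["truth"].true_de_pseudogenes:
            assert counts.loc[gid, t].mean() > counts.loc[gid, n].mean()


class TestMethylation:
    def test_beta_in_unit_interval(self, dataset):
        b = dataset["methylation"].beta.to_numpy()
        assert b.min() >= 0 and b.max() <= 1

    def test_probes_inside_gene_bodies(self, dataset):
        spans = {
            (g.chrom, g.gene_id): (g.start, g.end)
            for g in dataset["genes"]
            if g.gene_class != "miRNA"
        }
        pos = dataset["methylation"].probe_positions
        covered = []
        for chrom, p in zip(pos["chrom"], pos["pos"]):
            covered.append(
                any(s <= p < e for (c, _), (s, e) in spans.items() if c == chrom)
            )
        assert all(covered)

    def test_planted_hypomethylation_direction(self, dataset):
        """Tumor methylation of true DE pseudogenes sits below normal —
        normal samples are the more methylated group."""
        meth = dataset["methylation"]
        labels = dataset["labels"]
        pos_by_gene = {}
        for g in dataset["genes"]:
            if g.gene_id in dataset["truth"].true_de_pseudogenes:
                mask = (meth.probe_positions["chrom"] == g.chrom) & (
                    meth.probe_positions["pos"].between(g.start, g.end - 1)
                )
                pos_by_gene[g.gene_id] = meth.beta.loc[mask[mask].index]
        t = labels.index[labels == "tumor"]
        n = labels.index[labels == "normal"]
        for gid, probes in pos_by_gene.items():
            assert probes[t].mean().mean() < probes[n].mean().mean()

    def test_comethylated_pair_correlation_in_band(self):
        rs = []
        for seed in range(12):
            cfg = small_config(seed=seed, n_tumor=70, n_normal=30)
            genes = simulate.generate_annotations(cfg)
            _, _, truth = simulate.generate_interactions(genes, cfg)
            meth = simulate.generate_methylation(genes, truth, cfg)
            gene_of_probe = {}
            for g in genes:
                if g.gene_class == "miRNA":
                    continue
                mask = (meth.probe_positions["chrom"] == g.chrom) & meth.probe_positions[
                    "pos"
                ].between(g.start, g.end - 1)
                for probe in mask[mask].index:
                    gene_of_probe.setdefault(g.gene_id, []).append(probe)
            for p, g in truth.true_comethylated_pairs:
                a = meth.beta.loc[gene_of_probe[p]].mean()
                b = meth.beta.loc[gene_of_probe[g]].mean()
                rs.append(np.corrcoef(a, b)[0, 1])
        assert 0.28 <= np.mean(rs) <= 0.70


class TestSurvival:
    def test_deterministic(self, dataset):
        again = simulate.generate_survival(dataset["counts"], dataset["truth"], dataset["config"])
        pd.testing.assert_frame_equal(dataset["clinical"], again)

    def test_times_positive_events_binary(self, dataset):
        clin = dataset["clinical"]
        assert (clin["time"] > 0).all()
        assert set(clin["event"].unique()) <= {0, 1}

    def test_stronger_hazard_shortens_high_expression_lives(self):
        """Mean event time of the high-expression half decreases as the
        planted log-hazard grows."""
        cfg = small_config()
        genes = simulate.generate_annotations(cfg)
        _, _, truth = simulate.generate_interactions(genes, cfg)
        counts, _ = simulate.generate_expression(genes, truth, cfg)
        node = truth.true_pairs[0][0]
        x = np.log2(counts.counts.loc[node] + 1.0)
        high = x > x.median()
        means = []
        for beta in (0.0, 0.5, 1.0):
            t2 = simulate.PlantedTruth(
                truth.true_pairs, truth.true_de_pseudogenes, truth.true_comethylated_pairs, {node: beta}
            )
            cfg_b = small_config(censoring_rate=0.0)
            surv = simulate.generate_survival(counts, t2, cfg_b).set_index("sample_id")
            means.append(surv.loc[high[high].index, "time"].mean())
        assert means[0] > means[1] > means[2]


class TestDrugTable:
    def test_directions_and_uniqueness(self, dataset, config):
        table = simulate.generate_drug_table(dataset["genes"], config)
        assert set(table["direction"].unique()) <= {"up", "down"}
        assert not table.duplicated(["drug", "mirna_id"]).any()

    def test_deterministic(self, dataset, config):
        a = simulate.generate_drug_table(dataset["genes"], config)
        b = simulate.generate_drug_table(dataset["genes"], config)
        pd.testing.assert_frame_equal(a, b)


class TestConservationTrack:
    def test_scores_in_unit_interval_and_sorted(self, dataset, config):
        track = simulate.generate_conservation_track(dataset["genes"], config)
        assert track["score"].between(0, 1).all()
        for _, sub in track.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
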