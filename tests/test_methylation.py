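"""Probe assignment, detection filtering, gene-level averaging,
co-methylation edges and the differential-expression rule."""

import numpy as np
import pandas as pd
import pytest

from pseudosponge import methylation as mm
from pseudosponge.annotation import GeneRecord
from pseudosponge.errors import DomainError, ScaleError
from pseudosponge.matrices import (
    ExpressionMatrix,
    GeneMethylation,
    MethylationMatrix,
    make_sample_info,
    normal_samples,
    tumor_samples,
)


def gene(gid, chrom, start, end, cls="pseudogene"):
    return GeneRecord(gid, cls, chrom, "+", start, end, ((start, end),))


def meth_matrix(beta_rows, detp_rows, positions, samples=None):
    probes = list(beta_rows)
    samples = samples or [f"s{i}" for i in range(len(next(iter(beta_rows.values()))))]
    beta = pd.DataFrame.from_dict(beta_rows, orient="index", columns=samples).astype(float)
    detp = pd.DataFrame.from_dict(detp_rows, orient="index", columns=samples).astype(float)
    pos = pd.DataFrame(positions, index=probes, columns=["chrom", "pos"])
    return MethylationMatrix(beta, detp, pos)


class TestProbeAssignment:
    def test_inside_and_boundary(self):
        genes = [gene("g1", "chr1", 100, 200)]
        pos = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [150, 200, 99]},
            index=["in", "at_end", "before"],
        )
        out = mm.assign_probes_to_gene_body(pos, genes)
        assert out["probe_id"].tolist() == ["in"]

    def test_probe_in_overlapping_genes_goes_to_both(self):
        genes = [gene("g1", "chr1", 100, 300), gene("g2", "chr1", 200, 400, cls="mRNA")]
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [250]}, index=["cg1"])
        out = mm.assign_probes_to_gene_body(pos, genes)
        assert sorted(out["gene_id"]) == ["g1", "g2"]


class TestGeneMethylationLevel:
    def toy(self):
        """Three probes in one gene; one probe fails detection in sample s1."""
        meth = meth_matrix(
            beta_rows={"cg1": [0.2, 0.2], "cg2": [0.4, 0.6], "cg3": [0.9, 0.4]},
            detp_rows={"cg1": [0.001, 0.001], "cg2": [0.001, 0.001], "cg3": [0.2, 0.001]},
            positions=[("chr1", 110), ("chr1", 120), ("chr1", 130)],
        )
        assignment = pd.DataFrame({"probe_id": ["cg1", "cg2", "cg3"], "gene_id": ["g1"] * 3})
        return meth, assignment

    def test_mean_of_passing_probes_by_hand(self):
        meth, assignment = self.toy()
        out = mm.gene_methylation_level(meth, assignment)
        # s1: cg3 fails detection -> mean(0.2, 0.4); s2: all pass
        assert out.levels.loc["g1", "s0"] == pytest.approx((0.2 + 0.4) / 2)
        assert out.levels.loc["g1", "s1"] == pytest.approx((0.2 + 0.6 + 0.4) / 3)
        assert out.n_probes.loc["g1", "s0"] == 2 and out.n_probes.loc["g1", "s1"] == 3

    def test_all_failing_gives_missing(self):
        meth = meth_matrix(
            beta_rows={"cg1": [0.5]},
            detp_rows={"cg1": [0.9]},
            positions=[("chr1", 110)],
        )
        assignment = pd.DataFrame({"probe_id": ["cg1"], "gene_id": ["g1"]})
        out = mm.gene_methylation_level(meth, assignment)
        assert np.isnan(out.levels.loc["g1"].iloc[0])

    def test_levels_within_unit_interval(self, dataset):
        meth = dataset["methylation"]
        assignment = mm.assign_probes_to_gene_body(meth.probe_positions, dataset["genes"])
        out = mm.gene_methylation_level(meth, assignment)
        vals = out.levels.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_raising_alpha_never_decreases_probe_count(self):
        meth, assignment = self.toy()
        strict = mm.gene_methylation_level(meth, assignment, detection_alpha=0.05)
        lax = mm.gene_methylation_level(meth, assignment, detection_alpha=0.5)
        assert (lax.n_probes.to_numpy() >= strict.n_probes.to_numpy()).all()

    def test_empty_assignment_raises(self):
        meth, _ = self.toy()
        with pytest.raises(DomainError):
            mm.gene_methylation_level(meth, pd.DataFrame(columns=["probe_id", "gene_id"]))


def correlated_levels(rho, n=120, seed=6):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rho * a + np.sqrt(max(1 - rho**2, 0)) * rng.normal(size=n)
    sig = lambda x: 1 / (1 + np.exp(-x))
    frame = pd.DataFrame([sig(a), sig(b)], index=["p1", "g1"], columns=[f"s{i}" for i in range(n)])
    return GeneMethylation(levels=frame, n_probes=frame.notna().astype(int))


class TestComethylationNetwork:
    def pairs(self):
        return pd.DataFrame({"pseudogene_id": ["p1"], "mrna_id": ["g1"]})

    def test_moderate_positive_correlation_is_edge(self):
        out = mm.comethylation_network(self.pairs(), correlated_levels(0.35))
        assert len(out) == 1 and out["p"].iloc[0] < 0.05

    def test_weak_correlation_no_edge(self):
        out = mm.comethylation_network(self.pairs(), correlated_levels(0.05))
        assert out.empty

    def test_identical_vectors_edge_with_r_one(self):
        lv = correlated_levels(1.0)
        out = mm.comethylation_network(self.pairs(), lv)
        assert out["pcc"].iloc[0] == pytest.approx(1.0)

    def test_network_is_subset_of_candidates(self, dataset):
        meth = dataset["methylation"]
        assignment = mm.assign_probes_to_gene_body(meth.probe_positions, dataset["genes"])
        gm = mm.gene_methylation_level(meth, assignment)
        pairs = pd.DataFrame(dataset["truth"].true_pairs, columns=["pseudogene_id", "mrna_id"])
        edges = mm.comethylation_network(pairs, gm)
        candidate_keys = set(dataset["truth"].true_pairs)
        assert set(zip(edges["pseudogene_id"], edges["mrna_id"])) <= candidate_keys

    def test_planted_comethylation_recovered(self, dataset):
        meth = dataset["methylation"]
        assignment = mm.assign_probes_to_gene_body(meth.probe_positions, dataset["genes"])
        gm = mm.gene_methylation_level(meth, assignment)
        pairs = pd.DataFrame(
            dataset["truth"].true_comethylated_pairs, columns=["pseudogene_id", "mrna_id"]
        )
        edges = mm.comethylation_network(pairs, gm)
        assert len(edges) >= 0.7 * len(pairs)


class TestDifferentialExpression:
    def make(self, tumor_mult, n_t=30, n_n=30, seed=7):
        rng = np.random.default_rng(seed)
        samples = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
        labels = make_sample_info(samples, ["tumor"] * n_t + ["normal"] * n_n)
        base = rng.uniform(5, 10, size=n_n)
        vals = np.concatenate([base[:n_t] * tumor_mult, base])  # paired bases: exact group-mean ratio
        expr = ExpressionMatrix(pd.DataFrame([vals], index=["g1"], columns=samples), scale="rpkm")
        return expr, labels

    def test_up_regulated_gene_flagged(self):
        expr, labels = self.make(4.0)
        row = mm.differential_expression(expr, labels).iloc[0]
        assert row["is_de"] and row["direction"] == "up" and row["fold_change"] > 1.5

    def test_fold_change_gate_blocks_small_shifts(self):
        expr, labels = self.make(1.2)
        row = mm.differential_expression(expr, labels).iloc[0]
        assert not row["is_de"]

    def test_down_regulation_symmetric_fold_change(self):
        expr, labels = self.make(0.5)
        row = mm.differential_expression(expr, labels).iloc[0]
        assert row["direction"] == "down"
        assert row["fold_change"] == pytest.approx(2.0, rel=0.01)
        assert row["is_de"]

    def test_requires_rpkm_scale(self):
        expr, labels = self.make(2.0)
        expr.scale = "log2"
        with pytest.raises(ScaleError):
            mm.differential_expression(expr, labels)

    def test_flag_equals_brute_force_on_random_genes(self):
        rng = np.random.default_rng(8)
        n_t, n_n, n_genes = 25, 25, 1000
        samples = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
        labels = make_sample_info(samples, ["tumor"] * n_t + ["normal"] * n_n)
        vals = rng.gamma(2.0, 5.0, size=(n_genes, n_t + n_n))
        shift = rng.choice([0.5, 1.0, 2.0], size=n_genes)
        vals[:, :n_t] *= shift[:, None]
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=samples),
            scale="rpkm",
        )
        out = mm.differential_expression(expr, labels).set_index("gene_id")
        expected = (out["fold_change"] > 1.5) & (out["fdr"] < 0.01)
        assert (out["is_de"] == expected).all()
        assert out["is_de"].any() and not out["is_de"].all()

    def test_planted_de_pseudogenes_all_flagged(self, dataset, processed):
        psg = [
            g.gene_id
            for g in dataset["genes"]
            if g.gene_class == "pseudogene" and g.gene_id in processed["rpkm"].values.index
        ]
        expr = ExpressionMatrix(processed["rpkm"].values.loc[psg], scale="rpkm")
        out = mm.differential_expression(expr, dataset["labels"]).set_index("gene_id")
        for gid in dataset["truth"].true_de_pseudogenes:
            assert bool(out.loc[gid, "is_de"])


class TestGroupContrast:
    def test_tumor_hypomethylation_direction(self, dataset):
        meth = dataset["methylation"]
        assignment = mm.assign_probes_to_gene_body(meth.probe_positions, dataset["genes"])
        gm = mm.gene_methylation_level(meth, assignment)
        de_genes = sorted(dataset["truth"].true_de_pseudogenes)
        sub = GeneMethylation(gm.levels.loc[de_genes], gm.n_probes.loc[de_genes])
        t_ids = tumor_samples(dataset["labels"])
        n_ids = normal_samples(dataset["labels"])
        _, p, (mean_t, mean_n) = mm.methylation_group_contrast(sub, ("samples", t_ids, n_ids))
        assert mean_t < mean_n
        assert p < 0.05

    def test_de_vs_nde_gene_grouping(self, dataset):
        meth = dataset["methylation"]
        assignment = mm.assign_probes_to_gene_body(meth.probe_positions, dataset["genes"])
        gm = mm.gene_methylation_level(meth, assignment)
        de = sorted(dataset["truth"].true_de_pseudogenes)
        nde = [
            g.gene_id
            for g in dataset["genes"]
            if g.gene_class == "pseudogene" and g.gene_id not in dataset["truth"].true_de_pseudogenes
        ]
        _, _, (mean_de, mean_nde) = mm.methylation_group_contrast(gm, ("genes", de, nde))
        assert mean_de < mean_nde

    def test_identical_groups_large_p(self):
        lv = correlated_levels(0.5)
        _, p, _ = mm.methylation_group_contrast(lv, ("genes", ["p1"], ["p1"]))
        assert p >= 0.9

    def test_empty_group_raises(self):
        lv = correlated_levels(0.5)
        with pytest.raises(DomainError):
            mm.methylation_group_contrast(lv, ("genes", [], ["p1"]))
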