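"""Gene-body methylation of the candidate pairs.

Assigns probes to gene bodies, averages detection-passing betas, builds
the co-methylation network over the candidate ceRNA pairs
(PCC >= 0.2, p < 0.05), runs the tumor/normal DE rule on pseudogenes
(fold change > 1.5, FDR < 0.01) and contrasts methylation between
groups — tumor vs normal and DE vs non-DE pseudogenes.
"""

import argparse
from pathlib import Path

from pseudosponge import io, methylation as mm
from pseudosponge.annotation import by_class
from pseudosponge.matrices import ExpressionMatrix, normal_samples, tumor_samples


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    sim = args.outdir / "simdata"
    out = args.outdir / "methylation"
    out.mkdir(parents=True, exist_ok=True)

    meth = io.read_methylation(sim / "beta.tsv", sim / "detection_p.tsv")
    genes = io.read_annotations(sim / "annotations.tsv")
    labels = io.read_labels(sim / "labels.tsv")
    candidates = io.read_table(args.outdir / "discovery" / "candidate_pairs.tsv")
    passing = candidates[candidates["passed"]]

    assignment = mm.assign_probes_to_gene_body(meth.probe_positions, genes)
    gene_meth = mm.gene_methylation_level(meth, assignment)
    io.write_table(gene_meth.levels.rename_axis("gene_id").reset_index(), out / "gene_methylation.tsv")

    edges = mm.comethylation_network(passing, gene_meth)
    io.write_table(edges, out / "comethylation_edges.tsv")
    print(f"co-methylated candidate pairs (PCC >= 0.2, p < 0.05): {len(edges)} of {len(passing)}")

    rpkm = io.read_expression(args.outdir / "preprocessed" / "rpkm.tsv", scale="rpkm")
    psg_ids = [g.gene_id for g in by_class(genes, "pseudogene") if g.gene_id in rpkm.values.index]
    de = mm.differential_expression(ExpressionMatrix(rpkm.values.loc[psg_ids], scale="rpkm"), labels)
    io.write_table(de, out / "de_pseudogenes.tsv")
    de_ids = sorted(de.loc[de["is_de"], "gene_id"])
    print(f"DE pseudogenes (FC > 1.5, FDR < 0.01): {len(de_ids)}: {', '.join(de_ids)}")

    nde_ids = [g for g in psg_ids if g not in set(de_ids) and g in gene_meth.levels.index]
    de_in_meth = [g for g in de_ids if g in gene_meth.levels.index]
    if de_in_meth and nde_ids:
        _, p, (m_de, m_nde) = mm.methylation_group_contrast(gene_meth, ("genes", de_in_meth, nde_ids))
        print(f"methylation DE vs NDE pseudogenes: {m_de:.3f} vs {m_nde:.3f} (p = {p:.2e})")
    sub = mm.GeneMethylation(gene_meth.levels.loc[de_in_meth], gene_meth.n_probes.loc[de_in_meth])
    _, p, (m_t, m_n) = mm.methylation_group_contrast(
        sub, ("samples", tumor_samples(labels), normal_samples(labels))
    )
    print(f"DE-pseudogene methylation tumor vs normal: {m_t:.3f} vs {m_n:.3f} (p = {p:.2e})")


if __name__ == "__main__":
    main()
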