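"""Generate the synthetic study cohort.

Writes a full planted-signal dataset — annotations, miRNA-target edges,
disease lists, tumor/normal counts, 450k-style methylation, clinical
follow-up, a drug->miRNA table and a conservation track — under
results/simdata/, together with the ground truth used by later stages
to report recovery.
"""

import argparse
from pathlib import Path

from pseudosponge import io, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=None, help="override the default config seed")
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    config = simulate.SimulationConfig()
    if args.seed is not None:
        config.seed = args.seed
    out = args.outdir / "simdata"
    out.mkdir(parents=True, exist_ok=True)

    genes = simulate.generate_annotations(config)
    interactions, disease, truth = simulate.generate_interactions(genes, config)
    counts, labels = simulate.generate_expression(genes, truth, config)
    meth = simulate.generate_methylation(genes, truth, config)
    clinical = simulate.generate_survival(counts, truth, config)
    drug_table = simulate.generate_drug_table(genes, config)
    track = simulate.generate_conservation_track(genes, config)

    io.write_annotations(genes, out / "annotations.tsv")
    io.write_edges(interactions, out / "edges.tsv")
    io.write_id_list(disease["disease_mrnas"], out / "disease_mrnas.txt")
    io.write_id_list(disease["disease_mirnas"], out / "disease_mirnas.txt")
    io.write_counts(counts, out / "counts.tsv", out / "library_sizes.tsv")
    io.write_labels(labels, out / "labels.tsv")
    io.write_methylation(meth, out / "beta.tsv", out / "detection_p.tsv")
    io.write_clinical(clinical, out / "clinical.tsv")
    io.write_table(drug_table, out / "drug_table.tsv")
    io.write_bedgraph(track, out / "conservation.bedgraph")
    io.write_truth(truth, out / "truth.tsv")
    io.write_config(config, out / "config.txt")

    print(f"cohort: {len(genes)} genes, {len(interactions)} miRNA-target edges")
    print(f"samples: {config.n_tumor} tumor + {config.n_normal} normal")
    print(
        f"planted: {len(truth.true_pairs)} ceRNA pairs, "
        f"{len(truth.true_de_pseudogenes)} DE pseudogenes, "
        f"{len(truth.true_risk_nodes)} risk nodes"
    )
    print(f"written to {out}")


if __name__ == "__main__":
    main()
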