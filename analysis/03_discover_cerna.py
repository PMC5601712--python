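"""Identify candidate pseudogene-mRNA ceRNA pairs.

Builds disease-filtered pseudogene-miRNA-mRNA triples, tests shared-miRNA
counts with the upper-tail hypergeometric test (BH FDR < 0.05), then
keeps the top decile of the significant pairs by tumor co-expression.
Reports recovery of the planted pairs.
"""

import argparse
from pathlib import Path

from pseudosponge import cerna, io
from pseudosponge.matrices import tumor_samples


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--fdr", type=float, default=0.05)
    parser.add_argument("--top", type=float, default=0.10)
    args = parser.parse_args()
    sim = args.outdir / "simdata"
    out = args.outdir / "discovery"
    out.mkdir(parents=True, exist_ok=True)

    interactions = io.read_edges(sim / "edges.tsv")
    disease = {
        "disease_mrnas": io.read_id_list(sim / "disease_mrnas.txt"),
        "disease_mirnas": io.read_id_list(sim / "disease_mirnas.txt"),
    }
    expr = io.read_expression(args.outdir / "preprocessed" / "log_expr.tsv", scale="log2")
    labels = io.read_labels(sim / "labels.tsv")
    samples = [s for s in tumor_samples(labels) if s in expr.values.columns]

    candidates, passing_triples = cerna.identify_candidates(
        interactions, disease, expr, fdr_threshold=args.fdr, top_fraction=args.top, samples=samples
    )
    io.write_table(candidates, out / "candidate_pairs.tsv")
    io.write_table(passing_triples, out / "passing_triples.tsv")

    passing = candidates[candidates["passed"]]
    truth = io.read_truth(sim / "truth.tsv")
    planted = set(truth.true_pairs)
    reported = set(zip(passing["pseudogene_id"], passing["mrna_id"]))
    print(f"pairs tested (>= 1 shared disease miRNA): {len(candidates)}")
    print(f"FDR < {args.fdr}: {(candidates['fdr'] < args.fdr).sum()}")
    print(f"passed top-decile correlation filter: {len(passing)}")
    print(f"planted-pair recall: {len(planted & reported) / len(planted):.2f}")
    print(f"false pairs among reported: {len(reported - planted)}")
    print(f"triples induced by passing pairs: {len(passing_triples)}")


if __name__ == "__main__":
    main()
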