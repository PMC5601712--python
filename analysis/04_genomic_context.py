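"""Characterize the candidate pseudogenes genomically.

Transcript length and exon counts per class, exon-averaged conservation
scores with class contrasts and ECDFs, flanking protein-coding genes
within 500 kb, and the cis-acting co-expression network (PCC >= 0.6).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pseudosponge import genomic_context as gc, io
from pseudosponge.annotation import by_class


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--window", type=int, default=500_000)
    parser.add_argument("--pcc", type=float, default=0.6)
    args = parser.parse_args()
    sim = args.outdir / "simdata"
    out = args.outdir / "context"
    out.mkdir(parents=True, exist_ok=True)

    genes = io.read_annotations(sim / "annotations.tsv")
    expr = io.read_expression(args.outdir / "preprocessed" / "log_expr.tsv", scale="log2")
    track = gc.ConservationTrack(io.read_bedgraph(sim / "conservation.bedgraph"))
    candidates = io.read_table(args.outdir / "discovery" / "candidate_pairs.tsv")
    candidate_psg = set(candidates.loc[candidates["passed"], "pseudogene_id"])

    table, comparisons = gc.feature_summary(genes)
    io.write_table(table, out / "features.tsv")
    io.write_table(comparisons, out / "class_comparisons.tsv")

    scores = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_class": [g.gene_class for g in genes],
            "conservation": [gc.exon_conservation_score(g, track) for g in genes],
        }
    )
    scores.loc[scores["gene_id"].isin(candidate_psg), "gene_class"] = "candidate_pseudogene"
    io.write_table(scores, out / "conservation_scores.tsv")
    for cls, sub in scores.groupby("gene_class"):
        io.write_table(gc.conservation_ecdf(sub["conservation"]), out / f"ecdf_{cls}.tsv")
        print(f"mean conservation {cls}: {np.nanmean(sub['conservation']):.3f}")

    pseudos = [g for g in by_class(genes, "pseudogene") if g.gene_id in candidate_psg]
    neighbors = gc.neighboring_pcgs(pseudos, by_class(genes, "mRNA"), window=args.window)
    io.write_table(neighbors, out / "neighbors.tsv")
    edges = gc.cis_network(neighbors, expr, pcc_threshold=args.pcc)
    io.write_table(edges, out / "cis_edges.tsv")
    print(f"candidate pseudogenes: {len(pseudos)}")
    print(f"neighboring PCGs within {args.window/1000:.0f} kb: {len(neighbors)} pairs")
    print(f"cis-acting edges (PCC >= {args.pcc}): {len(edges)}")


if __name__ == "__main__":
    main()
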