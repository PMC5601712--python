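"""Preprocess raw counts into filtered log2 RPKM expression.

Applies the fixed stage order — cross-class overlap exclusion, RPKM,
missing-value filter (> 50% missing removed), log2(x + 1e-5) — and
reports how many genes each stage retained.
"""

import argparse
from pathlib import Path

from pseudosponge import io, preprocessing


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    sim = args.outdir / "simdata"
    out = args.outdir / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(sim / "counts.tsv", sim / "library_sizes.tsv")
    genes = io.read_annotations(sim / "annotations.tsv")
    kept, rpkm, logged = preprocessing.preprocess(counts, genes)

    io.write_annotations(kept, out / "annotations_filtered.tsv")
    io.write_expression(rpkm, out / "rpkm.tsv")
    io.write_expression(logged, out / "log_expr.tsv")

    print(f"input genes: {len(counts.counts)}")
    print(f"after overlap exclusion: {len(kept)}")
    print(f"after missing filter: {len(rpkm.values)} (log2 matrix has the same genes)")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
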