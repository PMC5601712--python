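"""Small-molecule candidates for the prognostic triples.

A triple's miRNA with a positive risk coefficient should be
down-regulated, a negative one up-regulated; the drug table rows whose
recorded direction matches are emitted as candidates.
"""

import argparse
from pathlib import Path

from pseudosponge import drugs, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    out = args.outdir / "drugs"
    out.mkdir(parents=True, exist_ok=True)

    risk = io.read_table(args.outdir / "survival" / "triple_risk.tsv")
    significant = risk[risk["significant"]]
    betas = dict(zip(significant["mirna_id"], significant["beta_mirna"]))
    drug_table = io.read_table(args.outdir / "simdata" / "drug_table.tsv")

    candidates = drugs.infer_candidate_drugs(significant, betas, drug_table)
    io.write_table(candidates, out / "drug_candidates.tsv")

    print(f"prognostic triples: {len(significant)}")
    for mirna, beta in sorted(betas.items()):
        req = drugs.required_mirna_regulation(beta)
        print(f"  {mirna}: risk coefficient {beta:+.3f} -> {req}-regulate")
    print(f"matched drug rows: {len(candidates)}")


if __name__ == "__main__":
    main()
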