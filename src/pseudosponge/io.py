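"""Plain-text I/O for every table the pipeline reads or writes.

All tabular formats are TSV with a header row; missing values are "NA".
Annotations use a BED-like TSV (one row per gene, exon starts/ends as
comma lists); conservation tracks use 4-column headerless bedGraph.
"""

from __future__ import annotations

import ast
from pathlib import Path

import pandas as pd

from .annotation import GeneRecord, annotations_to_frame, frame_to_annotations
from .matrices import CountMatrix, ExpressionMatrix, MethylationMatrix, make_sample_info
from .simulate import SimulationConfig, PlantedTruth

NA = "NA"


def write_annotations(genes: list[GeneRecord], path) -> None:
    annotations_to_frame(genes).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[GeneRecord]:
    return frame_to_annotations(pd.read_csv(path, sep="\t"))


def _write_matrix(frame: pd.DataFrame, path, index_name: str) -> None:
    frame.rename_axis(index_name).to_csv(path, sep="\t", na_rep=NA)


def _read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def write_counts(counts: CountMatrix, counts_path, totals_path=None) -> None:
    _write_matrix(counts.counts, counts_path, "gene_id")
    if totals_path is not None:
        counts.per_sample_total.rename_axis("sample_id").rename("total_reads").to_csv(
            totals_path, sep="\t"
        )


def read_counts(counts_path, totals_path=None) -> CountMatrix:
    frame = _read_matrix(counts_path)
    totals = None
    if totals_path is not None and Path(totals_path).exists():
        totals = pd.read_csv(totals_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(frame, totals)


def write_expression(expr: ExpressionMatrix, path) -> None:
    # scale travels in the filename-independent header comment-free way:
    # a sibling ".scale" file keeps the TSV plain
    _write_matrix(expr.values, path, "gene_id")
    Path(str(path) + ".scale").write_text(expr.scale + "\n")


def read_expression(path, scale: str | None = None) -> ExpressionMatrix:
    if scale is None:
        marker = Path(str(path) + ".scale")
        scale = marker.read_text().strip() if marker.exists() else "rpkm"
    return ExpressionMatrix(_read_matrix(path), scale=scale)


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("sample_id").rename("condition").to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return make_sample_info(frame.index, frame.iloc[:, 0])


def write_edges(interactions: pd.DataFrame, path) -> None:
    interactions.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_id_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_methylation(meth: MethylationMatrix, beta_path, detp_path) -> None:
    beta = pd.concat([meth.probe_positions, meth.beta], axis=1)
    beta.rename_axis("probe_id").to_csv(beta_path, sep="\t", na_rep=NA)
    _write_matrix(meth.detection_p, detp_path, "probe_id")


def read_methylation(beta_path, detp_path) -> MethylationMatrix:
    frame = _read_matrix(beta_path)
    positions = frame[["chrom", "pos"]]
    beta = frame.drop(columns=["chrom", "pos"]).astype(float)
    detp = _read_matrix(detp_path).astype(float)
    return MethylationMatrix(beta, detp, positions)


def write_clinical(survival: pd.DataFrame, path) -> None:
    survival.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])


# --- config and planted truth ------------------------------------------------


def write_config(config: SimulationConfig, path) -> None:
    lines = [f"{k} = {v!r}\n" for k, v in config.to_dict().items()]
    Path(path).write_text("".join(lines))


def read_config(path) -> SimulationConfig:
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = ast.literal_eval(raw.strip())
    return SimulationConfig(**values)


def write_truth(truth: PlantedTruth, path) -> None:
    rows = []
    for p, g in truth.true_pairs:
        rows.append(("pair", p, g, ""))
    for p in sorted(truth.true_de_pseudogenes):
        rows.append(("de", p, "", ""))
    for p, g in truth.true_comethylated_pairs:
        rows.append(("cometh", p, g, ""))
    for node, beta in sorted(truth.true_risk_nodes.items()):
        rows.append(("risk", node, "", beta))
    pd.DataFrame(rows, columns=["record", "id1", "id2", "value"]).to_csv(path, sep="\t", index=False)


def read_truth(path) -> PlantedTruth:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    pairs = [(r.id1, r.id2) for r in frame[frame["record"] == "pair"].itertuples()]
    de = {r.id1 for r in frame[frame["record"] == "de"].itertuples()}
    cometh = [(r.id1, r.id2) for r in frame[frame["record"] == "cometh"].itertuples()]
    risk = {r.id1: float(r.value) for r in frame[frame["record"] == "risk"].itertuples()}
    return PlantedTruth(pairs, de, cometh, risk)
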