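"""Small-molecule direction inference.

A triple's miRNA with a positive Cox coefficient is a hazard — it should
be down-regulated; a negative coefficient calls for up-regulation.
Candidate drugs are the table rows whose recorded regulation direction
matches the required one for the triple's miRNA.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import DomainError


def required_mirna_regulation(mirna_beta: float) -> str | None:
    """Map a miRNA's Cox risk coefficient to the desired drug action.

    beta > 0 -> 'down', beta < 0 -> 'up', beta == 0 -> no recommendation.
    """
    if not math.isfinite(mirna_beta):
        raise DomainError("miRNA Cox coefficient must be finite")
    if mirna_beta > 0:
        return "down"
    if mirna_beta < 0:
        return "up"
    return None


def infer_candidate_drugs(
    significant_triples: pd.DataFrame,
    mirna_betas: dict[str, float],
    drug_table: pd.DataFrame,
) -> pd.DataFrame:
    """Drugs whose recorded direction matches each triple's requirement.

    ``significant_triples`` needs columns pseudogene_id, mirna_id,
    mrna_id; ``drug_table`` columns drug, mirna_id, direction.  Triples
    whose miRNA is absent from the table (or has beta 0) contribute no
    rows.
    """
    cols = [
        "pseudogene_id",
        "mirna_id",
        "mrna_id",
        "required_direction",
        "drug",
        "drug_direction",
        "matched",
    ]
    rows = []
    by_mirna = dict(tuple(drug_table.groupby("mirna_id"))) if len(drug_table) else {}
    for t in significant_triples.itertuples(index=False):
        beta = mirna_betas.get(t.mirna_id)
        if beta is None:
            raise DomainError(f"no Cox fit for miRNA {t.mirna_id}")
        required = required_mirna_regulation(beta)
        if required is None:
            continue
        for d in by_mirna.get(t.mirna_id, pd.DataFrame(columns=["drug", "direction"])).itertuples(
            index=False
        ):
            if d.direction == required:
                rows.append(
                    (t.pseudogene_id, t.mirna_id, t.mrna_id, required, d.drug, d.direction, True)
                )
    return pd.DataFrame(rows, columns=cols)
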