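"""In-memory containers for expression and methylation data.

All matrices are pandas DataFrames with genes/probes as rows and samples
as columns.  Missing measurements are NaN — distinct from zero, because
the missing-fraction filter must tell "unmeasured" apart from "not
expressed".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class CountMatrix:
    """Raw read counts per gene and sample plus per-sample library sizes.

    ``per_sample_total`` is the ``N`` of the RPKM formula (total mapped
    reads); it must dominate the column sums of the non-missing counts.
    """

    counts: pd.DataFrame
    per_sample_total: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.per_sample_total is None:
            self.per_sample_total = self.counts.sum(axis=0, skipna=True)
        self.per_sample_total = self.per_sample_total.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0, skipna=True)
        if (self.per_sample_total + 1e-9 < colsum).any():
            raise ValueError("per_sample_total below column sum of counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpressionMatrix:
    """Normalized expression, either RPKM or log2(RPKM + pseudocount)."""

    values: pd.DataFrame
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MethylationMatrix:
    """Probe-level beta values, detection p-values and probe positions.

    ``probe_positions`` is indexed by probe id with columns chrom, pos.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    probe_positions: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(dtype=float)
        if np.nanmin(b) < 0 or np.nanmax(b) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if not self.beta.index.equals(self.detection_p.index):
            raise ValueError("beta and detection_p probe ids differ")
        if not self.beta.columns.equals(self.detection_p.columns):
            raise ValueError("beta and detection_p sample ids differ")


@dataclass
class GeneMethylation:
    """Gene-level methylation: mean beta of detection-passing probes.

    ``levels`` is genes x samples (NaN where no probe passed);
    ``n_probes`` counts the probes actually averaged per cell.
    """

    levels: pd.DataFrame
    n_probes: pd.DataFrame


def make_sample_info(sample_ids, conditions) -> pd.Series:
    """Build the sample->condition map ('tumor'/'normal')."""
    info = pd.Series(list(conditions), index=list(sample_ids), name="condition")
    if info.index.has_duplicates:
        raise ValueError("duplicate sample ids")
    bad = set(info.unique()) - {TUMOR, NORMAL}
    if bad:
        raise ValueError(f"unknown conditions: {bad}")
    return info


def tumor_samples(info: pd.Series) -> list[str]:
    return list(info.index[info == TUMOR])


def normal_samples(info: pd.Series) -> list[str]:
    return list(info.index[info == NORMAL])
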