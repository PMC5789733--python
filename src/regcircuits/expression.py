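"""Tissue-expressed gene calls and the tissue-specificity z-score.

A gene is called expressed in a tissue when its level reaches RPKM >= 1 in
strictly more than 80% of the tissue's samples.  The specificity of gene i
in tissue t is

    z_E(i, t) = (E(i, t) - <E(i)>) / delta_E(i)

where E(i, t) is the gene's mean expression over tissue t's samples and
<E(i)>, delta_E(i) are the mean and sample (n-1) standard deviation of
those per-tissue means across the considered tissues.  A larger z means
higher expression in that tissue relative to the others; when delta_E is 0
(identical means) z is defined as 0 everywhere.

Statistics run on per-tissue means, not pooled samples, so tissues with
different sample counts weigh equally.  No log transform is applied by
default; ``log_transform=True`` applies log1p before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

RPKM_MIN_DEFAULT = 1.0
SAMPLE_FRAC_DEFAULT = 0.8


@dataclass
class TissueExpressedSet:
    tissue: str
    genes: set[str]


@dataclass
class ExpressionSummary:
    """Per-tissue means, grand mean/SD across tissues and z per tissue."""

    gene_id: str
    tissue_means: dict[str, float]
    grand_mean: float
    sd: float
    z: dict[str, float]

    @property
    def max_z_tissue(self) -> str:
        return max(self.z, key=lambda t: (self.z[t], t))


def _samples_by_tissue(
    matrix: pd.DataFrame, sample_map: Mapping[str, str]
) -> dict[str, list[str]]:
    by_tissue: dict[str, list[str]] = {}
    for sample in matrix.columns:
        tissue = sample_map.get(sample)
        if tissue is None:
            raise ValueError(f"sample {sample!r} missing from tissue map")
        by_tissue.setdefault(tissue, []).append(sample)
    return by_tissue


def tissue_expressed_genes(
    matrix: pd.DataFrame,
    sample_map: Mapping[str, str],
    tissue: str,
    rpkm_min: float = RPKM_MIN_DEFAULT,
    sample_frac: float = SAMPLE_FRAC_DEFAULT,
) -> TissueExpressedSet:
    """Genes with expression >= ``rpkm_min`` in strictly more than
    ``sample_frac`` of the tissue's samples."""
    samples = _samples_by_tissue(matrix, sample_map).get(tissue)
    if not samples:
        raise ValueError(f"tissue {tissue!r} has no samples in the map")
    frac = (matrix[samples] >= rpkm_min).mean(axis=1)
    return TissueExpressedSet(tissue=tissue, genes=set(matrix.index[frac > sample_frac]))


def tissue_specificity_z(tissue_means: Mapping[str, float]) -> dict[str, float]:
    """z per tissue from per-tissue mean expressions (sample SD, n-1).

    Identical means across tissues (SD 0) yield z = 0 everywhere; fewer
    than two tissues is an error.
    """
    tissues = sorted(tissue_means)
    if len(tissues) < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    vals = np.array([tissue_means[t] for t in tissues], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        return {t: 0.0 for t in tissues}
    return {t: float((v - mean) / sd) for t, v in zip(tissues, vals)}


def expression_summaries(
    matrix: pd.DataFrame,
    sample_map: Mapping[str, str],
    tissues: Optional[Sequence[str]] = None,
    log_transform: bool = False,
) -> dict[str, ExpressionSummary]:
    """Per-gene tissue means and specificity z over the considered tissues."""
    by_tissue = _samples_by_tissue(matrix, sample_map)
    considered = sorted(by_tissue) if tissues is None else list(tissues)
    if len(considered) < 2:
        raise ValueError("tissue specificity needs at least 2 tissues")
    missing = [t for t in considered if t not in by_tissue]
    if missing:
        raise ValueError(f"tissue(s) {missing} have no samples")
    data = np.log1p(matrix) if log_transform else matrix
    means = pd.DataFrame(
        {t: data[by_tissue[t]].mean(axis=1) for t in considered}
    )
    grand = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    out: dict[str, ExpressionSummary] = {}
    for gene in matrix.index:
        tm = {t: float(means.at[gene, t]) for t in considered}
        s = float(sd.at[gene])
        if s == 0.0:
            z = {t: 0.0 for t in considered}
        else:
            g = float(grand.at[gene])
            z = {t: (tm[t] - g) / s for t in considered}
        out[gene] = ExpressionSummary(
            gene_id=str(gene), tissue_means=tm, grand_mean=float(grand.at[gene]), sd=s, z=z
        )
    return out


def summary_rows(summaries: Mapping[str, ExpressionSummary], tissues: Sequence[str]) -> list[list]:
    rows = []
    for gene in sorted(summaries):
        s = summaries[gene]
        row: list = [gene, s.grand_mean, s.sd]
        for t in tissues:
            row.append(s.tissue_means[t])
        for t in tissues:
            row.append(s.z[t])
        rows.append(row)
    return rows


def summary_header(tissues: Sequence[str]) -> list[str]:
    return (
        ["gene_id", "grand_mean", "sd"]
        + [f"mean_{t}" for t in tissues]
        + [f"z_{t}" for t in tissues]
    )
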