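"""Pathway-level expression characterization and cross-dataset consistency.

A pathway's expression state in one dataset is summarized by three numbers
computed from its member DEGs (p < 0.05):

* ``rateFC`` — the fraction of the pathway's measured genes that are
  over-expressed DEGs (count of members with log2FC > 0 over the pathway's
  total measured gene count); in [0, 1].
* ``normMeanFC`` — the weighted mean of the normalized histogram of member
  log2FC values: values are clipped to ``[-range_limit, +range_limit]``,
  binned into ``n_bins`` equal-width bins, frequencies normalized to sum 1,
  and the bin centers averaged under those weights. As ``n_bins`` grows this
  converges to the plain mean of the clipped log2FC.
* ``combinedFC = rateFC + clip((normMeanFC + L) / 2L, 0, 1)`` with
  ``L = range_limit`` — a score in [0, 2] where values in (1, 2] indicate
  that the majority of participating genes are over-expressed and [0, 1)
  an overall under-expression. The additive combination is the simplest
  form satisfying that range and interpretation; the exact combining
  function is a design choice of this package (see docs/methods.md).

Cross-dataset consistency asks, per gene, in how many datasets it is a DEG
with its majority sign; a gene is *consistent* when that count reaches
``max(2, ceil(min_fraction * n_datasets))`` — at least one-third of the
datasets, and never fewer than two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cohortpath.errors import ConfigurationError, LookupError_
from cohortpath.enrichment import GeneSetCollection

#: Histogram defaults for normMeanFC: 20 bins over +/- 4 log2 units.
DEFAULT_N_BINS = 20
DEFAULT_RANGE_LIMIT = 4.0


def pathway_degs(
    deg_table: pd.DataFrame,
    collection: GeneSetCollection,
    pathway_id: str,
) -> pd.DataFrame:
    """Rows of ``deg_table`` (already p-filtered) restricted to one pathway."""
    members = set(collection.members(pathway_id))  # raises on unknown id
    return deg_table[deg_table["gene"].isin(members)].reset_index(drop=True)


def rate_fc(member_degs: pd.DataFrame, n_total: int) -> float:
    """Fraction of the pathway's measured genes that are up-regulated DEGs."""
    if n_total <= 0:
        raise ConfigurationError("rate_fc: pathway has no measured genes (n_total=0)")
    n_up = int((member_degs["log2FC"] > 0).sum()) if len(member_degs) else 0
    return n_up / n_total


def norm_mean_fc(
    member_degs: pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> float:
    """Weighted mean of the normalized log2FC histogram of member DEGs.

    Raises
    ------
    ConfigurationError
        If there are no member DEGs (the pathway is unscored).
    """
    if member_degs.empty:
        raise ConfigurationError("norm_mean_fc: no member DEGs; pathway unscored")
    vals = np.clip(member_degs["log2FC"].to_numpy(dtype=float),
                   -range_limit, range_limit)
    edges = np.linspace(-range_limit, range_limit, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    # values exactly at +range_limit fall into the last bin via np.histogram
    freq = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(np.dot(centers, freq))


def combined_fc(
    rate: float,
    norm_mean: float,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> float:
    """Combine rateFC and normMeanFC into the [0, 2] pathway score."""
    m = (norm_mean + range_limit) / (2.0 * range_limit)
    m = min(max(m, 0.0), 1.0)
    return rate + m


@dataclass
class PathwayScore:
    """One pathway's expression summary in one dataset."""

    pathway_id: str
    n_deg: int
    n_total: int
    rate_fc: float
    norm_mean_fc: float | None
    combined_fc: float | None


def score_pathway(
    deg_table: pd.DataFrame,
    collection: GeneSetCollection,
    pathway_id: str,
    measured_genes: list[str],
    n_bins: int = DEFAULT_N_BINS,
    range_limit: float = DEFAULT_RANGE_LIMIT,
) -> PathwayScore:
    """Compute rateFC / normMeanFC / combinedFC for one pathway and dataset.

    ``n_total`` is the number of pathway members present in
    ``measured_genes`` (the platform universe), so scores are comparable
    across platforms with different coverage. A pathway with no member DEGs
    gets ``rateFC=0`` and undefined (None) normMeanFC/combinedFC.
    """
    members = set(collection.members(pathway_id))
    measured = members & set(measured_genes)
    if not measured:
        raise LookupError_(
            f"pathway {pathway_id!r} has no genes in the measured universe"
        )
    degs = deg_table[deg_table["gene"].isin(measured)]
    rate = rate_fc(degs, len(measured))
    if degs.empty:
        return PathwayScore(pathway_id, 0, len(measured), rate, None, None)
    nmf = norm_mean_fc(degs, n_bins=n_bins, range_limit=range_limit)
    return PathwayScore(
        pathway_id, len(degs), len(measured), rate, nmf,
        combined_fc(rate, nmf, range_limit=range_limit),
    )


def consistency_scores(
    per_dataset_degs: dict[str, pd.DataFrame],
    min_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Per-gene cross-dataset direction consistency.

    Parameters
    ----------
    per_dataset_degs
        Mapping dataset name -> (p-filtered) DEG table; typically already
        restricted to one pathway's members via :func:`pathway_degs`.
    min_fraction
        The consistency rule: a gene is flagged when its majority sign
        recurs in at least ``max(2, ceil(min_fraction * n_datasets))``
        datasets.

    Returns a DataFrame with one row per gene appearing in any table:
    per-dataset log2FC columns (NaN where absent), ``majority_sign``
    (+1/-1; ties break toward the sign with larger summed |log2FC|, then
    +1), ``score`` (datasets carrying the majority sign), and
    ``consistent``. Invariant to dataset ordering.
    """
    if len(per_dataset_degs) < 2:
        raise ConfigurationError("consistency_scores needs >= 2 datasets")
    names = sorted(per_dataset_degs)
    n = len(names)
    need = max(2, math.ceil(min_fraction * n))
    lfc: dict[str, dict[str, float]] = {}
    for ds in names:
        t = per_dataset_degs[ds]
        for gene, val in zip(t["gene"], t["log2FC"]):
            lfc.setdefault(gene, {})[ds] = float(val)
    rows = []
    for gene in sorted(lfc):
        vals = lfc[gene]
        ups = [v for v in vals.values() if v > 0]
        downs = [v for v in vals.values() if v < 0]
        if len(ups) > len(downs):
            sign = 1
        elif len(downs) > len(ups):
            sign = -1
        else:
            sign = 1 if sum(abs(v) for v in ups) >= sum(abs(v) for v in downs) else -1
        score = len(ups) if sign > 0 else len(downs)
        rows.append({
            "gene": gene,
            **{ds: vals.get(ds, np.nan) for ds in names},
            "majority_sign": sign,
            "score": score,
            "consistent": score >= need,
        })
    return pd.DataFrame(rows)
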