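"""Gene-set over-representation, unweighted GSEA, and cross-dataset term selection.

Two complementary enrichment modes are provided. Over-representation tests
whether a DEG list overlaps a gene set more than a hypergeometric draw from
the measured universe would; the reported ``combined_score`` is
``-ln(p) * z`` where ``z`` standardizes the observed overlap against its
hypergeometric mean and standard deviation — the product of significance and
effect size familiar from enrichment web services.

Unweighted GSEA walks a ranked gene list accumulating ``+sqrt((N-k)/k)`` at
set members and ``-sqrt(k/(N-k))`` elsewhere (the Kolmogorov-Smirnov running
sum with unit-sum increments, so the sum returns to zero at the end); the
statistic is the signed extreme of the running sum, and its p-value comes
from permuting the member positions — exactly, by enumerating all C(N, k)
placements when that is feasible, else by seeded sampling with the +1
correction so p is never exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from cohortpath.errors import ConfigurationError, FormatError, LookupError_

logger = logging.getLogger(__name__)

#: Enumerate all hit placements exactly when C(N, k) is at most this.
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class GeneSetCollection:
    """A named gene-set collection restricted to a scorable universe.

    ``sets`` maps set-id -> (display name, member genes). ``universe`` is the
    list of genes that can be scored at all (e.g. genes measured on the
    platform); :meth:`restrict` intersects every set with it.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] = field(default_factory=list)

    def members(self, set_id: str) -> list[str]:
        if set_id not in self.sets:
            raise LookupError_(f"unknown gene set {set_id!r}")
        return list(self.sets[set_id][1])

    def name(self, set_id: str) -> str:
        if set_id not in self.sets:
            raise LookupError_(f"unknown gene set {set_id!r}")
        return self.sets[set_id][0]

    def restrict(self, universe: list[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = set(universe)
        restricted = {}
        for sid, (name, members) in self.sets.items():
            kept = [g for g in members if g in uni]
            if kept:
                restricted[sid] = (name, kept)
        return GeneSetCollection(sets=restricted, universe=list(universe))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set-id, description, members...) into a collection."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields"
                )
            sid, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            sets[sid] = (desc or sid, members)
    universe = sorted({g for _, m in sets.values() for g in m})
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid in collection.sets:
            name, members = collection.sets[sid]
            fh.write("\t".join([sid, name, *members]) + "\n")


@dataclass
class EnrichmentResult:
    """One gene set's enrichment outcome."""

    set_id: str
    name: str
    p_value: float
    hits: int
    expected: float
    odds_enrichment: float = float("nan")
    combined_score: float = 0.0
    statistic: float = float("nan")
    selected: bool = False


def over_representation(
    gene_list: list[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``gene_list`` in every set.

    The universe is ``collection.universe``; query genes outside it are
    dropped (logged). For a universe of M genes, a set of K members and a
    query of n genes with x observed hits, the one-sided p is
    ``P[X >= x]`` for X ~ Hypergeometric(M, K, n). Results with p < alpha
    are flagged ``selected``.
    """
    uni = set(collection.universe)
    query = sorted({g for g in gene_list if g in uni})
    dropped = len(set(gene_list)) - len(query)
    if dropped:
        logger.info("over_representation: dropped %d query genes outside universe",
                    dropped)
    if not query:
        logger.warning("over_representation: empty query list; no results")
        return []

    M, n = len(uni), len(query)
    qset = set(query)
    out = []
    for sid in collection.sets:
        name, members = collection.sets[sid]
        memb = set(members) & uni
        K = len(memb)
        if K == 0:
            continue
        x = len(memb & qset)
        p = float(stats.hypergeom.sf(x - 1, M, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        mean = n * K / M
        var = n * (K / M) * (1 - K / M) * (M - n) / (M - 1) if M > 1 else 0.0
        z = (x - mean) / math.sqrt(var) if var > 0 else 0.0
        combined = -math.log(p) * z
        out.append(
            EnrichmentResult(
                set_id=sid,
                name=name,
                p_value=p,
                hits=x,
                expected=mean,
                odds_enrichment=(x / mean) if mean > 0 else float("nan"),
                combined_score=combined,
                selected=p < alpha,
            )
        )
    out.sort(key=lambda r: (r.p_value, r.set_id))
    return out


def _running_sum_extremum(hit_mask: np.ndarray, up: float, down: float) -> tuple[float, int]:
    """Signed extreme deviation of the running sum and its 1-based position."""
    increments = np.where(hit_mask, up, -down)
    cum = np.cumsum(increments)
    i_max = int(np.argmax(cum))
    i_min = int(np.argmin(cum))
    if abs(cum[i_max]) >= abs(cum[i_min]):
        return float(cum[i_max]), i_max + 1
    return float(cum[i_min]), i_min + 1


def unweighted_gsea(
    ranked_genes: list[str],
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    exact: bool | None = None,
) -> EnrichmentResult:
    """Unweighted (Kolmogorov-Smirnov) GSEA of one set against a ranked list.

    Parameters
    ----------
    ranked_genes
        Gene list already sorted by the expression score, no duplicates.
    gene_set
        The set to test; restricted to genes present in the ranked list.
    n_perm, seed
        Permutation budget and RNG seed for the sampled null.
    exact
        Force (True) or forbid (False) exact enumeration over all C(N, k)
        hit placements; default: exact when C(N, k) <= 200,000.

    Returns hits (set size in the list), the signed extreme deviation as
    ``statistic``, ``expected`` = k * (extremum position) / N (hits expected
    at that depth under uniform interleaving), and the permutation p-value.
    """
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ConfigurationError("ranked_genes contains duplicates")
    positions = {g: i for i, g in enumerate(ranked_genes)}
    in_set = sorted({g for g in gene_set if g in positions})
    N, k = len(ranked_genes), len(in_set)
    if k == 0:
        raise ConfigurationError("gene_set shares no genes with the ranked list")
    if k == N:
        raise ConfigurationError("gene_set covers the entire ranked list")

    up = math.sqrt((N - k) / k)
    down = math.sqrt(k / (N - k))
    hit_mask = np.zeros(N, dtype=bool)
    hit_mask[[positions[g] for g in in_set]] = True
    statistic, pos = _running_sum_extremum(hit_mask, up, down)
    expected = k * pos / N

    if exact is None:
        exact = math.comb(N, k) <= EXACT_ENUMERATION_LIMIT
    if exact:
        n_ge = 0
        total = 0
        mask = np.zeros(N, dtype=bool)
        for placement in combinations(range(N), k):
            mask[:] = False
            mask[list(placement)] = True
            s, _ = _running_sum_extremum(mask, up, down)
            if abs(s) >= abs(statistic) - 1e-12:
                n_ge += 1
            total += 1
        p = n_ge / total
    else:
        rng = np.random.default_rng(seed)
        n_ge = 0
        for _ in range(n_perm):
            placement = rng.choice(N, size=k, replace=False)
            mask = np.zeros(N, dtype=bool)
            mask[placement] = True
            s, _ = _running_sum_extremum(mask, up, down)
            if abs(s) >= abs(statistic) - 1e-12:
                n_ge += 1
        p = (n_ge + 1) / (n_perm + 1)

    return EnrichmentResult(
        set_id="",
        name="",
        p_value=float(p),
        hits=k,
        expected=float(expected),
        statistic=statistic,
        selected=p < 0.05,
    )


def consistent_terms(
    results: list[list[EnrichmentResult]],
    min_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Terms selected (p < alpha) in at least ``ceil(min_fraction * n)`` datasets.

    ``results`` holds one enrichment result list per dataset. Returns a
    DataFrame (set_id, name, n_selected, threshold, per-dataset p-values)
    restricted to terms meeting the ceiling rule.
    """
    if not results:
        raise ConfigurationError("consistent_terms needs >= 1 dataset result list")
    n = len(results)
    need = math.ceil(min_fraction * n)
    counts: dict[str, int] = {}
    names: dict[str, str] = {}
    pvals: dict[str, list[float]] = {}
    for dlist in results:
        for r in dlist:
            names.setdefault(r.set_id, r.name)
            pvals.setdefault(r.set_id, [float("nan")] * n)
    for di, dlist in enumerate(results):
        for r in dlist:
            pvals[r.set_id][di] = r.p_value
            if r.selected:
                counts[r.set_id] = counts.get(r.set_id, 0) + 1
    rows = []
    for sid, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if cnt >= need:
            rows.append(
                {"set_id": sid, "name": names[sid], "n_selected": cnt,
                 "threshold": need,
                 **{f"p_ds{di + 1}": pvals[sid][di] for di in range(n)}}
            )
    return pd.DataFrame(rows)


def rollup_categories(
    term_ids: list[str],
    category_map: dict[str, str],
) -> pd.DataFrame:
    """Percentage occurrence of each category among selected terms.

    ``category_map`` maps term id -> category label (a user-supplied
    grouping); unmapped terms count under ``unassigned``. Returns a
    DataFrame (category, n_terms, percent) with percent summing to 100 for
    non-empty input.
    """
    if not term_ids:
        return pd.DataFrame(columns=["category", "n_terms", "percent"])
    counts: dict[str, int] = {}
    for t in term_ids:
        cat = category_map.get(t, "unassigned")
        counts[cat] = counts.get(cat, 0) + 1
    total = len(term_ids)
    rows = [
        {"category": c, "n_terms": n, "percent": 100.0 * n / total}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def read_category_map(path) -> dict[str, str]:
    """Read a 2-column TSV (term_id, category) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: category map needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
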