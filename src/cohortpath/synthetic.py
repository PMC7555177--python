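"""Synthetic multi-dataset cohorts with known ground truth.

Every downstream stage of the pipeline — harmonization, differential
expression, pathway scoring, guided walks, PPI modules — is exercised here on
generated data whose perturbations are known exactly. The generator emulates
the structure of a multi-cohort microarray compendium: several independent
case/control datasets per tissue, i.i.d. Gaussian noise on the log2 scale,
additive mean shifts on affected samples for designated gene sets, and the
file dialects (series-matrix tables, GMT gene sets, edge lists, scored PPI
tables) that the readers consume.

What it does **not** emulate: probe-level artifacts (background, saturation),
batch effects, or count-based RNA-seq noise. Conclusions from tests on these
cohorts are about the pipeline's statistical machinery, not about array
chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from cohortpath.errors import ConfigurationError
from cohortpath.expression_io import ExpressionDataset
from cohortpath.enrichment import GeneSetCollection

DIALECTS = ("log2", "linear", "linear_with_negatives")

#: Baseline log2 expression range typical of normalized microarray data.
BASELINE_RANGE = (4.0, 12.0)


@dataclass
class CohortSpec:
    """Specification of a synthetic multi-dataset case/control cohort.

    Parameters
    ----------
    n_datasets, n_genes
        Number of independent datasets and size of the shared gene universe.
    n_affected, n_control
        Samples per group in every dataset; both must be >= 2 so each
        gene-wise fit has at least 2 residual degrees of freedom.
    perturbed_sets
        Mapping set-id -> signed effect size in log2 units, applied as an
        additive mean shift to affected samples only.
    set_members
        Mapping set-id -> member genes for every perturbed set. May be
        omitted only when ``perturbed_sets`` is empty.
    consistent_fraction
        Each perturbation is active in ``ceil(consistent_fraction *
        n_datasets)`` datasets (chosen by seed); in the remaining datasets
        the genes behave as nulls.
    noise_sd
        Gaussian noise standard deviation on the log2 scale.
    dialect
        ``log2`` emits values as generated; ``linear`` emits ``2**x``;
        ``linear_with_negatives`` additionally subtracts a constant so the
        matrix minimum is negative (exercises the positive-shift step).
    duplicate_probes
        Emit two probes per gene with independent noise.
    flip_fraction
        Fraction of duplicated perturbed genes whose second probe carries
        the opposite injected sign (exercises the multi-sign-probe filter).
    """

    n_datasets: int
    n_genes: int
    n_affected: int
    n_control: int
    perturbed_sets: dict[str, float] = field(default_factory=dict)
    set_members: dict[str, list[str]] | None = None
    consistent_fraction: float = 1.0
    noise_sd: float = 0.5
    dialect: str = "log2"
    seed: int = 0
    duplicate_probes: bool = False
    flip_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ConfigurationError("n_datasets must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_affected < 2 or self.n_control < 2:
            raise ConfigurationError(
                "n_affected and n_control must be >= 2 "
                "(variance estimation needs residual df >= 2)"
            )
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not (0 < self.consistent_fraction <= 1):
            raise ConfigurationError("consistent_fraction must be in (0, 1]")
        if self.dialect not in DIALECTS:
            raise ConfigurationError(
                f"dialect must be one of {DIALECTS}, got {self.dialect!r}"
            )
        if not (0 <= self.flip_fraction <= 1):
            raise ConfigurationError("flip_fraction must be in [0, 1]")
        if self.perturbed_sets and not self.set_members:
            raise ConfigurationError(
                "set_members is required when perturbed_sets is non-empty"
            )
        for sid in self.perturbed_sets:
            if self.set_members is None or sid not in self.set_members:
                raise ConfigurationError(f"set_members missing entry for {sid!r}")


@dataclass
class GroundTruth:
    """What was actually planted in a generated cohort.

    Attributes
    ----------
    perturbed
        Per dataset name, mapping gene -> signed injected effect (log2).
    pathway_direction
        Per perturbed set-id, +1 (up) or -1 (down).
    active_datasets
        Per perturbed set-id, the dataset names in which it is active.
    probe_map
        probe id -> gene symbol, when probes were duplicated; else empty.
    flipped_probes
        Probe ids whose injected sign was inverted.
    """

    perturbed: dict[str, dict[str, float]]
    pathway_direction: dict[str, int]
    active_datasets: dict[str, list[str]]
    probe_map: dict[str, str] = field(default_factory=dict)
    flipped_probes: set[str] = field(default_factory=set)

    @property
    def all_perturbed_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.perturbed.values():
            out.update(genes)
        return out


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene symbols G0000..G{n-1}."""
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def generate_cohort(spec: CohortSpec) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate ``spec.n_datasets`` expression datasets plus their ground truth.

    Each dataset draws per-gene baselines uniform on the log2 range
    ``BASELINE_RANGE``, adds i.i.d. Gaussian noise, and shifts the mean of
    affected samples by the signed effect for genes of active perturbed
    sets. Generation is bit-reproducible under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = gene_universe(spec.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for sid, members in (spec.set_members or {}).items():
        unknown = [g for g in members if g not in gene_index]
        if unknown:
            raise ConfigurationError(
                f"set_members[{sid!r}] contains genes outside the universe: "
                f"{unknown[:5]}"
            )

    n_active = {
        sid: math.ceil(spec.consistent_fraction * spec.n_datasets)
        for sid in spec.perturbed_sets
    }
    dataset_names = [f"{'synthds'}{k + 1:02d}" for k in range(spec.n_datasets)]
    active: dict[str, list[str]] = {
        sid: sorted(rng.choice(spec.n_datasets, size=n_active[sid], replace=False))
        for sid in spec.perturbed_sets
    }
    active_names = {
        sid: [dataset_names[k] for k in idx] for sid, idx in active.items()
    }

    n_samp = spec.n_affected + spec.n_control
    datasets: list[ExpressionDataset] = []
    perturbed: dict[str, dict[str, float]] = {}
    probe_map: dict[str, str] = {}
    flipped: set[str] = set()

    # choose flipped genes once so the flip is consistent across datasets
    if spec.duplicate_probes and spec.flip_fraction > 0:
        all_members = sorted({g for m in (spec.set_members or {}).values() for g in m})
        n_flip = int(round(spec.flip_fraction * len(all_members)))
        flip_genes = set(
            rng.choice(all_members, size=n_flip, replace=False)
        ) if n_flip else set()
    else:
        flip_genes = set()

    for k, ds_name in enumerate(dataset_names):
        effects = np.zeros(spec.n_genes)
        ds_truth: dict[str, float] = {}
        for sid, eff in spec.perturbed_sets.items():
            if k not in set(active[sid]):
                continue
            for g in spec.set_members[sid]:
                effects[gene_index[g]] += eff
                ds_truth[g] = ds_truth.get(g, 0.0) + eff
        perturbed[ds_name] = ds_truth

        baseline = rng.uniform(*BASELINE_RANGE, size=spec.n_genes)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samp))
        log2 = baseline[:, None] + noise
        log2[:, : spec.n_affected] += effects[:, None]

        sample_ids = [f"S{j + 1:02d}" for j in range(n_samp)]
        groups = {
            s: ("affected" if j < spec.n_affected else "control")
            for j, s in enumerate(sample_ids)
        }
        if spec.duplicate_probes:
            noise2 = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samp))
            log2b = baseline[:, None] + noise2
            eff2 = effects.copy()
            for g in flip_genes:
                i = gene_index[g]
                eff2[i] = -eff2[i]
            log2b[:, : spec.n_affected] += eff2[:, None]
            probes = [f"{g}.p1" for g in genes] + [f"{g}.p2" for g in genes]
            mat = np.vstack([log2, log2b])
            for g in genes:
                probe_map[f"{g}.p1"] = g
                probe_map[f"{g}.p2"] = g
            flipped |= {f"{g}.p2" for g in flip_genes if g in ds_truth}
            values = pd.DataFrame(mat, index=probes, columns=sample_ids)
        else:
            values = pd.DataFrame(log2, index=genes, columns=sample_ids)

        is_log2 = spec.dialect == "log2"
        if spec.dialect in ("linear", "linear_with_negatives"):
            values = np.power(2.0, values)
            if spec.dialect == "linear_with_negatives":
                # shift so the minimum is negative, exercising positive_shift
                values = values - (float(values.to_numpy().min()) + 1.0)
        datasets.append(
            ExpressionDataset(values=values, groups=groups, is_log2=is_log2,
                              name=ds_name)
        )

    direction = {sid: (1 if eff > 0 else -1) for sid, eff in spec.perturbed_sets.items()}
    truth = GroundTruth(
        perturbed=perturbed,
        pathway_direction=direction,
        active_datasets=active_names,
        probe_map=probe_map,
        flipped_probes=flipped,
    )
    return datasets, truth


def generate_pathways(
    n_pathways: int,
    size_range: tuple[int, int],
    universe: list[str],
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Generate a gene-set collection with controlled neighbor overlap.

    Consecutive sets (``PW01``/``PW02``, ``PW02``/``PW03``, ...) are the
    designated neighbors; each neighbor pair attains Jaccard overlap >=
    ``overlap_fraction``. With ``overlap_fraction=0`` all sets are pairwise
    disjoint (requires a large enough universe). With a positive
    ``overlap_fraction``, non-neighbor sets also share genes by chance —
    members are drawn from the whole universe, as in real curated
    collections where pleiotropic genes recur across many sets.
    """
    lo, hi = size_range
    if not universe:
        raise ConfigurationError("universe is empty")
    if lo < 1 or hi < lo or hi > len(universe):
        raise ConfigurationError(
            f"size_range {size_range} infeasible for universe of {len(universe)}"
        )
    if not (0 <= overlap_fraction <= 1):
        raise ConfigurationError("overlap_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    unused = list(universe)
    rng.shuffle(unused)
    width = max(2, len(str(n_pathways)))
    sets: dict[str, list[str]] = {}
    prev: list[str] = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if prev and overlap_fraction > 0:
            # Jaccard(A,B) = k / (|A| + |B| - k) >= f  =>  k >= f(|A|+|B|)/(1+f)
            k = math.ceil(overlap_fraction * (len(prev) + size) / (1 + overlap_fraction))
            if k > min(len(prev), size):
                raise ConfigurationError(
                    f"overlap_fraction {overlap_fraction} infeasible for set "
                    f"sizes {len(prev)} and {size}"
                )
            shared = list(rng.choice(prev, size=k, replace=False))
        else:
            shared = []
        n_fresh = size - len(shared)
        if overlap_fraction > 0:
            pool = [g for g in universe if g not in set(shared)]
            fresh = list(rng.choice(pool, size=n_fresh, replace=False))
        else:
            if n_fresh > len(unused):
                raise ConfigurationError(
                    f"universe of {len(universe)} genes exhausted at pathway "
                    f"{i + 1} of {n_pathways}"
                )
            fresh, unused = unused[:n_fresh], unused[n_fresh:]
        members = sorted(set(shared) | set(fresh))
        sid = f"PW{i + 1:0{width}d}"
        sets[sid] = members
        prev = members
    return GeneSetCollection(
        sets={sid: (sid, members) for sid, members in sets.items()},
        universe=list(universe),
    )


def generate_pathway_network(
    collection: GeneSetCollection,
    min_shared: int = 1,
    seed: int = 0,
) -> nx.Graph:
    """Build a pathway-to-pathway graph from shared-gene counts.

    An undirected edge joins two sets sharing at least ``min_shared`` genes
    (``min_shared=0`` yields the complete graph). If the result is
    disconnected, a spanning backbone of extra edges is added so walks can
    reach every pathway; backbone edges carry ``backbone=True`` and the
    graph attribute ``backbone_added`` flags the intervention.
    """
    if not collection.sets:
        raise ConfigurationError("collection is empty")
    g = nx.Graph(backbone_added=False)
    ids = sorted(collection.sets)
    g.add_nodes_from(ids)
    members = {sid: set(collection.members(sid)) for sid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if len(members[a] & members[b]) >= min_shared:
                g.add_edge(a, b, backbone=False)
    if nx.number_connected_components(g) > 1:
        rng = np.random.default_rng(seed)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        for prev_comp, comp in zip(comps, comps[1:]):
            u = prev_comp[int(rng.integers(len(prev_comp)))]
            v = comp[int(rng.integers(len(comp)))]
            g.add_edge(u, v, backbone=True)
        g.graph["backbone_added"] = True
    return g


def generate_ppi_table(
    genes: list[str],
    module_assignments: dict[str, int],
    intra_score_range: tuple[float, float] = (0.75, 0.99),
    inter_score_range: tuple[float, float] = (0.15, 0.5),
    seed: int = 0,
    intra_density: float = 0.9,
    inter_density: float = 0.05,
) -> pd.DataFrame:
    """Emit a 3-column scored interaction table with planted modules.

    Pairs within a module are drawn with probability ``intra_density`` and
    scored uniformly in ``intra_score_range``; pairs across modules with
    probability ``inter_density`` in ``inter_score_range``. Thresholding at
    a score above ``inter_score_range`` therefore recovers the planted
    modules exactly. Columns: protein1, protein2, combined_score.
    """
    for name, (a, b) in (("intra", intra_score_range), ("inter", inter_score_range)):
        if not (0 <= a <= b <= 1):
            raise ConfigurationError(f"{name}_score_range must be within [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    ordered = sorted(genes)
    for i, u in enumerate(ordered):
        for v in ordered[i + 1:]:
            same = (
                u in module_assignments
                and v in module_assignments
                and module_assignments[u] == module_assignments[v]
            )
            density = intra_density if same else inter_density
            if rng.random() >= density:
                continue
            lo, hi = intra_score_range if same else inter_score_range
            rows.append((u, v, float(np.round(rng.uniform(lo, hi), 3))))
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
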