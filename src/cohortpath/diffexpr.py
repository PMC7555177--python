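"""Per-gene two-group differential expression with empirical-Bayes moderation.

The model is the classical gene-wise linear fit: for each gene,
``log2FC = mean(affected) - mean(control)`` with a pooled residual variance
``s_g^2`` on ``df = n_a + n_c - 2`` degrees of freedom. The per-gene
variances are then shrunk toward a common prior by empirical Bayes: assuming
``s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_df / df`` and a scaled inverse-chi-square
prior ``1/sigma_g^2 ~ chi2_d0 / (d0 s0^2)``, the marginal distribution of
``log s_g^2`` has closed-form moments in terms of digamma/trigamma functions,
so the prior degrees of freedom ``d0`` and prior variance ``s0^2`` are
estimated by moment matching with a Newton inversion of the trigamma
function (Smyth 2004). The posterior variance

    s_tilde_g^2 = (d0 s0^2 + df s_g^2) / (d0 + df)

yields the moderated t-statistic ``t = log2FC / sqrt(s_tilde^2 (1/n_a +
1/n_c))`` on ``d0 + df`` degrees of freedom. With ``d0 = 0`` this reduces to
the ordinary pooled t; with ``d0 -> inf`` every gene is judged against the
common prior variance.

Downstream filters reproduce a fixed cascade: raw-p cutoff, removal of genes
whose probes disagree in fold-change sign, lowest-p deduplication of
same-sign probes, biotype/prefix exclusion of non-coding entries, and a
fold-change-ranked cap. Benjamini-Hochberg adjusted p-values are reported
alongside but intentionally not used for filtering.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from cohortpath.errors import DegenerateVarianceError, DesignError
from cohortpath.expression_io import ExpressionDataset

#: Biotypes excluded by the coding filter (case-insensitive, separators ignored).
EXCLUDED_BIOTYPES = frozenset({
    "noncoding", "ncrna", "lncrna", "lincrna", "microrna", "mirna",
    "miscrna", "snrna", "snorna", "uncharacterized", "pseudogene",
})

#: Symbol prefixes excluded by the coding filter.
EXCLUDED_PREFIXES = ("LOC", "FLJ", "RP")

_CLONE_RE = re.compile(r"^RP\d+-")


def fit_linear_model(
    dataset: ExpressionDataset,
    probe_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Gene-wise least-squares fit of the affected-vs-control contrast.

    Carrier samples are excluded from the design. Returns a DataFrame with
    columns ``probe, gene, log2FC, residual_var, df_residual, n_affected,
    n_control``; ``gene`` equals ``probe`` unless ``probe_map`` translates it.

    Raises
    ------
    DesignError
        If either group has fewer than 2 samples.
    """
    aff = dataset.samples_in_group("affected")
    ctl = dataset.samples_in_group("control")
    if len(aff) < 2 or len(ctl) < 2:
        raise DesignError(
            f"{dataset.name}: need >= 2 samples per group, got "
            f"{len(aff)} affected / {len(ctl)} control"
        )
    a = dataset.values[aff].to_numpy(dtype=float)
    c = dataset.values[ctl].to_numpy(dtype=float)
    na, nc = a.shape[1], c.shape[1]
    mean_a, mean_c = a.mean(axis=1), c.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((c - mean_c[:, None]) ** 2).sum(axis=1)
    df = na + nc - 2
    probes = list(dataset.values.index)
    genes = [probe_map.get(p, p) if probe_map else p for p in probes]
    return pd.DataFrame({
        "probe": probes,
        "gene": genes,
        "log2FC": mean_a - mean_c,
        "residual_var": ss / df,
        "df_residual": df,
        "n_affected": na,
        "n_control": nc,
    })


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration.

    Uses the monotone transform suggested by the asymptotics
    ``trigamma(y) ~ 1/y``: starting from ``y = 0.5 + 1/x``, iterate
    ``y <- y + trigamma(y) * (1 - trigamma(y)/x) / psi''(y)`` until the
    relative step falls below ``tol``.
    """
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        delta = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += delta
        if abs(delta) < tol * y:
            break
    return y


@dataclass
class ModerationResult:
    """Empirical-Bayes prior and the per-gene moderated statistics table."""

    d0: float
    s0_sq: float
    table: pd.DataFrame  # probe, gene, log2FC, posterior_var, moderated_t, p_value, adj_p_value


def estimate_prior(residual_var: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Works on ``e_g = log s_g^2 - digamma(df/2) + log(df/2)``: under the
    hierarchical model ``mean(e) = log s0^2 - digamma(d0/2) + log(d0/2)``
    and ``var(e) = trigamma(df/2) + trigamma(d0/2)``, so ``d0`` comes from a
    trigamma inversion of the excess variance and ``s0^2`` from the mean.
    Genes with zero residual variance are excluded from the moments.
    """
    pos = residual_var > 0
    if not pos.any():
        raise DegenerateVarianceError("all residual variances are zero")
    s2 = residual_var[pos]
    d = df[pos].astype(float)
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_bar = float(np.mean(e))
    n = len(e)
    if n < 2:
        return float("inf"), float(np.exp(e_bar))
    excess = float(np.sum((e - e_bar) ** 2) / (n - 1)) - float(
        np.mean(special.polygamma(1, d / 2.0))
    )
    if excess <= 0:
        return float("inf"), float(np.exp(e_bar))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(
        e_bar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    ))
    return d0, s0_sq


def moderate_variances(
    fits: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModerationResult:
    """Shrink per-gene variances and compute moderated t and p-values.

    ``d0`` / ``s0_sq`` default to the moment estimates of
    :func:`estimate_prior`; passing ``d0=0`` recovers the ordinary pooled t.
    Two-sided p-values come from a t distribution with ``d0 + df`` degrees
    of freedom (standard normal in the ``d0 = inf`` limit). Adds
    Benjamini-Hochberg ``adj_p_value`` for reporting.
    """
    s2 = fits["residual_var"].to_numpy(dtype=float)
    df = fits["df_residual"].to_numpy(dtype=float)
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if math.isinf(d0):
        post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)

    na = fits["n_affected"].to_numpy(dtype=float)
    nc = fits["n_control"].to_numpy(dtype=float)
    se = np.sqrt(post * (1.0 / na + 1.0 / nc))
    lfc = fits["log2FC"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    df_total = d0 + df
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    table = fits[["probe", "gene", "log2FC"]].copy()
    table["posterior_var"] = post
    table["moderated_t"] = t
    table["p_value"] = p
    table["adj_p_value"] = adj
    return ModerationResult(d0=float(d0), s0_sq=float(s0_sq), table=table)


def filter_degs(table: pd.DataFrame, p_thresh: float = 0.05) -> pd.DataFrame:
    """Apply the p cutoff, multi-sign-probe removal, and lowest-p dedup.

    Order matters and is fixed: (1) drop rows with ``p >= p_thresh``;
    (2) remove genes whose *surviving* probes carry both positive and
    negative log2FC; (3) collapse remaining same-sign duplicates to the row
    with the lowest p-value (ties: larger |log2FC|, then probe id).
    """
    surv = table[table["p_value"] < p_thresh].copy()
    if surv.empty:
        return surv.reset_index(drop=True)
    sign = np.sign(surv["log2FC"].to_numpy())
    surv["_sign"] = sign
    by_gene = surv.groupby("gene")["_sign"]
    conflicted = by_gene.agg(lambda s: (s > 0).any() and (s < 0).any())
    keep_genes = conflicted[~conflicted].index
    surv = surv[surv["gene"].isin(keep_genes)].copy()
    sort_cols = ["gene", "p_value", "_abs_lfc"]
    surv["_abs_lfc"] = -surv["log2FC"].abs()
    if "probe" in surv.columns:
        sort_cols.append("probe")
    surv = surv.sort_values(sort_cols, kind="stable")
    surv = surv.drop_duplicates(subset="gene", keep="first")
    return (
        surv.drop(columns=["_sign", "_abs_lfc"])
        .sort_values(["p_value", "gene"], kind="stable")
        .reset_index(drop=True)
    )


def _normalize_biotype(biotype: str) -> str:
    return re.sub(r"[\s_\-]", "", biotype.strip().lower())


def coding_filter(
    table: pd.DataFrame,
    annotation: dict[str, str] | None = None,
    rp_prefix_mode: str = "literal",
) -> pd.DataFrame:
    """Drop non-coding and uncharacterized entries.

    Rows are removed when the annotated biotype is in ``EXCLUDED_BIOTYPES``
    or the symbol starts with LOC, FLJ, or RP. ``rp_prefix_mode='literal'``
    applies the RP prefix as written (which also removes ribosomal-protein
    RPL/RPS symbols); ``'clone_only'`` restricts it to RP11-style clone ids
    (``RP<digits>-``).
    """
    if rp_prefix_mode not in ("literal", "clone_only"):
        raise ValueError(f"rp_prefix_mode must be literal|clone_only, got {rp_prefix_mode!r}")

    def excluded(gene: str) -> bool:
        if annotation and gene in annotation:
            if _normalize_biotype(annotation[gene]) in EXCLUDED_BIOTYPES:
                return True
        for pref in EXCLUDED_PREFIXES:
            if gene.startswith(pref):
                if pref == "RP" and rp_prefix_mode == "clone_only":
                    return bool(_CLONE_RE.match(gene))
                return True
        return False

    mask = ~table["gene"].map(excluded)
    return table[mask].reset_index(drop=True)


def select_top(
    table: pd.DataFrame,
    abs_lfc_thresh: float = 0.585,
    top_n: int = 500,
) -> list[str]:
    """Fold-change-ranked selection of the strongest DEGs.

    Keeps rows with ``|log2FC|`` strictly above ``abs_lfc_thresh``, then
    returns at most ``top_n`` genes by descending |log2FC|; ties at the cut
    break by ascending p-value, then lexicographic gene id.
    """
    passing = table[table["log2FC"].abs() > abs_lfc_thresh].copy()
    passing["_abs"] = passing["log2FC"].abs()
    passing = passing.sort_values(
        ["_abs", "p_value", "gene"], ascending=[False, True, True], kind="stable"
    )
    return passing["gene"].head(top_n).tolist()


def deg_overlap(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise and all-way DEG intersection counts across datasets.

    Returns a DataFrame with one row per dataset pair plus a final ``ALL``
    row, and columns ``n_shared`` (gene id intersection) and
    ``n_same_sign`` (intersection restricted to agreeing log2FC sign).
    """
    if len(tables) < 2:
        raise DesignError("deg_overlap needs >= 2 DEG tables")
    signs = {
        name: dict(zip(t["gene"], np.sign(t["log2FC"])))
        for name, t in tables.items()
    }
    names = list(tables)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = set(signs[a]) & set(signs[b])
            same = {g for g in shared if signs[a][g] == signs[b][g]}
            rows.append({"datasets": f"{a}&{b}", "n_shared": len(shared),
                         "n_same_sign": len(same)})
    common = set.intersection(*(set(s) for s in signs.values()))
    same_all = {
        g for g in common
        if len({signs[n][g] for n in names}) == 1
    }
    rows.append({"datasets": "ALL", "n_shared": len(common),
                 "n_same_sign": len(same_all)})
    return pd.DataFrame(rows)
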