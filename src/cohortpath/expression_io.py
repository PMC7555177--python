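"""Reading and harmonizing case/control expression matrices.

Input matrices arrive in the GEO Series-Matrix dialect: ``!``-prefixed
metadata lines surrounding a tab-delimited table delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end``, with probe or
gene identifiers in the first column and one column per sample.

Harmonization brings every dataset onto a common scale before model fitting:
pre-logged matrices are reverse-transformed to linear intensities, a positive
shift removes zeros and negative values, all sample distributions are forced
to a common reference by quantile normalization, and the result is
log2-transformed. After harmonization every column holds the same sorted
multiset of values, so between-sample distributional differences cannot
masquerade as differential expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cohortpath.errors import FormatError, NumericRangeError

logger = logging.getLogger(__name__)

#: Sample phenotype labels. Carriers are retained in the dataset object but
#: excluded from the differential-expression design downstream.
VALID_GROUPS = ("affected", "control", "carrier")

#: Matrices whose maximum exceeds this are assumed to hold linear-scale
#: intensities; at or below it, log2. Advisory only — override per dataset.
LOG_SCALE_MAX = 30.0


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene/probe identifier, one column per sample.
    groups
        Mapping sample id -> one of ``affected``, ``control``, ``carrier``.
    is_log2
        Whether ``values`` are on the log2 scale (as opposed to linear
        intensities).
    name
        Optional dataset label used in logs and report artifacts.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    is_log2: bool
    name: str = "dataset"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise FormatError(
                f"{self.name}: samples without a group label: {missing[:5]}"
            )
        bad = {s: g for s, g in self.groups.items() if g not in VALID_GROUPS}
        if bad:
            raise FormatError(f"{self.name}: invalid group labels: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


def read_group_map(path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, group) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: group map needs 2 columns, found {df.shape[1]}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        return token[1:-1]
    return token


def read_series_matrix(
    path,
    group_map: dict[str, str] | str,
    is_log2: bool | None = None,
    probe_map: dict[str, str] | None = None,
    name: str | None = None,
) -> ExpressionDataset:
    """Parse a Series-Matrix-dialect file into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        Path to the tab-delimited file. Exactly one table block delimited by
        ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` is
        expected; other ``!`` metadata lines are ignored.
    group_map
        Mapping sample -> group, or path to a 2-column TSV holding one.
    is_log2
        Scale of the stored values. When ``None``, :func:`detect_log_scale`
        decides (advisory heuristic).
    probe_map
        Optional probe -> gene symbol mapping applied to row identifiers;
        rows absent from the map keep their original id.

    Blank and ``NA``/``null`` cells are recorded as missing (NaN); they are
    imputed later by :func:`harmonize`.
    """
    if isinstance(group_map, (str,)) or hasattr(group_map, "__fspath__"):
        group_map = read_group_map(group_map)

    header: list[str] | None = None
    rows: list[list[str]] = []
    index: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                saw_begin, in_table = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                saw_end, in_table = True, False
                continue
            if not in_table or not line.strip():
                continue
            fields = [_unquote(t) for t in line.split("\t")]
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"{path}:{lineno}: ragged row with {len(fields)} fields, "
                    f"expected {len(header) + 1}"
                )
            index.append(fields[0])
            rows.append(fields[1:])
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing series-matrix table delimiter"
            f" ({'begin' if not saw_begin else 'end'} marker not found)"
        )
    if header is None:
        raise FormatError(f"{path}: table block contains no header row")

    # blank / NA / null cells become NaN and are imputed by harmonize();
    # float() is used directly for correctly-rounded decimal parsing
    def _cell(tok: str) -> float:
        try:
            return float(tok)
        except ValueError:
            return float("nan")

    arr = np.array([[_cell(t) for t in row] for row in rows], dtype=float)
    arr = arr.reshape(len(index), len(header))
    values = pd.DataFrame(arr, index=index, columns=header)
    if probe_map:
        values.index = [probe_map.get(g, g) for g in values.index]

    groups = {s: group_map[s] for s in values.columns if s in group_map}
    absent = [s for s in values.columns if s not in group_map]
    if absent:
        raise FormatError(f"{path}: samples missing from group map: {absent[:5]}")

    ds_name = name if name is not None else str(path)
    ds = ExpressionDataset(values=values, groups=groups, is_log2=bool(is_log2),
                           name=ds_name)
    if is_log2 is None:
        ds.is_log2 = detect_log_scale(ds)
    return ds


def write_series_matrix(dataset: ExpressionDataset, path, float_format: str = "%.17g") -> None:
    """Write a dataset in the Series-Matrix dialect read by :func:`read_series_matrix`."""
    with open(path, "w") as fh:
        fh.write(f"!Series_title\t\"{dataset.name}\"\n")
        fh.write("!Sample_geo_accession\t"
                 + "\t".join(f'"{s}"' for s in dataset.sample_ids) + "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s}"' for s in dataset.sample_ids) + "\n")
        for gene, row in dataset.values.iterrows():
            cells = ["" if not np.isfinite(v) else float_format % v for v in row.to_numpy()]
            fh.write(f'"{gene}"\t' + "\t".join(cells) + "\n")
        fh.write("!series_matrix_table_end\n")


def detect_log_scale(dataset: ExpressionDataset) -> bool:
    """Heuristic scale detection: log2 iff the matrix maximum is <= 30.

    Microarray intensities on the linear scale run into the tens of
    thousands, while log2 values rarely exceed ~20; the boundary is
    inclusive (a maximum of exactly 30 reads as log2). Advisory only.
    """
    mx = np.nanmax(dataset.values.to_numpy())
    return bool(mx <= LOG_SCALE_MAX)


def positive_shift(dataset: ExpressionDataset) -> ExpressionDataset:
    """Shift the whole matrix so its minimum is strictly positive.

    If the matrix minimum ``m`` is <= 0, every value is increased by
    ``-m + 0.01`` (so a former zero becomes 0.01); an all-positive matrix is
    returned unchanged.
    """
    m = np.nanmin(dataset.values.to_numpy())
    if m > 0:
        return dataset
    if m == 0:
        logger.info("%s: matrix minimum is exactly 0; shifting by 0.01", dataset.name)
    return replace(dataset, values=dataset.values + (-m + 0.01))


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference distribution.

    Ties within a column receive the average of the reference values their
    sorted positions span.
    """
    arr = values.to_numpy(dtype=float)
    n, p = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(arr, order, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(p):
        col_sorted_ref = ref.copy()
        col = arr[:, j]
        # average reference values over each run of tied input values
        sorted_vals = col[order[:, j]]
        start = 0
        assigned = np.empty(n)
        while start < n:
            end = start + 1
            while end < n and sorted_vals[end] == sorted_vals[start]:
                end += 1
            assigned[start:end] = col_sorted_ref[start:end].mean()
            start = end
        out[order[:, j], j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize all samples of a dataset to a common distribution."""
    return replace(dataset, values=_quantile_normalize_frame(dataset.values))


def harmonize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Run the full harmonization pipeline, returning a log2-scale dataset.

    Steps: missing-value imputation by row median -> (if pre-logged) reverse
    transform ``x -> 2**x`` -> :func:`positive_shift` ->
    :func:`quantile_normalize` -> log2. The output has ``is_log2=True`` and
    only finite values.

    Raises
    ------
    NumericRangeError
        If reverse transformation overflows to non-finite values.
    """
    values = dataset.values
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: imputing %d missing cells with row medians",
                    dataset.name, n_missing)
        med = values.median(axis=1)
        values = values.apply(lambda col: col.fillna(med))
        # rows that are entirely missing have no median; drop them
        all_na = values.isna().any(axis=1)
        if all_na.any():
            logger.warning("%s: dropping %d all-missing rows",
                           dataset.name, int(all_na.sum()))
            values = values.loc[~all_na]
    ds = replace(dataset, values=values)

    if ds.is_log2:
        linear = np.power(2.0, ds.values)
        if not np.isfinite(linear.to_numpy()).all():
            raise NumericRangeError(
                f"{ds.name}: reverse log2 transform produced non-finite values"
            )
        ds = replace(ds, values=linear, is_log2=False)

    ds = positive_shift(ds)
    ds = quantile_normalize(ds)
    return replace(ds, values=np.log2(ds.values), is_log2=True)
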