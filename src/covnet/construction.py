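"""Group-level network construction from regional thickness tables.

The structural covariance pipeline: per-region thickness values are
residualised on each subject's overall mean thickness (removing the
global-thickness nuisance), correlated across subjects within each group
to give a region-by-region Pearson matrix, and binarized at a set of
connection densities.  Rather than one absolute correlation threshold,
networks are compared across a density grid whose lower bound is the
smallest density at which both groups' networks are a single connected
component (D_min) and whose upper bound is 0.5, in steps of 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Reserved (non-region) column names in delimited thickness tables.
META_COLUMNS = ("subject", "group", "mean_thickness")


@dataclass
class ThicknessTable:
    """Subject-by-region thickness matrix for one group.

    ``values`` is ``(n_subjects, n_regions)`` in millimetres;
    ``mean_thickness`` is the per-subject whole-cortex mean used as the
    nuisance covariate.  ``adjusted`` marks residualised tables, whose
    values are zero-centred and may be negative.
    """

    group_label: str
    subject_ids: list[str]
    region_labels: list[str]
    values: np.ndarray
    mean_thickness: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean_thickness = np.asarray(self.mean_thickness, dtype=float)
        n, r = self.values.shape
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length != number of rows")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject ids must be unique")
        if len(self.region_labels) != r:
            raise ValidationError("region_labels length != number of columns")
        if len(set(self.region_labels)) != r:
            raise ValidationError("region labels must be unique")
        if self.mean_thickness.shape != (n,):
            raise ValidationError("mean_thickness must have one value per subject")
        if not np.all(np.isfinite(self.values)) or not np.all(
            np.isfinite(self.mean_thickness)
        ):
            raise ValidationError("thickness values must be finite (no missing data)")
        if not self.adjusted and np.any(self.values <= 0):
            raise ValidationError("raw thickness values must be positive (mm)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"subject": self.subject_ids, "group": self.group_label,
             "mean_thickness": self.mean_thickness}
        )
        for j, label in enumerate(self.region_labels):
            frame[label] = self.values[:, j]
        return frame

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_thickness_tables(
    path: str | Path, sep: str | None = None
) -> dict[str, ThicknessTable]:
    """Read a delimited subject-by-region table and split it by group.

    The header must contain ``subject``, ``group`` and ``mean_thickness``;
    every other column is taken as a region.  ``sep=None`` sniffs comma vs
    tab from the header line.
    """
    path = Path(path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    region_labels = [c for c in frame.columns if c not in META_COLUMNS]
    if not region_labels:
        raise ValidationError(f"{path}: no region columns found")
    tables: dict[str, ThicknessTable] = {}
    for label, sub in frame.groupby("group", sort=True):
        tables[str(label)] = ThicknessTable(
            group_label=str(label),
            subject_ids=[str(s) for s in sub["subject"]],
            region_labels=region_labels,
            values=sub[region_labels].to_numpy(dtype=float),
            mean_thickness=sub["mean_thickness"].to_numpy(dtype=float),
        )
    return tables


@dataclass
class CovarianceMatrix:
    """Symmetric region-by-region Pearson correlation matrix, zero diagonal."""

    region_labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.region_labels)
        if self.r.shape != (n, n):
            raise ValidationError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValidationError("correlations must lie in [-1, 1]")
        if np.any(np.diag(self.r) != 0):
            raise ValidationError("diagonal must be exactly zero")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_labels,
                            columns=self.region_labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal graph at a stated connection density."""

    region_labels: list[str]
    a: np.ndarray
    density: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        n = len(self.region_labels)
        if self.a.shape != (n, n):
            raise ValidationError("adjacency shape mismatch")
        if not np.array_equal(self.a, self.a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(self.a) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.isin(self.a, (0, 1)).all():
            raise ValidationError("adjacency must be binary")
        if not (0 < self.density <= 1):
            raise ValidationError("density must lie in (0, 1]")

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def edge_list(self) -> pd.DataFrame:
        i, j = np.where(np.triu(self.a, 1))
        return pd.DataFrame(
            {"region_a": [self.region_labels[k] for k in i],
             "region_b": [self.region_labels[k] for k in j]}
        )

    def write_edge_list(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(self.region_labels)
        frame = self.edge_list()
        graph.add_edges_from(frame.itertuples(index=False, name=None))
        nx.write_graphml(graph, str(path))


@dataclass
class DensityGrid:
    """The density range of one pairwise contrast.

    ``lower`` is the larger of the two groups' minimum connected densities;
    the grid climbs in ``step`` increments while it stays at or below
    ``upper``.
    """

    d_min_per_group: dict[str, float]
    lower: float
    step: float = 0.05
    upper: float = 0.5
    densities: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.densities:
            self.densities = _enumerate_densities(self.lower, self.step, self.upper)
        if any(b <= a for a, b in zip(self.densities, self.densities[1:])):
            raise ValidationError("densities must be strictly increasing")


def _enumerate_densities(lower: float, step: float, upper: float) -> tuple[float, ...]:
    out = []
    k = 0
    while True:
        d = round(lower + k * step, 10)
        if d > upper + 1e-9:
            break
        out.append(d)
        k += 1
    return tuple(out)


def adjust_for_mean_thickness(table: ThicknessTable) -> ThicknessTable:
    """Residualise each region on the subject-level mean thickness.

    Per-region ordinary least squares with intercept, fit within the group;
    the returned residual columns are zero-mean and exactly uncorrelated
    with the covariate.  A constant covariate degrades to plain mean
    centering (warned), and a constant region column yields zero residuals
    (warned).
    """
    if table.n_subjects < 3:
        raise ValidationError("adjustment needs at least 3 subjects")
    y = table.values
    x = table.mean_thickness
    xc = x - x.mean()
    sxx = float(xc @ xc)
    constant_regions = [
        label
        for j, label in enumerate(table.region_labels)
        if np.ptp(y[:, j]) == 0
    ]
    if constant_regions:
        logger.warning(
            "group %s: constant region column(s) %s; residuals set to zero",
            table.group_label, constant_regions,
        )
    yc = y - y.mean(axis=0, keepdims=True)
    if sxx == 0.0:
        logger.warning(
            "group %s: mean thickness constant across subjects; "
            "falling back to mean centering", table.group_label,
        )
        resid = yc
    else:
        slopes = (xc @ yc) / sxx
        resid = yc - np.outer(xc, slopes)
    return ThicknessTable(
        group_label=table.group_label,
        subject_ids=list(table.subject_ids),
        region_labels=list(table.region_labels),
        values=resid,
        mean_thickness=table.mean_thickness.copy(),
        adjusted=True,
    )


def pearson_matrix(table: ThicknessTable) -> CovarianceMatrix:
    """Across-subject Pearson correlation of the (adjusted) regional values.

    Zero-variance regions get zero rows/columns with a warning; the
    diagonal is set to zero.
    """
    if table.n_subjects < 3:
        raise ValidationError("correlation needs at least 3 subjects")
    y = table.values
    sd = y.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [l for l, d in zip(table.region_labels, degenerate) if d]
        logger.warning(
            "group %s: zero-variance region(s) %s; correlations set to 0",
            table.group_label, bad,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y, rowvar=False)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return CovarianceMatrix(region_labels=list(table.region_labels), r=r)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (x >= 0 here)."""
    return int(math.floor(x + 0.5))


def ranked_pairs(c: CovarianceMatrix) -> np.ndarray:
    """Node-pair indices (P, 2) ordered by descending correlation.

    Ties break deterministically by lexicographic region-label order so
    binarization is reproducible under permutation replicates.
    """
    n = c.n_regions
    iu, ju = np.triu_indices(n, 1)
    label_rank = np.argsort(np.argsort(np.asarray(c.region_labels)))
    order = np.lexsort((label_rank[ju], label_rank[iu], -c.r[iu, ju]))
    return np.column_stack((iu[order], ju[order]))


def binarize_at_density(c: CovarianceMatrix, density: float) -> AdjacencyMatrix:
    """Keep the top ``round(density * P)`` correlations as edges.

    Ranking is by signed r (largest positive first), reflecting the
    positive-covariance notion of connectivity; if the requested edge count
    exceeds the number of positive correlations, negative ones are admitted
    with a logged warning.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must lie in (0, 1]")
    n = c.n_regions
    p = n * (n - 1) // 2
    m = round_half_away(density * p)
    pairs = ranked_pairs(c)[:m]
    if m > 0:
        n_pos = int((c.r[np.triu_indices(n, 1)] > 0).sum())
        if m > n_pos:
            logger.warning(
                "density %.3f requires %d edges but only %d positive "
                "correlations exist; admitting non-positive edges",
                density, m, n_pos,
            )
    a = np.zeros((n, n), dtype=np.int8)
    a[pairs[:, 0], pairs[:, 1]] = 1
    a[pairs[:, 1], pairs[:, 0]] = 1
    return AdjacencyMatrix(region_labels=list(c.region_labels), a=a,
                           density=density)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj
            self.n_components -= 1


def minimum_connected_density(
    c: CovarianceMatrix, resolution: float = 0.01
) -> float:
    """Smallest grid density at which the binarized network is one component.

    Edges are admitted in ranked order until the graph connects (union-find);
    the answer is the smallest multiple of ``resolution`` whose rounded edge
    count reaches that point.  Resolution 0.01 matches the two-decimal
    convention for reporting D_min.
    """
    n = c.n_regions
    if n < 2:
        raise ValidationError("need at least 2 regions")
    pairs = ranked_pairs(c)
    uf = _UnionFind(n)
    m_connect = len(pairs)
    for m, (i, j) in enumerate(pairs, start=1):
        uf.union(int(i), int(j))
        if uf.n_components == 1:
            m_connect = m
            break
    p = n * (n - 1) // 2
    k = 1
    while True:
        d = round(k * resolution, 10)
        if round_half_away(d * p) >= m_connect or d >= 1.0:
            return min(d, 1.0)
        k += 1


def build_density_grid(
    d_min_a: float,
    d_min_b: float,
    step: float = 0.05,
    upper: float = 0.5,
    group_labels: tuple[str, str] = ("a", "b"),
) -> DensityGrid:
    """Density grid for a pairwise contrast, anchored at max(D_min_a, D_min_b)."""
    for d in (d_min_a, d_min_b):
        if not (0 < d <= upper):
            raise ValidationError(
                f"D_min {d} outside (0, {upper}]: grid would be empty"
            )
    lower = max(d_min_a, d_min_b)
    return DensityGrid(
        d_min_per_group={group_labels[0]: d_min_a, group_labels[1]: d_min_b},
        lower=lower,
        step=step,
        upper=upper,
    )
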