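"""Locus x ratio p-gain matrix construction, normalization and clustering,
plus effect-profile comparison utilities."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateColumnError, ValidationError
from .pgain import PGainRecord, ThresholdSet

STAGE_RAW_PGAIN = "raw"
STAGE_NORMALIZED = "normalized"


@dataclass
class LocusRatioMatrix:
    """Lead-ratio rows x locus columns of (normalized) log10 p-gains.

    Cells absent from the association run are 0 (no evidence); at the
    normalized stage every column maximum is 1.
    """

    data: pd.DataFrame
    stage: str = STAGE_RAW_PGAIN

    @property
    def n_ratios(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]


def build_pgain_matrix(records: list[PGainRecord], thresholds: ThresholdSet) -> LocusRatioMatrix:
    """Matrix of log10 p-gains over per-locus lead ratios.

    Columns are the loci (variants) with at least one pgain-significant
    record; rows are the union of those loci's lead ratios (the
    maximal-log10_pgain significant record per locus); cells hold the
    log10 p-gain of that (ratio, locus) pair, 0 where not computed.
    """
    by_locus: dict[str, list[PGainRecord]] = {}
    for r in records:
        by_locus.setdefault(r.variant, []).append(r)
    lead_ratio: dict[str, str] = {}
    for locus, recs in by_locus.items():
        sig = [r for r in recs if r.significant_pgain]
        if sig:
            best = max(sig, key=lambda r: (r.log10_pgain, r.test.label))
            lead_ratio[locus] = best.test.label
    if not lead_ratio:
        warnings.warn("no pgain-significant loci; returning empty matrix", stacklevel=2)
        return LocusRatioMatrix(pd.DataFrame())
    loci = sorted(lead_ratio)
    rows = sorted(set(lead_ratio.values()))
    mat = pd.DataFrame(0.0, index=rows, columns=loci)
    for locus in loci:
        for r in by_locus[locus]:
            if r.test.label in mat.index:
                mat.loc[r.test.label, locus] = r.log10_pgain
    return LocusRatioMatrix(mat, STAGE_RAW_PGAIN)


def normalize_per_locus(matrix: LocusRatioMatrix) -> LocusRatioMatrix:
    """Divide every locus column by its own maximum log10 p-gain.

    Columns with a non-positive maximum carry no usable evidence and are
    dropped with a warning.  Idempotent: normalizing twice equals once.
    """
    if matrix.stage == STAGE_NORMALIZED:
        return LocusRatioMatrix(matrix.data.copy(), STAGE_NORMALIZED)
    data = matrix.data.copy()
    maxima = data.max(axis=0)
    bad = maxima[maxima <= 0].index.tolist()
    if bad:
        warnings.warn(f"dropping loci with non-positive column maximum: {bad}", stacklevel=2)
        data = data.drop(columns=bad)
        maxima = maxima.drop(bad)
    return LocusRatioMatrix(data / maxima, STAGE_NORMALIZED)


@dataclass
class ClusterResult:
    """Row/column leaf orders and merge trees from agglomerative clustering."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def newick(self, axis: str = "rows") -> str:
        linkage = self.row_linkage if axis == "rows" else self.col_linkage
        labels = self.row_labels if axis == "rows" else self.col_labels
        if linkage is None:
            raise ValidationError(f"no merge tree for axis {axis!r}")
        tree = hierarchy.to_tree(linkage)

        def rec(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hierarchical_cluster(
    matrix: LocusRatioMatrix,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster rows and columns independently; deterministic given inputs.

    Fewer than 2 rows or columns on an axis yields the identity ordering
    with a warning for that axis.
    """
    if matrix.stage != STAGE_NORMALIZED:
        raise ValidationError("hierarchical_cluster expects a normalized matrix")
    data = matrix.data
    res = ClusterResult(
        row_order=list(range(data.shape[0])),
        col_order=list(range(data.shape[1])),
        row_linkage=None,
        col_linkage=None,
        row_labels=[str(i) for i in data.index],
        col_labels=[str(c) for c in data.columns],
    )
    if data.shape[0] >= 2:
        res.row_linkage = hierarchy.linkage(pdist(data.to_numpy(), metric=metric), method=linkage)
        res.row_order = hierarchy.leaves_list(res.row_linkage).tolist()
    else:
        warnings.warn("fewer than 2 rows; identity row order", stacklevel=2)
    if data.shape[1] >= 2:
        res.col_linkage = hierarchy.linkage(pdist(data.to_numpy().T, metric=metric), method=linkage)
        res.col_order = hierarchy.leaves_list(res.col_linkage).tolist()
    else:
        warnings.warn("fewer than 2 columns; identity column order", stacklevel=2)
    return res


@dataclass
class EffectProfile:
    """Per-trait effect sizes for one entity (variant or exposure)."""

    entity: str
    traits: list[str]
    beta: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.beta.shape:
                raise ValidationError("beta and se lengths differ")
        if len(self.traits) != self.beta.shape[0]:
            raise ValidationError("traits and beta lengths differ")


def compare_effect_profiles(a: EffectProfile, b: EffectProfile):
    """Pearson correlation of two beta vectors over a shared trait order.

    Returns ``(r, r_squared, paired_table)``; the table is suitable for
    scatter export.
    """
    if a.traits != b.traits:
        raise ValidationError("profiles must share the same trait order")
    if len(a.traits) < 3:
        raise ValidationError("need >= 3 shared traits")
    x, y = a.beta, b.beta
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateColumnError("constant beta vector in compare_effect_profiles")
    r = float(np.corrcoef(x, y)[0, 1])
    table = pd.DataFrame({"trait": a.traits, a.entity: x, b.entity: y})
    return r, r * r, table


def directionality_panel(betas: pd.DataFrame, reference: str):
    """Re-sign per-class effects relative to each variant's reference-class sign.

    ``betas`` is variants x size-class columns; entries in the reference
    column become non-negative by construction.  Variants with a zero beta
    at the reference keep their raw signs and are flagged.
    """
    if reference not in betas.columns:
        raise ValidationError(f"reference class {reference!r} missing from panel")
    signs = np.sign(betas[reference].to_numpy())
    flagged = [str(i) for i, s in zip(betas.index, signs) if s == 0]
    signs = np.where(signs == 0, 1.0, signs)
    out = betas.mul(signs, axis=0)
    return out, flagged
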