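"""Trait-panel preprocessing and ratio-phenotype construction.

The analysis phenotype for every test (single trait or trait ratio) is the
inverse-normal transform of the natural-log trait values; ratios are built
on the log scale as ``log A - log B`` so association statistics are
invariant to inverting numerator and denominator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import STAGE_INT, STAGE_LOG, STAGE_RAW, TraitMatrix
from .errors import DataError, DegenerateColumnError, ValidationError

log = logging.getLogger(__name__)

#: Blom offset for the rank-based inverse-normal transform.
BLOM_OFFSET = 3.0 / 8.0

_INT_OFFSETS = {"blom": 3.0 / 8.0, "tukey": 1.0 / 3.0, "vanderwaerden": 0.0}


@dataclass(frozen=True, order=True)
class TestId:
    """Identifier of one association test: a single trait or a trait ratio.

    Ratios are canonically oriented: ``trait_a`` precedes ``trait_b`` in
    panel order, and reported effect sizes refer to this orientation.
    """

    kind: str  # 'single' | 'ratio'
    trait_a: str
    trait_b: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "ratio"):
            raise ValidationError(f"unknown test kind {self.kind!r}")
        if self.kind == "single" and self.trait_b is not None:
            raise ValidationError("single test must not carry trait_b")
        if self.kind == "ratio":
            if self.trait_b is None:
                raise ValidationError("ratio test requires trait_b")
            if self.trait_a == self.trait_b:
                raise ValidationError(f"ratio of a trait with itself: {self.trait_a!r}")

    @property
    def label(self) -> str:
        return self.trait_a if self.kind == "single" else f"{self.trait_a}/{self.trait_b}"

    @staticmethod
    def single(trait: str) -> "TestId":
        return TestId("single", trait)

    @staticmethod
    def ratio(trait_a: str, trait_b: str) -> "TestId":
        return TestId("ratio", trait_a, trait_b)


def enumerate_tests(traits: int | Sequence[str]) -> list[TestId]:
    """All single-trait tests plus all unordered distinct trait pairs.

    ``traits`` may be a panel size (names are synthesised as ``T1..Tm``) or
    an ordered sequence of trait ids.  Returns ``m(m+1)/2`` tests in
    deterministic panel order: singles first, then pairs ``(i, j)`` with
    ``i < j``.
    """
    if isinstance(traits, (int, np.integer)):
        if traits < 1:
            raise ValidationError(f"n_traits must be >= 1, got {traits}")
        names = [f"T{i + 1}" for i in range(int(traits))]
    else:
        names = [str(t) for t in traits]
        if len(names) < 1:
            raise ValidationError("empty trait panel")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate trait ids in panel")
    tests = [TestId.single(t) for t in names]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            tests.append(TestId.ratio(names[i], names[j]))
    return tests


def zeros_to_missing(traits: TraitMatrix) -> TraitMatrix:
    """Convert exact-zero cells of a raw panel to missing.

    The number of converted cells is logged; all other cells are unchanged.
    """
    if traits.stage != STAGE_RAW:
        raise ValidationError(f"zeros_to_missing expects a raw panel, got stage {traits.stage!r}")
    data = traits.data.copy()
    zero_mask = data == 0.0
    n_converted = int(zero_mask.to_numpy().sum())
    data = data.mask(zero_mask)
    log.info("zeros_to_missing: converted %d zero cells to missing", n_converted)
    out = TraitMatrix(data, STAGE_RAW)
    out.n_zeros_converted = n_converted  # type: ignore[attr-defined]
    return out


def log_transform(traits: TraitMatrix) -> TraitMatrix:
    """Natural log of every non-missing cell; requires strictly positive values."""
    if traits.stage != STAGE_RAW:
        raise ValidationError(f"log_transform expects a raw panel, got stage {traits.stage!r}")
    values = traits.data.to_numpy()
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-positive value {values[i, j]!r} at sample {traits.data.index[i]!r}, "
            f"trait {traits.data.columns[j]!r}; run zeros_to_missing first"
        )
    with np.errstate(invalid="ignore"):
        logged = np.log(values)
    return TraitMatrix(pd.DataFrame(logged, index=traits.data.index, columns=traits.data.columns), STAGE_LOG)


def inverse_normal(values, offset: float | str = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal transform of one column.

    Ranks (ties averaged) are mapped through the normal quantile function
    as ``ndtri((r - c) / (n - 2c + 1))`` over the ``n`` non-missing
    entries; the default offset ``c = 3/8`` gives the Blom scores
    ``(r - 3/8)/(n + 1/4)``.  Missing entries are preserved.
    """
    if isinstance(offset, str):
        try:
            offset = _INT_OFFSETS[offset]
        except KeyError:
            raise ValidationError(f"unknown INT offset {offset!r}") from None
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise DegenerateColumnError(f"inverse_normal needs >= 3 non-missing values, got {n}")
    obs = x[mask]
    if np.all(obs == obs[0]):
        raise DegenerateColumnError("constant column cannot be inverse-normal transformed")
    ranks = rankdata(obs, method="average")
    out[mask] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def int_transform(traits: TraitMatrix, offset: float | str = BLOM_OFFSET) -> TraitMatrix:
    """Columnwise inverse-normal transform of a log-stage panel.

    Constant columns are dropped with a warning rather than aborting the
    panel; downstream code treats them as excluded.
    """
    if traits.stage != STAGE_LOG:
        raise ValidationError(f"int_transform expects a log panel, got stage {traits.stage!r}")
    cols = {}
    dropped = []
    for name in traits.data.columns:
        try:
            cols[name] = inverse_normal(traits.data[name].to_numpy(), offset)
        except DegenerateColumnError:
            dropped.append(name)
    if dropped:
        log.warning("int_transform: dropped degenerate columns %s", dropped)
    out = TraitMatrix(pd.DataFrame(cols, index=traits.data.index), STAGE_INT)
    out.dropped_columns = dropped  # type: ignore[attr-defined]
    return out


def make_ratio(log_traits: TraitMatrix, test: TestId) -> pd.Series:
    """Log-ratio vector ``log A - log B``; missing where either side is missing."""
    if log_traits.stage != STAGE_LOG:
        raise ValidationError(f"make_ratio expects a log panel, got stage {log_traits.stage!r}")
    if test.kind != "ratio":
        raise ValidationError("make_ratio requires a ratio TestId")
    for t in (test.trait_a, test.trait_b):
        if t not in log_traits.data.columns:
            raise ValidationError(f"unknown trait {t!r}")
    return log_traits.data[test.trait_a] - log_traits.data[test.trait_b]


def phenotype(log_traits: TraitMatrix, test: TestId, offset: float | str = BLOM_OFFSET) -> np.ndarray:
    """Final analysis phenotype: INT of a log trait or of a log ratio."""
    if log_traits.stage != STAGE_LOG:
        raise ValidationError(f"phenotype expects a log panel, got stage {log_traits.stage!r}")
    if test.kind == "single":
        if test.trait_a not in log_traits.data.columns:
            raise ValidationError(f"unknown trait {test.trait_a!r}")
        vec = log_traits.data[test.trait_a].to_numpy()
    else:
        vec = make_ratio(log_traits, test).to_numpy()
    return inverse_normal(vec, offset)
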