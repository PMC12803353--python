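"""Shared tabular containers.

Thin, validated wrappers around :class:`pandas.DataFrame` so that stage
information (raw / log / inverse-normal) travels with the trait panel and
per-variant allele-frequency metadata travels with the dosage table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

STAGE_RAW = "raw"
STAGE_LOG = "log"
STAGE_INT = "int"
_STAGES = (STAGE_RAW, STAGE_LOG, STAGE_INT)


@dataclass
class TraitMatrix:
    """Samples x traits panel with an explicit transformation stage.

    Missing values are ``NaN``.  ``stage`` is one of ``raw`` (positive
    concentrations, zeros allowed), ``log`` (natural log of non-missing
    cells) or ``int`` (inverse-normal scores).
    """

    data: pd.DataFrame
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def trait_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_traits(self) -> int:
        return self.data.shape[1]

    def copy(self, stage: str | None = None) -> "TraitMatrix":
        return TraitMatrix(self.data.copy(), self.stage if stage is None else stage)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage table with per-variant MAF metadata.

    ``maf`` holds the *empirical* alternate-allele frequency computed from
    the dosages (dosage mean / 2); callers needing the minor-allele
    frequency should fold at 0.5.
    """

    data: pd.DataFrame
    maf: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        if self.maf is None:
            self.maf = self.data.mean(axis=0, skipna=True) / 2.0
        self.maf = pd.Series(self.maf, index=self.data.columns, dtype=float)

    @property
    def variant_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def dosage(self, variant_id: str) -> np.ndarray:
        if variant_id not in self.data.columns:
            raise ValidationError(f"unknown variant {variant_id!r}")
        return self.data[variant_id].to_numpy()

    def minor_allele_frequency(self, variant_id: str) -> float:
        f = float(self.maf[variant_id])
        return min(f, 1.0 - f)
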