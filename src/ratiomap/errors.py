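"""Exception hierarchy.

Validation errors signal misuse of the API (bad parameters, wrong stage);
data errors signal defects in the input tables; degeneracy errors signal
columns/variants that cannot be analysed (constant vectors, perfect
collinearity) and are usually caught and converted to flagged results.
"""


class RatiomapError(Exception):
    """Base class for all package errors."""


class ValidationError(RatiomapError, ValueError):
    """A parameter or call violates a documented precondition."""


class DataError(RatiomapError, ValueError):
    """An input table contains values the pipeline cannot process."""


class DegenerateColumnError(RatiomapError, ValueError):
    """A trait/phenotype column is constant or otherwise untransformable."""


class DegenerateVariantError(RatiomapError, ValueError):
    """A dosage vector is constant on the analysis sample."""


class RankDeficiencyError(RatiomapError, ValueError):
    """The covariate design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design; suspect columns: {self.columns}")
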