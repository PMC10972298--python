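"""Feature-matrix preprocessing: normalization, transforms, confound removal.

Default chain is total-metabolome normalization (removes urine
dilution), natural-log transform with a half-minimum offset, pareto
scaling (mean-center, divide by sqrt of the sample sd), then OLS
residualization of age and sex.  The chain order is configurable; the
log/pareto order in particular is supported both ways since logging a
mean-centered matrix is undefined for negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    order: tuple[str, ...] = ("normalize", "log", "pareto")
    log_offset_policy: str = "half-minimum"  # or "fixed"
    log_epsilon: float = 0.0
    covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self) -> None:
        allowed = {"normalize", "log", "pareto"}
        if set(self.order) - allowed:
            raise ValueError(f"unknown steps: {set(self.order) - allowed}")
        if len(set(self.order)) != len(self.order):
            raise ValueError("each step may appear at most once")
        if "normalize" in self.order and self.order[0] != "normalize":
            raise ValueError("normalize must precede scaling steps")


def _rewrap(matrix: FeatureMatrix, values: pd.DataFrame) -> FeatureMatrix:
    return FeatureMatrix(values=values, bins=matrix.bins)


def normalize_total(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample's row by its total over the (non-excluded) bins."""
    sums = matrix.values.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum rows for samples: {list(zero.index)}")
    return _rewrap(matrix, matrix.values.div(sums, axis=0))


def log_transform(matrix: FeatureMatrix, policy: str = "half-minimum",
                  epsilon: float = 0.0) -> FeatureMatrix:
    """Natural log with offset: value -> ln(value + delta).

    delta is half the smallest positive value in the matrix
    (``half-minimum``, the default) or a fixed ``epsilon``.
    """
    vals = matrix.values.to_numpy()
    if np.any(vals < 0):
        raise ValueError("log transform requires non-negative values")
    if policy == "half-minimum":
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError("all-zero matrix: half-minimum offset undefined")
        delta = float(positive.min()) / 2.0
    elif policy == "fixed":
        delta = epsilon
        if np.any(vals + delta <= 0):
            raise ValueError("fixed offset leaves non-positive values")
    else:
        raise ValueError(f"unknown log offset policy: {policy}")
    return _rewrap(matrix, np.log(matrix.values + delta))


def pareto_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per column: subtract the mean, divide by sqrt(sample sd, n-1 denominator).

    Constant columns map to all zeros (logged) rather than dividing by
    zero.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("pareto scaling needs >= 2 samples")
    centered = matrix.values - matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("pareto: %d constant columns set to zero", int(constant.sum()))
    scale = np.sqrt(sd.where(~constant, 1.0))
    out = centered.div(scale, axis=1)
    out.loc[:, constant] = 0.0
    return _rewrap(matrix, out)


def residualize_confounds(
    matrix: FeatureMatrix,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
) -> FeatureMatrix:
    """Replace each column by its OLS residual on [intercept, covariates].

    Removes additive confounding (e.g. age, sex) from every feature at
    once via one least-squares solve; idempotent, and leaves columns
    orthogonal to the covariates unchanged.
    """
    meta = metadata.reindex(matrix.values.index)
    missing = meta[list(covariates)].isna().any()
    if missing.any():
        raise ValueError(f"missing covariate values: {list(missing[missing].index)}")
    X = np.column_stack(
        [np.ones(len(meta))] + [meta[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design (e.g. a constant covariate); drop the offending covariate"
        )
    Y = matrix.values.to_numpy()
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return _rewrap(matrix, pd.DataFrame(resid, index=matrix.values.index,
                                        columns=matrix.values.columns))


def preprocess_chain(
    matrix: FeatureMatrix,
    metadata: pd.DataFrame | None = None,
    config: PreprocessConfig | None = None,
) -> FeatureMatrix:
    """Apply the configured steps in order, then residualize if covariates given."""
    config = config or PreprocessConfig()
    out = matrix
    for step in config.order:
        if step == "normalize":
            out = normalize_total(out)
        elif step == "log":
            out = log_transform(out, config.log_offset_policy, config.log_epsilon)
        elif step == "pareto":
            out = pareto_scale(out)
    if config.covariates and metadata is not None:
        out = residualize_confounds(out, metadata, config.covariates)
    return out
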