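"""Shared covariate encoding for the regression models and the generator.

Fixed reference levels keep coefficients reproducible across runs and make
the generator's planted linear predictors and the fitted models agree on the
meaning of every column: male, White, Northeast, and flag-absent are the
references.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORY_LEVELS: Mapping[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "race": ("White", "Black", "Asian", "Other", "Unknown"),
    "region": ("Northeast", "Midwest", "South", "West", "Other"),
}

PSYCHIATRIC_FLAGS = ("anxiety", "bipolar", "depression", "panic", "ptsd", "substance_use")

#: the adjusted-model covariate set: sociodemographics plus clinical history
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age", "gender", "race", "region", "cci",
) + PSYCHIATRIC_FLAGS


class DesignError(ValueError):
    """The design matrix cannot be built as requested."""


def encode_design(
    data: pd.DataFrame,
    exposure: str = "ns",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    drop_empty: bool = True,
    require_full_rank: bool = True,
) -> pd.DataFrame:
    """Intercept + exposure + encoded covariates, as a float DataFrame.

    Categoricals expand to treatment-coded dummies against the fixed
    reference level; binary flags coerce to 0/1; continuous columns pass
    through.  All-zero dummy columns (categories absent from the data) are
    dropped when ``drop_empty`` so the matrix stays full rank.
    """
    if exposure in covariates:
        raise DesignError("exposure must not be duplicated among covariates")
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    if exposure not in data.columns:
        raise DesignError(f"missing exposure column {exposure!r}")
    cols[exposure] = data[exposure].astype(float).to_numpy()
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[cov]
            values = data[cov].astype(str)
            unknown = set(values) - set(levels)
            if unknown:
                raise DesignError(f"unknown {cov} level(s): {sorted(unknown)}")
            for level in levels[1:]:  # first level is the reference
                col = (values == level).astype(float).to_numpy()
                if drop_empty and not col.any():
                    continue
                cols[f"{cov}_{level}"] = col
        else:
            if cov not in data.columns:
                raise DesignError(f"missing covariate column {cov!r}")
            cols[cov] = data[cov].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    if require_full_rank and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("design matrix is rank deficient after encoding")
    return X


def linear_predictor(data: pd.DataFrame, coefs: Mapping[str, float], exposure: str = "ns") -> np.ndarray:
    """Evaluate a named-coefficient linear predictor on a covariate frame.

    Coefficient names follow :func:`encode_design` columns; names absent from
    the frame's encoding contribute nothing, covariates without a named
    coefficient get 0.  Used by the synthetic generator to plant effects.
    """
    X = encode_design(
        data, exposure=exposure, drop_empty=False, require_full_rank=False
    )
    lp = np.zeros(len(data))
    for name, value in coefs.items():
        if name not in X.columns:
            raise DesignError(f"coefficient {name!r} matches no design column")
        lp += value * X[name].to_numpy()
    return lp
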