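"""Lande–Arnold selection-gradient estimation.

Directional selection gradients β_i are the partial regression
coefficients of relative fitness w (individual fitness divided by the
group mean) on traits standardized to mean 0 and sample variance 1
*within* each population x morph x treatment stratum. Standardizing and
relativizing within the stratum makes gradients comparable across
strata with very different trait scales and fitness levels, and puts β
in units of relative fitness change per trait standard deviation.

Correlational (cross-product) terms γ_ij can be appended to probe
selection on trait combinations; variance inflation factors (VIFs)
diagnose the multicollinearity that such terms typically introduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTraitError,
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)
from .study import TRAITS, GroupKey, StudyTable

#: smallest stratum admitted to a gradient fit
MIN_GROUP_SIZE = 8

_RANK_TOL = 1e-10


@dataclass
class LinearFit:
    """Ordinary least-squares fit summary.

    ``params`` are ordered as ``names`` (intercept first when present);
    p-values are two-sided from the t distribution on ``df_resid``.
    """

    names: list[str]
    params: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    df_resid: int
    r2: float
    nobs: int

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "t": self.t, "p": self.p},
            index=self.names,
        )


@dataclass
class StandardizedDesign:
    """Within-stratum standardized traits and relative fitness."""

    group: GroupKey
    z: pd.DataFrame          # columns = trait names, mean 0, sample var 1
    w: np.ndarray            # relative fitness, mean 1
    trait_names: tuple[str, ...] = field(default=TRAITS)


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
) -> LinearFit:
    """Least-squares fit of ``y`` on ``X`` via QR decomposition.

    Standard errors come from the residual variance (RSS / residual df)
    times the diagonal of (X'X)^{-1}. Raises
    :class:`~pollsel.errors.SingularDesignError` on rank deficiency and
    :class:`~pollsel.errors.InsufficientDataError` when there are no
    residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) > 1:
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
        p += 1
    if len(y) != n:
        raise ValidationError("response and design have different lengths")
    if n <= p:
        raise InsufficientDataError(f"n={n} rows for p={p} parameters")
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_TOL * max(diag.max(), 1.0):
        j = int(np.argmin(diag))
        raise SingularDesignError(f"design is rank deficient (column {names[j]!r} aliased)")
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - p
    r_inv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.sum(r_inv * r_inv, axis=1)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    if add_intercept or np.allclose(X @ np.linalg.lstsq(X, np.ones(n), rcond=None)[0], 1.0):
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)
    r2 = 0.0 if tss <= 0 else float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    return LinearFit(names, coef, se, t, pvals, rss, df, r2, n)


def standardize_group(records: pd.DataFrame, traits: Sequence[str] = TRAITS) -> StandardizedDesign:
    """Standardize traits and relativize fitness within one stratum.

    z-scores use the sample (n−1) standard deviation; relative fitness
    is individual female fitness over the stratum mean. The input frame
    is not modified.
    """
    traits = tuple(traits)
    n = len(records)
    if n < len(traits) + 2:
        raise InsufficientDataError(f"{n} records for {len(traits)} traits")
    key = GroupKey(
        str(records["population"].iloc[0]),
        str(records["morph"].iloc[0]),
        str(records["treatment"].iloc[0]),
    )
    z = {}
    for trait in traits:
        x = records[trait].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise DegenerateTraitError(f"trait {trait!r} has zero variance in group {key}")
        z[trait] = (x - x.mean()) / sd
    fitness = records["female_fitness"].to_numpy(dtype=float)
    mean_w = fitness.mean()
    if mean_w <= 0:
        raise DegenerateTraitError(f"group {key} has zero mean fitness")
    return StandardizedDesign(key, pd.DataFrame(z), fitness / mean_w, traits)


def vif(z: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 − R²_j).

    R²_j is from regressing column j on the remaining columns with an
    intercept. Perfectly collinear columns get ``inf`` rather than an
    exception. Columns whose VIF exceeds 10 signal multicollinearity
    severe enough to drop the offending terms.
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if p < 2:
        raise ValidationError("VIF needs at least two columns")
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} rows for {p} columns")
    out = np.empty(p)
    for j in range(p):
        others = np.delete(z, j, axis=1)
        try:
            f = fit_ols(z[:, j], others, add_intercept=True)
            r2 = f.r2
        except SingularDesignError:
            r2 = 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _cross_product_design(z: pd.DataFrame) -> pd.DataFrame:
    """Append all pairwise products z_i * z_j of standardized traits."""
    out = z.copy()
    for a, b in combinations(z.columns, 2):
        out[f"{a}:{b}"] = z[a] * z[b]
    return out


def estimate_gradients(
    table: StudyTable,
    traits: Sequence[str] = TRAITS,
    include_cross_products: bool = False,
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """Estimate directional selection gradients for every stratum.

    For each population x morph x treatment group, fits relative
    fitness on the within-group standardized traits by multiple linear
    regression. With ``include_cross_products`` the ten pairwise
    products of standardized traits (correlational terms γ_ij) are
    appended as additional predictors.

    Returns a tidy frame with one row per (group, predictor):
    ``population, morph, treatment, trait, n, beta, se, t, p, vif``.
    """
    rows = []
    for key, records in table.iter_groups(with_treatment=True):
        if len(records) < min_group_size:
            raise InsufficientDataError(
                f"group {key} has {len(records)} records (< {min_group_size})"
            )
        try:
            design = standardize_group(records, traits)
            z = _cross_product_design(design.z) if include_cross_products else design.z
            fit = fit_ols(design.w, z.to_numpy(), names=list(z.columns))
            vifs = vif(z.to_numpy())
        except (DegenerateTraitError, SingularDesignError, InsufficientDataError) as exc:
            raise type(exc)(f"group {key}: {exc}") from exc
        for j, name in enumerate(z.columns):
            rows.append(
                {
                    "population": key.population,
                    "morph": key.morph,
                    "treatment": key.treatment,
                    "trait": name,
                    "n": len(records),
                    "beta": fit.params[j + 1],
                    "se": fit.se[j + 1],
                    "t": fit.t[j + 1],
                    "p": fit.p[j + 1],
                    "vif": vifs[j],
                }
            )
    return pd.DataFrame(rows)
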