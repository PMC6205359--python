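"""ANCOVA contrasts for spatial and morph variation in selection.

Two pooled analyses of covariance ask whether trait–fitness slopes
differ across design factors:

* **Model A** (open-pollination data only): relative fitness on the five
  standardized traits, population, morph, and the trait x population,
  trait x morph and trait x population x morph interactions. A
  significant trait x factor block means net directional selection on
  that trait varies across that factor.
* **Model B** (both treatments): Model A's terms plus pollination and
  every pollination interaction up to trait x population x morph x
  pollination. Significant trait x ... x pollination blocks mean the
  *pollinator-mediated* component of selection varies.

Pollinator-mediated selection itself is quantified per population and
morph as Δβ_poll = β_C − β_HP: the gradient under open pollination
minus the gradient when pollen receipt is saturated by hand. With
within-arm standardization this subtraction is algebraically identical
to the trait x pollination coefficient of a fully treatment-interacted
model, which also supplies its significance test.

Block tests are nested-model F tests. The default is marginal
(drop-one-block against the full model, Type-III-like), because each
interaction is interpreted in the presence of all the others;
sequential (Type-I) testing is available via ``test_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GroupError, ValidationError
from .gradients import LinearFit, fit_ols, standardize_group
from .study import TRAITS, GroupKey, StudyTable

Term = tuple[str, ...]


@dataclass
class ModelSpec:
    """Declarative linear-model layout.

    ``factors`` maps factor name to its ordered levels (first level is
    the reference); ``covariates`` are numeric columns used as is;
    ``blocks`` maps a block label to the list of terms it comprises,
    each term a tuple of factor/covariate names whose columns are
    multiplied elementwise.
    """

    response: str
    covariates: list[str]
    factors: dict[str, list[str]]
    blocks: dict[str, list[Term]] = field(default_factory=dict)

    def validate(self, df: pd.DataFrame) -> None:
        for c in [self.response, *self.covariates]:
            if c not in df.columns:
                raise ValidationError(f"column {c!r} not in data")
        for f in self.factors:
            if f not in df.columns:
                raise ValidationError(f"factor {f!r} not in data")
        declared = set(self.covariates) | set(self.factors)
        for label, terms in self.blocks.items():
            for term in terms:
                for name in term:
                    if name not in declared:
                        raise ValidationError(
                            f"block {label!r} references undeclared term {name!r}"
                        )


@dataclass
class AnovaResult:
    """Per-block F tests plus the full model they are computed against."""

    table: pd.DataFrame          # term, df_num, df_den, F, p
    rss: float
    df_resid: int
    nobs: int
    fit: LinearFit

    def row(self, term: str) -> pd.Series:
        match = self.table[self.table["term"] == term]
        if len(match) != 1:
            raise KeyError(f"term {term!r} not found")
        return match.iloc[0]


def _expand(
    df: pd.DataFrame, term: Term, factors: Mapping[str, Sequence[str]]
) -> tuple[list[np.ndarray], list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[str] = [""]
    for name in term:
        if name in factors:
            levels = list(factors[name])
            parts = [
                ((df[name] == lv).to_numpy(dtype=float), f"{name}[{lv}]")
                for lv in levels[1:]
            ]
        else:
            parts = [(df[name].to_numpy(dtype=float), name)]
        cols = [c * pc for c in cols for pc, _ in parts]
        labels = [
            (f"{lab}:{pl}" if lab else pl) for lab in labels for _, pl in parts
        ]
    return cols, labels


def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Build the treatment-coded design matrix for ``spec``.

    Returns the matrix (intercept first), deterministic column labels,
    and a map from block label to the column indices it owns. Factor
    levels declared but absent from the data are dropped with a log
    message; the reference level is each factor's first declared level.
    """
    spec.validate(df)
    factors: dict[str, list[str]] = {}
    for name, levels in spec.factors.items():
        present = [lv for lv in levels if (df[name] == lv).any()]
        if len(present) < len(levels):
            import logging

            logging.getLogger("pollsel").info(
                "build_design: dropping unused levels of %s", name
            )
        if len(present) < 1:
            raise ValidationError(f"factor {name!r} has no observed levels")
        factors[name] = present
    X_cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[str] = ["intercept"]
    block_index: dict[str, list[int]] = {}
    for label, terms in spec.blocks.items():
        idx = []
        for term in terms:
            cols, labs = _expand(df, term, factors)
            for c, lab in zip(cols, labs):
                idx.append(len(labels))
                X_cols.append(c)
                labels.append(lab)
        block_index[label] = idx
    return np.column_stack(X_cols), labels, block_index


def test_block(full: LinearFit, reduced: LinearFit) -> pd.Series:
    """Nested-model F test of the columns present in ``full`` only.

    F = ((RSS_r − RSS_f) / (df_r − df_f)) / (RSS_f / df_f), with the
    p-value from the F distribution. The reduced model must be nested
    in the full one (same rows, strict column subset).
    """
    if reduced.nobs != full.nobs:
        raise ValidationError("full and reduced models fit different rows")
    df_num = reduced.df_resid - full.df_resid
    if df_num < 0 or not set(reduced.names) <= set(full.names):
        raise ValidationError("models are not nested")
    if df_num == 0:
        return pd.Series({"df_num": 0, "df_den": full.df_resid, "F": 0.0, "p": 1.0})
    extra = max(reduced.rss - full.rss, 0.0)
    scale = max(full.rss, reduced.rss, 1.0)
    if full.rss <= 1e-12 * scale:
        # saturated fit: the block explains nothing beyond a perfect model
        F = np.inf if extra > 1e-12 * scale else 0.0
    else:
        F = (extra / df_num) / (full.rss / full.df_resid)
    p = float(stats.f.sf(F, df_num, full.df_resid))
    return pd.Series({"df_num": df_num, "df_den": full.df_resid, "F": F, "p": p})


def _fit_design(y: np.ndarray, X: np.ndarray, labels: list[str]) -> LinearFit:
    return fit_ols(y, X, names=labels, add_intercept=False)


def _block_anova(
    y: np.ndarray,
    X: np.ndarray,
    labels: list[str],
    block_index: dict[str, list[int]],
    tested_blocks: Sequence[str],
    test_type: str = "marginal",
    extra_subblocks: Mapping[str, list[int]] | None = None,
) -> AnovaResult:
    full = _fit_design(y, X, labels)
    rows = []
    if test_type == "marginal":
        for label in tested_blocks:
            keep = [j for j in range(X.shape[1]) if j not in set(block_index[label])]
            reduced = _fit_design(y, X[:, keep], [labels[j] for j in keep])
            rows.append({"term": label, **test_block(full, reduced)})
    elif test_type == "sequential":
        order = list(block_index)
        prev_cols = [0]  # intercept
        prev = _fit_design(y, X[:, prev_cols], [labels[0]])
        for label in order:
            cols = prev_cols + block_index[label]
            cur = _fit_design(y, X[:, cols], [labels[j] for j in cols])
            df_num = prev.df_resid - cur.df_resid
            extra = max(prev.rss - cur.rss, 0.0)
            F = (extra / df_num) / (full.rss / full.df_resid) if df_num else 0.0
            p = float(stats.f.sf(F, df_num, full.df_resid)) if df_num else 1.0
            if label in tested_blocks:
                rows.append(
                    {"term": label, "df_num": df_num, "df_den": full.df_resid, "F": F, "p": p}
                )
            prev, prev_cols = cur, cols
    else:
        raise ValidationError(f"unknown test_type {test_type!r}")
    if extra_subblocks:
        for label, idx in extra_subblocks.items():
            keep = [j for j in range(X.shape[1]) if j not in set(idx)]
            reduced = _fit_design(y, X[:, keep], [labels[j] for j in keep])
            rows.append({"term": label, **test_block(full, reduced)})
    table = pd.DataFrame(rows)
    table[["df_num", "df_den"]] = table[["df_num", "df_den"]].astype(int)
    return AnovaResult(table, full.rss, full.df_resid, full.nobs, full)


def _ancova_frame(table: StudyTable, traits: Sequence[str]) -> pd.DataFrame:
    """Stack within-stratum standardized traits and relative fitness."""
    frames = []
    for key, records in table.iter_groups(with_treatment=True):
        design = standardize_group(records, traits)
        f = design.z.copy()
        f["relative_fitness"] = design.w
        f["population"] = key.population
        f["morph"] = key.morph
        f["pollination"] = key.treatment
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _model_spec(
    table: StudyTable, traits: Sequence[str], with_pollination: bool
) -> ModelSpec:
    traits = list(traits)
    factors = {
        "population": list(table.populations),
        "morph": list(table.morphs),
    }
    blocks: dict[str, list[Term]] = {
        "trait": [(t,) for t in traits],
        "population": [("population",)],
        "morph": [("morph",)],
    }
    if with_pollination:
        # HP is the reference level so pollination-interaction
        # coefficients read as (C minus HP), i.e. the pollinator-mediated part
        factors["pollination"] = ["HP", "C"]
        blocks["pollination"] = [("pollination",)]
    blocks["trait x population"] = [(t, "population") for t in traits]
    blocks["trait x morph"] = [(t, "morph") for t in traits]
    if with_pollination:
        blocks["trait x pollination"] = [(t, "pollination") for t in traits]
    blocks["trait x population x morph"] = [(t, "population", "morph") for t in traits]
    if with_pollination:
        blocks["trait x population x pollination"] = [
            (t, "population", "pollination") for t in traits
        ]
        blocks["trait x morph x pollination"] = [(t, "morph", "pollination") for t in traits]
        blocks["trait x population x morph x pollination"] = [
            (t, "population", "morph", "pollination") for t in traits
        ]
    return ModelSpec("relative_fitness", traits, factors, blocks)


def _per_trait_subblocks(
    spec: ModelSpec,
    df: pd.DataFrame,
    labels: list[str],
    block_index: dict[str, list[int]],
    traits: Sequence[str],
    interaction_blocks: Sequence[str],
) -> dict[str, list[int]]:
    sub: dict[str, list[int]] = {}
    for block in interaction_blocks:
        for trait in traits:
            idx = [j for j in block_index[block] if labels[j].startswith(f"{trait}:")]
            sub[f"{trait} {block.split(' ', 1)[1]}"] = idx
    return sub


def ancova_model_a(
    table: StudyTable, traits: Sequence[str] = TRAITS, test_type: str = "marginal"
) -> AnovaResult:
    """Pooled ANCOVA for variation in *net* directional selection.

    Runs on the open-pollination (C) records only. Alongside each
    interaction block, single-trait sub-blocks (e.g. one trait's
    trait x morph column) are tested against the full model, matching
    how per-trait F statistics are conventionally reported.
    """
    sub = table.subset_treatment("C") if set(table.df["treatment"]) != {"C"} else table
    if len(set(sub.df["population"])) < 2 or len(set(sub.df["morph"])) < 2:
        raise GroupError("Model A needs >=2 populations and both morphs under C")
    frame = _ancova_frame(sub, traits)
    spec = _model_spec(sub, traits, with_pollination=False)
    X, labels, block_index = build_design(frame, spec)
    y = frame["relative_fitness"].to_numpy()
    inter = ["trait x population", "trait x morph", "trait x population x morph"]
    extra = _per_trait_subblocks(spec, frame, labels, block_index, traits, inter)
    return _block_anova(y, X, labels, block_index, list(spec.blocks), test_type, extra)


def ancova_model_b(
    table: StudyTable, traits: Sequence[str] = TRAITS, test_type: str = "marginal"
) -> AnovaResult:
    """Pooled ANCOVA for variation in *pollinator-mediated* selection.

    Uses both treatment arms; adds pollination and all its trait
    interactions up to trait x population x morph x pollination.
    """
    cells = {(p, m, t) for p, m, t in zip(
        table.df["population"], table.df["morph"], table.df["treatment"]
    )}
    for pop in table.populations:
        for morph in table.morphs:
            for trt in table.treatments:
                if (pop, morph, trt) not in cells:
                    raise GroupError(f"missing treatment cell {pop}/{morph}/{trt}")
    frame = _ancova_frame(table, traits)
    spec = _model_spec(table, traits, with_pollination=True)
    X, labels, block_index = build_design(frame, spec)
    y = frame["relative_fitness"].to_numpy()
    inter = [
        "trait x population",
        "trait x morph",
        "trait x pollination",
        "trait x population x morph",
        "trait x population x pollination",
        "trait x morph x pollination",
        "trait x population x morph x pollination",
    ]
    extra = _per_trait_subblocks(spec, frame, labels, block_index, traits, inter)
    return _block_anova(y, X, labels, block_index, list(spec.blocks), test_type, extra)


def delta_beta(
    gradients: pd.DataFrame, table: StudyTable, traits: Sequence[str] = TRAITS
) -> pd.DataFrame:
    """Pollinator-mediated selection Δβ_poll = β_C − β_HP per stratum.

    The point value is the subtraction of the two gradient-table
    entries. Its p-value comes from the trait x pollination coefficient
    of a fully treatment-interacted model fit separately for each
    population x morph (with traits standardized and fitness
    relativized within each arm); that coefficient equals β_C − β_HP
    exactly, which is what licenses the two-step subtraction.

    Returns ``population, morph, trait, beta_C, beta_HP, delta_beta, p,
    n_C, n_HP``.
    """
    rows = []
    for key in table.group_keys(with_treatment=False):
        per_arm = {}
        for trt in ("C", "HP"):
            arm = table.group(GroupKey(key.population, key.morph, trt))
            if len(arm) == 0:
                raise GroupError(f"group {key} is missing treatment arm {trt}")
            per_arm[trt] = standardize_group(arm, traits)
        nC, nHP = len(per_arm["C"].w), len(per_arm["HP"].w)
        zC, zHP = per_arm["C"].z, per_arm["HP"].z
        frame = pd.concat([zHP, zC], ignore_index=True)
        frame["relative_fitness"] = np.concatenate([per_arm["HP"].w, per_arm["C"].w])
        frame["pollination"] = ["HP"] * nHP + ["C"] * nC
        spec = ModelSpec(
            "relative_fitness",
            list(traits),
            {"pollination": ["HP", "C"]},
            {
                "trait": [(t,) for t in traits],
                "pollination": [("pollination",)],
                "trait x pollination": [(t, "pollination") for t in traits],
            },
        )
        X, labels, _ = build_design(frame, spec)
        fit = fit_ols(frame["relative_fitness"].to_numpy(), X, names=labels, add_intercept=False)
        for trait in traits:
            sel = gradients[
                (gradients["population"] == key.population)
                & (gradients["morph"] == key.morph)
                & (gradients["trait"] == trait)
            ]
            bC = float(sel.loc[sel["treatment"] == "C", "beta"].iloc[0])
            bHP = float(sel.loc[sel["treatment"] == "HP", "beta"].iloc[0])
            j = labels.index(f"{trait}:pollination[C]")
            rows.append(
                {
                    "population": key.population,
                    "morph": key.morph,
                    "trait": trait,
                    "beta_C": bC,
                    "beta_HP": bHP,
                    "delta_beta": bC - bHP,
                    "interaction_coef": float(fit.params[j]),
                    "p": float(fit.p[j]),
                    "n_C": nC,
                    "n_HP": nHP,
                }
            )
    return pd.DataFrame(rows)


def factorial_anova(
    data: StudyTable | pd.DataFrame,
    response: str,
    factors: Sequence[str],
    log10_transform: bool = False,
    offset: float = 0.0,
    test_type: str = "marginal",
) -> AnovaResult:
    """Full-factorial ANOVA on a (possibly log10-transformed) response.

    Covers the descriptive analyses: multi-way tests of trait and
    fitness differences across population, morph and pollination, and
    the one-factor case (e.g. pollinator body/proboscis length between
    assemblages). With ``log10_transform`` the response must be strictly
    positive after adding ``offset``.
    """
    df = data.df if isinstance(data, StudyTable) else data
    if response not in df.columns:
        raise ValidationError(f"response {response!r} not in data")
    y = df[response].to_numpy(dtype=float) + offset
    if log10_transform:
        if (y <= 0).any():
            raise ValidationError(
                f"response {response!r} has values <= 0 after offset {offset}; "
                "pass a positive offset"
            )
        y = np.log10(y)
    levels = {f: list(dict.fromkeys(df[f].astype(str))) for f in factors}
    frame = df.copy()
    for f in factors:
        frame[f] = frame[f].astype(str)
    blocks: dict[str, list[Term]] = {}
    k = len(factors)
    for order in range(1, k + 1):
        from itertools import combinations

        for combo in combinations(factors, order):
            blocks[" x ".join(combo)] = [tuple(combo)]
    spec = ModelSpec(response, [], levels, blocks)
    frame["_y"] = y
    X, labels, block_index = build_design(frame, spec)
    return _block_anova(y, X, labels, block_index, list(blocks), test_type)


def proportion_explained(
    delta: pd.DataFrame, gradients: pd.DataFrame, ndigits: int = 1
) -> pd.DataFrame:
    """Percentage of net selection attributable to pollinators.

    100 x Δβ_poll / β_C per (population, morph, trait); undefined
    (NaN) where β_C = 0.
    """
    rows = []
    for _, r in delta.iterrows():
        bC = r["beta_C"]
        pct = np.nan if bC == 0 else round(100.0 * r["delta_beta"] / bC, ndigits)
        rows.append(
            {
                "population": r["population"],
                "morph": r["morph"],
                "trait": r["trait"],
                "percent_explained": pct,
            }
        )
    return pd.DataFrame(rows)
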