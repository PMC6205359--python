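"""Synthetic cohorts emulating a two-morph, two-treatment field study.

The generator reproduces the statistical structure the analysis
assumes: four populations (two bumblebee-dominated, PNP 1/2; two
syrphid-fly-dominated, BGTC 1/2) x two floral morphs (L/S) x two
pollination treatments (C = open, HP = supplemental hand pollination),
with ~80-100 individuals per cell. Per cell it draws the five floral
traits from a multivariate normal with the published group means and
SDs, then generates female fitness with a linear trait dependence on
the *within-cell standardized* trait scores z:

    E[W | z] = mu_W * (1 + sum_i beta_i z_i)

where mu_W is the cell's mean fitness — the hand-pollination mean for
HP cells and that mean scaled by (1 − PL) for open-pollination cells.
Because beta is defined on the same standardized scale the estimator
reports, ordinary least squares recovers the configured gradients
without unit bookkeeping, and the configured PL is the expected
open/hand fitness ratio deficit.

Fitness noise is multiplicative: W = E[W | z] * G with G a mean-1 gamma
variate whose coefficient of variation is ``fitness_noise_cv``. This
keeps fitness non-negative (seed counts cannot be negative), leaves the
conditional mean linear so gradient recovery stays unbiased, and gives
the right-skewed fitness distributions seen in real seed-set data. The
max(0, .) guard only engages when 1 + sum beta_i z_i itself goes
negative, which the configuration invariant makes vanishingly rare;
every clip is counted and reported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .study import TRAITS, GroupKey, StudyTable

POPULATIONS: tuple[str, ...] = ("BGTC1", "BGTC2", "PNP1", "PNP2")

# Published group trait summaries (mean, SD) per
# (population, morph, treatment, trait): flowering onset in Julian days,
# plant height in cm, flower number as a count, corolla tube length and
# width in mm.
_T = TRAITS
REFERENCE_TRAITS: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("BGTC1", "L", "C"): {_T[0]: (154.3, 1.3), _T[1]: (44.6, 7.3), _T[2]: (18.7, 6.3), _T[3]: (9.27, 0.64), _T[4]: (3.69, 0.23)},
    ("BGTC1", "L", "HP"): {_T[0]: (154.3, 1.6), _T[1]: (49.2, 7.9), _T[2]: (19.3, 7.3), _T[3]: (9.55, 0.57), _T[4]: (3.67, 0.30)},
    ("BGTC1", "S", "C"): {_T[0]: (154.2, 1.6), _T[1]: (45.6, 7.7), _T[2]: (18.5, 5.4), _T[3]: (10.23, 0.65), _T[4]: (3.02, 0.24)},
    ("BGTC1", "S", "HP"): {_T[0]: (154.1, 1.3), _T[1]: (44.3, 5.9), _T[2]: (20.5, 6.1), _T[3]: (10.03, 0.62), _T[4]: (3.05, 0.23)},
    ("BGTC2", "L", "C"): {_T[0]: (154.7, 1.9), _T[1]: (28.6, 5.4), _T[2]: (8.5, 2.5), _T[3]: (8.53, 1.07), _T[4]: (3.81, 0.42)},
    ("BGTC2", "L", "HP"): {_T[0]: (157.5, 5.0), _T[1]: (30.5, 5.1), _T[2]: (9.7, 4.0), _T[3]: (8.40, 0.93), _T[4]: (3.98, 0.43)},
    ("BGTC2", "S", "C"): {_T[0]: (154.0, 2.0), _T[1]: (29.0, 4.9), _T[2]: (9.2, 3.4), _T[3]: (9.36, 0.69), _T[4]: (3.25, 0.29)},
    ("BGTC2", "S", "HP"): {_T[0]: (155.1, 2.4), _T[1]: (29.6, 5.6), _T[2]: (8.4, 3.0), _T[3]: (8.94, 0.61), _T[4]: (3.06, 0.32)},
    ("PNP1", "L", "C"): {_T[0]: (158.4, 1.8), _T[1]: (34.6, 5.8), _T[2]: (14.8, 5.5), _T[3]: (10.04, 0.77), _T[4]: (3.51, 0.32)},
    ("PNP1", "L", "HP"): {_T[0]: (159.2, 1.6), _T[1]: (34.3, 7.2), _T[2]: (15.3, 4.2), _T[3]: (10.16, 0.60), _T[4]: (3.44, 0.33)},
    ("PNP1", "S", "C"): {_T[0]: (160.2, 1.5), _T[1]: (33.7, 7.0), _T[2]: (15.3, 7.1), _T[3]: (10.18, 0.59), _T[4]: (2.82, 0.25)},
    ("PNP1", "S", "HP"): {_T[0]: (157.8, 1.9), _T[1]: (35.6, 6.3), _T[2]: (14.7, 4.7), _T[3]: (10.02, 0.69), _T[4]: (2.85, 0.27)},
    ("PNP2", "L", "C"): {_T[0]: (161.2, 1.1), _T[1]: (28.0, 5.5), _T[2]: (13.9, 5.3), _T[3]: (9.92, 0.58), _T[4]: (3.31, 0.28)},
    ("PNP2", "L", "HP"): {_T[0]: (160.6, 1.3), _T[1]: (27.0, 6.1), _T[2]: (13.7, 4.8), _T[3]: (9.75, 0.70), _T[4]: (3.24, 0.28)},
    ("PNP2", "S", "C"): {_T[0]: (161.1, 1.3), _T[1]: (26.7, 6.5), _T[2]: (15.4, 6.0), _T[3]: (10.14, 3.15), _T[4]: (2.88, 0.30)},
    ("PNP2", "S", "HP"): {_T[0]: (162.4, 2.6), _T[1]: (27.5, 7.9), _T[2]: (14.1, 5.1), _T[3]: (9.94, 0.58), _T[4]: (2.84, 0.26)},
}

#: realized cell sizes (plants surviving to harvest out of 100 marked)
REFERENCE_N: dict[tuple[str, str, str], int] = {
    ("BGTC1", "L", "C"): 100, ("BGTC2", "L", "C"): 98, ("PNP1", "L", "C"): 88, ("PNP2", "L", "C"): 78,
    ("BGTC1", "L", "HP"): 97, ("BGTC2", "L", "HP"): 90, ("PNP1", "L", "HP"): 93, ("PNP2", "L", "HP"): 95,
    ("BGTC1", "S", "C"): 100, ("BGTC2", "S", "C"): 91, ("PNP1", "S", "C"): 96, ("PNP2", "S", "C"): 88,
    ("BGTC1", "S", "HP"): 97, ("BGTC2", "S", "HP"): 91, ("PNP1", "S", "HP"): 94, ("PNP2", "S", "HP"): 89,
}

# Published female reproductive performance per (population, morph):
# mean (SD) fruit production, mean female fitness (total seeds) under
# open (C) and hand (HP) pollination. The pollen-limitation index is
# derived from the two fitness means, never stored.
REFERENCE_PERFORMANCE: dict[tuple[str, str], dict[str, float]] = {
    ("BGTC1", "L"): {"fruit_C": 7.1, "fruit_HP": 15.4, "fitness_C": 569.1, "fitness_C_sd": 412.0, "fitness_HP": 1701.2, "fitness_HP_sd": 884.8},
    ("BGTC2", "L"): {"fruit_C": 3.5, "fruit_HP": 6.9, "fitness_C": 192.5, "fitness_C_sd": 124.0, "fitness_HP": 512.6, "fitness_HP_sd": 324.8},
    ("PNP1", "L"): {"fruit_C": 9.3, "fruit_HP": 11.7, "fitness_C": 905.9, "fitness_C_sd": 480.9, "fitness_HP": 1320.2, "fitness_HP_sd": 695.1},
    ("PNP2", "L"): {"fruit_C": 8.2, "fruit_HP": 10.3, "fitness_C": 857.6, "fitness_C_sd": 472.5, "fitness_HP": 1226.8, "fitness_HP_sd": 619.6},
    ("BGTC1", "S"): {"fruit_C": 7.4, "fruit_HP": 15.8, "fitness_C": 539.9, "fitness_C_sd": 453.2, "fitness_HP": 1793.3, "fitness_HP_sd": 691.2},
    ("BGTC2", "S"): {"fruit_C": 2.7, "fruit_HP": 5.7, "fitness_C": 121.1, "fitness_C_sd": 103.8, "fitness_HP": 367.3, "fitness_HP_sd": 243.2},
    ("PNP1", "S"): {"fruit_C": 9.2, "fruit_HP": 10.6, "fitness_C": 821.0, "fitness_C_sd": 553.2, "fitness_HP": 1198.6, "fitness_HP_sd": 693.3},
    ("PNP2", "S"): {"fruit_C": 8.9, "fruit_HP": 11.1, "fitness_C": 918.0, "fitness_C_sd": 574.7, "fitness_HP": 1241.7, "fitness_HP_sd": 642.9},
}

# Default selection scenario on the standardized scale, per
# (population, morph): beta_C encodes the net directional gradients —
# flower number favoured everywhere, wider corolla tubes favoured
# everywhere, shorter tubes favoured in L-morph plants of the
# syrphid-fly populations, later onset in S-morph BGTC2 — and delta
# (= beta_C − beta_HP) encodes where that selection is
# pollinator-mediated: tube-length selection confined to L-morph BGTC
# cells, tube-width contrasts in every population, flower-number
# contrasts of mixed sign.
# trait order: onset, height, n_flowers, tube length, tube width
_BETA_C: dict[tuple[str, str], tuple[float, ...]] = {
    ("BGTC1", "L"): (0.0, 0.0, 0.20, -0.123, 0.20),
    ("BGTC2", "L"): (0.0, 0.0, 0.20, -0.167, 0.23),
    ("PNP1", "L"): (0.12, 0.0, 0.20, 0.0, 0.15),
    ("PNP2", "L"): (0.0, 0.0, 0.20, 0.0, 0.18),
    ("BGTC1", "S"): (0.0, 0.0, 0.20, 0.0, 0.17),
    ("BGTC2", "S"): (0.222, 0.0, 0.20, 0.0, 0.174),
    ("PNP1", "S"): (0.0, 0.0, 0.20, 0.0, 0.15),
    ("PNP2", "S"): (0.0, 0.0, 0.20, 0.0, 0.16),
}
_DELTA: dict[tuple[str, str], tuple[float, ...]] = {
    ("BGTC1", "L"): (0.0, 0.0, -0.12, -0.108, 0.13),
    ("BGTC2", "L"): (0.0, 0.0, 0.0, -0.25, 0.146),
    ("PNP1", "L"): (0.0, 0.0, 0.12, 0.0, 0.112),
    ("PNP2", "L"): (0.0, 0.0, 0.0, 0.0, 0.13),
    ("BGTC1", "S"): (0.0, 0.0, 0.0, 0.0, 0.13),
    ("BGTC2", "S"): (0.173, 0.0, 0.0, 0.0, 0.146),
    ("PNP1", "S"): (0.0, 0.0, 0.146, 0.0, 0.114),
    ("PNP2", "S"): (0.0, 0.0, 0.0, 0.0, 0.126),
}


def default_trait_correlation() -> np.ndarray:
    """Mild trait correlation: tube length-width 0.2, height-flowers 0.3.

    Weak enough that all linear-term VIFs stay below 1.7.
    """
    corr = np.eye(5)
    corr[3, 4] = corr[4, 3] = 0.2
    corr[1, 2] = corr[2, 1] = 0.3
    return corr


@dataclass
class GroupSimParams:
    """Generator parameters for one population x morph x treatment cell."""

    n: int
    trait_means: np.ndarray
    trait_sds: np.ndarray
    trait_corr: np.ndarray
    mean_fitness_HP: float
    pl: float
    beta_C: np.ndarray
    beta_HP: np.ndarray
    fitness_noise_cv: float = 0.5
    fruit_set: float = 0.5

    def __post_init__(self):
        for name in ("trait_means", "trait_sds", "trait_corr", "beta_C", "beta_HP"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be positive")
        if (self.trait_sds <= 0).any() or (self.trait_means <= 0).any():
            raise ValidationError("trait means and SDs must be positive")
        c = self.trait_corr
        if c.shape != (5, 5) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ValidationError("trait_corr must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("trait_corr is not positive definite") from exc
        if not 0 <= self.pl < 1:
            raise ValidationError("pl must be in [0, 1)")
        if self.mean_fitness_HP <= 0:
            raise ValidationError("mean_fitness_HP must be positive")
        from scipy.stats import norm

        for beta in (self.beta_C, self.beta_HP):
            # sd of the combined linear predictor sum_i beta_i z_i;
            # cap the chance of a negative expected fitness (clipped
            # individual) at 1% per draw
            sd_lin = float(np.sqrt(beta @ c @ beta))
            if sd_lin > 0 and norm.cdf(-1.0 / sd_lin) > 0.01:
                raise ValidationError(
                    "gradients too steep: >1% of individuals would have a "
                    "negative expected fitness"
                )
        if self.fitness_noise_cv < 0:
            raise ValidationError("fitness_noise_cv must be >= 0")
        if not 0 < self.fruit_set <= 1:
            raise ValidationError("fruit_set must be in (0, 1]")


@dataclass
class SimConfig:
    """Full cohort scenario: one GroupSimParams per design cell."""

    cells: dict[GroupKey, GroupSimParams]
    seed: int = 0
    #: decimal places recorded per trait (0.1-day onset, 0.1-cm height,
    #: 0.01-mm caliper readings); flower number is always an integer count
    rounding: dict[str, int] = field(
        default_factory=lambda: {
            "flowering_onset": 1,
            "plant_height": 1,
            "corolla_tube_length": 2,
            "corolla_tube_width": 2,
        }
    )

    def validate(self) -> None:
        for key, params in self.cells.items():
            if key.treatment not in ("C", "HP"):
                raise ValidationError(f"cell {key} lacks a treatment")
            params.validate()

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        cells = {}
        for key, p in self.cells.items():
            d = asdict(p)
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    d[k] = v.tolist()
            cells[str(key)] = d
        return {"seed": self.seed, "rounding": dict(self.rounding), "cells": cells}

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        cells = {}
        for key_str, d in data["cells"].items():
            pop, morph, trt = key_str.split("/")
            cells[GroupKey(pop, morph, trt)] = GroupSimParams(**d)
        cfg = cls(cells, seed=int(data.get("seed", 0)))
        if data.get("rounding"):
            cfg.rounding = dict(data["rounding"])
        return cfg

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        if isinstance(path, (str,)) and "\n" in path:
            data = yaml.safe_load(io.StringIO(path))
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


def default_config(n: int | None = None, seed: int = 0) -> SimConfig:
    """The field-study-mirroring scenario.

    Trait moments, cell sizes, hand-pollination mean fitness and pollen
    limitation come from the published group summaries; the gradient
    scenario encodes the study's qualitative findings (see module
    docstring). ``n`` overrides every cell's sample size (e.g. 2000 for
    parameter-recovery checks).
    """
    cells: dict[GroupKey, GroupSimParams] = {}
    corr = default_trait_correlation()
    for pop in POPULATIONS:
        for morph in ("L", "S"):
            perf = REFERENCE_PERFORMANCE[(pop, morph)]
            pl = 1.0 - perf["fitness_C"] / perf["fitness_HP"]
            beta_C = np.array(_BETA_C[(pop, morph)])
            beta_HP = beta_C - np.array(_DELTA[(pop, morph)])
            for trt in ("C", "HP"):
                summaries = REFERENCE_TRAITS[(pop, morph, trt)]
                means = np.array([summaries[t][0] for t in TRAITS])
                sds = np.array([summaries[t][1] for t in TRAITS])
                fruit_set = min(
                    0.95, perf[f"fruit_{trt}"] / summaries["n_flowers"][0]
                )
                cells[GroupKey(pop, morph, trt)] = GroupSimParams(
                    n=n if n is not None else REFERENCE_N[(pop, morph, trt)],
                    trait_means=means,
                    trait_sds=sds,
                    trait_corr=corr.copy(),
                    mean_fitness_HP=perf["fitness_HP"],
                    pl=pl,
                    beta_C=beta_C,
                    beta_HP=beta_HP,
                    fruit_set=fruit_set,
                )
    return SimConfig(cells, seed=seed)


def _simulate_cell(
    key: GroupKey, p: GroupSimParams, rounding: dict[str, int], rng: np.random.Generator
) -> tuple[pd.DataFrame, int]:
    L = np.linalg.cholesky(p.trait_corr)
    raw = rng.standard_normal((p.n, 5)) @ L.T
    traits = p.trait_means + raw * p.trait_sds
    cols = {}
    for j, name in enumerate(TRAITS):
        x = traits[:, j]
        if name == "n_flowers":
            x = np.maximum(np.round(x), 1.0)
        else:
            nd = rounding.get(name)
            if nd is not None:
                x = np.round(x, nd)
                x = np.maximum(x, 10.0**-nd)
            else:
                x = np.maximum(x, 1e-6)
        cols[name] = x
    z = np.column_stack(
        [(cols[t] - cols[t].mean()) / cols[t].std(ddof=1) for t in TRAITS]
    )
    beta = p.beta_C if key.treatment == "C" else p.beta_HP
    mu = p.mean_fitness_HP * (1.0 - p.pl) if key.treatment == "C" else p.mean_fitness_HP
    lin = 1.0 + z @ beta
    n_clipped = int((lin < 0).sum())
    lin = np.maximum(lin, 0.0)
    if p.fitness_noise_cv > 0:
        shape = 1.0 / p.fitness_noise_cv**2
        noise = rng.gamma(shape, p.fitness_noise_cv**2, size=p.n)
    else:
        noise = np.ones(p.n)
    fitness = mu * lin * noise
    nf = cols["n_flowers"].astype(int)
    fruits = np.clip(rng.binomial(nf, p.fruit_set), 1, nf)
    fruits = np.where(fitness > 0, fruits, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        spf = np.where(fruits > 0, fitness / np.maximum(fruits, 1), 0.0)
    df = pd.DataFrame(
        {
            "individual_id": [
                f"{key.population}-{key.morph}-{key.treatment}-{i:04d}" for i in range(p.n)
            ],
            "population": key.population,
            "morph": key.morph,
            "treatment": key.treatment,
            **{t: cols[t] for t in TRAITS},
            "fruit_production": fruits.astype(float),
            "seeds_per_fruit": spf,
            "female_fitness": fitness,
        }
    )
    return df, n_clipped


def simulate_cohort(config: SimConfig, seed: int | None = None) -> StudyTable:
    """Draw one cohort from ``config``; deterministic under a fixed seed.

    Cells are generated in a fixed key order from independent RNG
    streams spawned off the master seed, so per-cell draws do not
    depend on which other cells are configured. The number of
    individuals whose linear fitness predictor was clipped at zero is
    logged (it is ~0 under the default scenario).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    keys = sorted(config.cells, key=lambda k: (k.population, k.morph, k.treatment))
    children = np.random.SeedSequence(seed).spawn(len(keys))
    frames, total_clipped = [], 0
    for key, child in zip(keys, children):
        df, n_clipped = _simulate_cell(
            key, config.cells[key], config.rounding, np.random.default_rng(child)
        )
        frames.append(df)
        total_clipped += n_clipped
    if total_clipped:
        import logging

        logging.getLogger("pollsel").info(
            "simulate_cohort: clipped %d negative linear-fitness values", total_clipped
        )
    pops = list(dict.fromkeys(k.population for k in keys))
    return StudyTable(pd.concat(frames, ignore_index=True), populations=pops)


def truth_table(config: SimConfig) -> pd.DataFrame:
    """Machine-readable generator truth, one row per (cell, trait).

    Columns align with the gradient and delta tables: ``population,
    morph, treatment, trait, beta, trait_mean, trait_sd, pl,
    mean_fitness``. The Δβ truth for a stratum is the difference of its
    C and HP ``beta`` rows.
    """
    config.validate()
    rows = []
    keys = sorted(config.cells, key=lambda k: (k.population, k.morph, k.treatment))
    for key in keys:
        p = config.cells[key]
        beta = p.beta_C if key.treatment == "C" else p.beta_HP
        mu = p.mean_fitness_HP * (1.0 - p.pl) if key.treatment == "C" else p.mean_fitness_HP
        for j, trait in enumerate(TRAITS):
            rows.append(
                {
                    "population": key.population,
                    "morph": key.morph,
                    "treatment": key.treatment,
                    "trait": trait,
                    "beta": float(beta[j]),
                    "trait_mean": float(p.trait_means[j]),
                    "trait_sd": float(p.trait_sds[j]),
                    "pl": p.pl,
                    "mean_fitness": mu,
                }
            )
    return pd.DataFrame(rows)
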