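"""Publication-style rendering of analysis artifacts.

Gradient tables print as beta ± SE with the conventional three-tier
significance annotation — ``*`` for p < 0.05, ``(*)`` for marginal
significance 0.05 <= p < 0.1, ``ns`` otherwise — and the pollen
limitation table mirrors the field-study layout (one row per
population x morph with its bootstrap CI).
"""

from __future__ import annotations

import pandas as pd

#: default annotation thresholds (significant, marginal)
SIGNIFICANCE_THRESHOLDS: tuple[float, float] = (0.05, 0.1)


def significance_symbol(p: float, thresholds=SIGNIFICANCE_THRESHOLDS) -> str:
    sig, marginal = thresholds
    if not 0 < sig < marginal < 1:
        raise ValueError("thresholds must satisfy 0 < significant < marginal < 1")
    if p < sig:
        return "*"
    if p < marginal:
        return "(*)"
    return "ns"


def render_gradient_table(gradients: pd.DataFrame, thresholds=SIGNIFICANCE_THRESHOLDS) -> pd.DataFrame:
    """Wide per-trait table of annotated ``beta ± se`` strings."""
    g = gradients.copy()
    g["cell"] = g["population"] + "/" + g["morph"] + "/" + g["treatment"]
    g["display"] = [
        f"{b:+.3f} ± {s:.3f} {significance_symbol(p, thresholds)}"
        for b, s, p in zip(g["beta"], g["se"], g["p"])
    ]
    return g.pivot_table(index="cell", columns="trait", values="display", aggfunc="first", sort=False)


def render_delta_table(delta: pd.DataFrame, thresholds=SIGNIFICANCE_THRESHOLDS) -> pd.DataFrame:
    """Wide table of pollinator-mediated contrasts with annotations."""
    d = delta.copy()
    d["cell"] = d["population"] + "/" + d["morph"]
    d["display"] = [
        f"{v:+.3f} {significance_symbol(p, thresholds)}"
        for v, p in zip(d["delta_beta"], d["p"])
    ]
    return d.pivot_table(index="cell", columns="trait", values="display", aggfunc="first", sort=False)


def render_pl_table(pl_frame: pd.DataFrame) -> pd.DataFrame:
    """Pollen limitation with 95% CIs, one row per population x morph."""
    out = pl_frame.copy()
    out["PL [95% CI]"] = [
        f"{pl:.3f} [{lo:.3f}, {hi:.3f}]"
        for pl, lo, hi in zip(out["pl"], out["ci_low"], out["ci_high"])
    ]
    return out[["population", "morph", "n_C", "n_HP", "PL [95% CI]", "method"]]


def to_markdown(df: pd.DataFrame, title: str) -> str:
    body = df.to_markdown() if hasattr(df, "to_markdown") else str(df)
    return f"## {title}\n\n{body}\n"
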