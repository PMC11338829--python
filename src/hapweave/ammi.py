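"""NIL allele-effect estimation: BLUEs, AMMI, ANOVA and trade-offs.

Replicated trial data yield per-environment best linear unbiased estimates
(BLUEs) from a fixed-effects line + block model.  The line x environment
BLUE matrix is decomposed by AMMI — additive main effects (grand mean,
line effects, environment effects) by two-way ANOVA, then an SVD of the
interaction residuals.  :class:`AMMI` is the model object; its ``fit()``
returns :class:`AMMIResults` carrying effects, singular terms, per-line
AMMI means and stability, with ``summary()``.  Allelic effects within a
NIL family are tested by one-way ANOVA on the AMMI-fitted values between
the two allele classes, and trait pairs are classified for trade-offs.
The BC2 crossing-scheme background expectation is summarized from
simulated NIL families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_blues",
    "AMMI",
    "AMMIResults",
    "AlleleEffect",
    "allele_effect_test",
    "tradeoff_classify",
    "bc2_background",
]


def compute_blues(traits: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Per-environment BLUEs from a two-way fixed-effects line + block model.

    ``traits`` is plot-level data (line, environment, replicate, trait,
    value) with the replicate column as the block.  The BLUE of a line is
    its model prediction averaged over all blocks (the adjusted mean; with
    a balanced design it equals the raw line mean).  Returns a lines x
    environments frame (NaN where a line was not trialled).  A
    line/block design that is disconnected within an environment raises,
    naming the components.
    """
    import statsmodels.formula.api as smf
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    df = traits if trait is None else traits[traits["trait"] == trait]
    if df.empty:
        raise ValueError("no observations for requested trait")
    envs = list(dict.fromkeys(df["environment"]))
    lines = list(dict.fromkeys(df["line"]))
    out = pd.DataFrame(np.nan, index=lines, columns=envs)
    for env in envs:
        sub = df[df["environment"] == env]
        ls = list(dict.fromkeys(sub["line"]))
        bs = list(dict.fromkeys(sub["replicate"]))
        li = sub["line"].map({l: i for i, l in enumerate(ls)}).to_numpy()
        bi = sub["replicate"].map({b: i for i, b in enumerate(bs)}).to_numpy()
        # connectivity of the line/block incidence graph
        g = coo_matrix((np.ones(len(sub)), (li, len(ls) + bi)),
                       shape=(len(ls) + len(bs), len(ls) + len(bs)))
        g = g + g.T
        n_comp, labels = connected_components(g, directed=False)
        used = np.unique(np.concatenate([li, len(ls) + bi]))
        if len(np.unique(labels[used])) > 1:
            comps = {}
            for i, l in enumerate(ls):
                comps.setdefault(labels[i], []).append(l)
            raise ValueError(f"disconnected line/block design in {env!r}: "
                             f"{sorted(map(sorted, comps.values()))}")
        if len(bs) > 1:
            fit = smf.ols("value ~ C(line) + C(replicate)", data=sub).fit()
            grid = pd.DataFrame(
                [(l, b) for l in ls for b in bs], columns=["line", "replicate"]
            )
            pred = fit.predict(grid)
            blue = pred.to_numpy().reshape(len(ls), len(bs)).mean(axis=1)
        else:
            blue = sub.groupby("line", sort=False)["value"].mean().loc[ls].to_numpy()
        for l, v in zip(ls, blue):
            out.loc[l, env] = v
    return out


@dataclass
class AMMIResults:
    """Fitted AMMI decomposition of a lines x environments BLUE matrix."""

    grand_mean: float
    line_effects: pd.Series
    env_effects: pd.Series
    singular_values: np.ndarray
    line_scores: np.ndarray       # U * s, lines x all terms
    env_scores: np.ndarray        # V * s, environments x all terms
    n_terms: int                  # multiplicative terms retained
    imputed: bool                 # True if missing cells were mean-imputed
    model: "AMMI"

    @property
    def ammi_means(self) -> pd.Series:
        """Per-line AMMI mean = grand mean + line main effect."""
        return self.grand_mean + self.line_effects

    @property
    def stability(self) -> pd.Series:
        """Per-line sum of squared scores on the retained axes (low = stable)."""
        k = self.n_terms
        return pd.Series(
            (self.line_scores[:, :k] ** 2).sum(axis=1), index=self.line_effects.index
        )

    def fitted(self, n_terms: int | None = None) -> pd.DataFrame:
        """Additive fit plus the first ``n_terms`` multiplicative terms."""
        k = self.n_terms if n_terms is None else n_terms
        lines = self.line_effects.index
        envs = self.env_effects.index
        add = (
            self.grand_mean
            + self.line_effects.to_numpy()[:, None]
            + self.env_effects.to_numpy()[None, :]
        )
        if k > 0:
            s = self.singular_values[:k]
            root = np.sqrt(s, where=s > 0, out=np.zeros_like(s))
            inv = np.divide(1.0, root, where=root > 0, out=np.zeros_like(root))
            u = self.line_scores[:, :k] * inv[None, :]
            v = self.env_scores[:, :k] * inv[None, :]
            add = add + u @ v.T
        return pd.DataFrame(add, index=lines, columns=envs)

    def reconstruct(self) -> pd.DataFrame:
        """Exact reconstruction with every multiplicative term retained."""
        return self.fitted(len(self.singular_values))

    def summary(self) -> str:
        lines = []
        lines.append("AMMI decomposition")
        lines.append(f"  lines: {len(self.line_effects)}  environments: "
                     f"{len(self.env_effects)}  terms retained: {self.n_terms}"
                     + ("  (mean-imputed cells)" if self.imputed else ""))
        lines.append(f"  grand mean: {self.grand_mean:.4f}")
        sv = ", ".join(f"{s:.3f}" for s in self.singular_values[:5])
        lines.append(f"  leading singular values: {sv}")
        lines.append("  line        effect    AMMI mean   stability")
        for l in self.line_effects.index:
            lines.append(
                f"  {str(l):<12}{self.line_effects[l]:>8.3f}"
                f"{self.ammi_means[l]:>12.3f}{self.stability[l]:>12.4f}"
            )
        return "\n".join(lines)


class AMMI:
    """Additive main effects and multiplicative interaction model.

    Parameters
    ----------
    blues : DataFrame
        Lines x environments BLUE matrix; at least 2 x 2.  Missing cells
        are mean-imputed (row + column - grand mean) and flagged.
    """

    def __init__(self, blues: pd.DataFrame):
        if blues.shape[0] < 2 or blues.shape[1] < 2:
            raise ValueError("AMMI needs >= 2 lines and >= 2 environments")
        self.blues = blues.astype(float)

    def fit(self, n_terms: int = 2) -> AMMIResults:
        X = self.blues.to_numpy().copy()
        imputed = bool(np.isnan(X).any())
        if imputed:
            row = np.nanmean(X, axis=1)
            col = np.nanmean(X, axis=0)
            gm = np.nanmean(X)
            fill = row[:, None] + col[None, :] - gm
            X = np.where(np.isnan(X), fill, X)
        grand = float(X.mean())
        line_eff = X.mean(axis=1) - grand
        env_eff = X.mean(axis=0) - grand
        resid = X - grand - line_eff[:, None] - env_eff[None, :]
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        k = int(min(n_terms, len(s)))
        return AMMIResults(
            grand_mean=grand,
            line_effects=pd.Series(line_eff, index=self.blues.index),
            env_effects=pd.Series(env_eff, index=self.blues.columns),
            singular_values=s,
            line_scores=u * s[None, :],
            env_scores=vt.T * s[None, :],
            n_terms=k,
            imputed=imputed,
            model=self,
        )


@dataclass
class AlleleEffect:
    """Allelic substitution effect within one NIL family."""

    family: str
    trait: str
    effect: float           # mean(donor-allele class) - mean(recurrent class)
    percent: float          # effect as % of the recurrent-class mean
    f_stat: float
    p_value: float
    significant: bool       # p < 0.05
    n_donor: int
    n_recurrent: int


def allele_effect_test(ammi_blues: pd.DataFrame, allele_of: dict,
                       family: str = "family", trait: str = "trait",
                       alpha: float = 0.05) -> AlleleEffect:
    """ANOVA between allele classes on AMMI-BLUE cells.

    ``ammi_blues`` is a lines x environments frame (typically
    ``AMMIResults.fitted()`` or the BLUE matrix itself); ``allele_of`` maps
    line -> 'donor' or 'recurrent'.  Observations are line x environment
    cells; the allele-class effect is tested controlling the environment
    main effect (it cancels in the contrast but would otherwise inflate the
    error term), i.e. an F-test of class in a class + environment
    fixed-effects model.  The effect is the adjusted class difference
    (donor minus recurrent), also as a percentage of the recurrent-class
    mean.
    """
    donor_lines = [l for l in ammi_blues.index if allele_of.get(l) == "donor"]
    rec_lines = [l for l in ammi_blues.index if allele_of.get(l) == "recurrent"]
    if not donor_lines or not rec_lines:
        raise ValueError("both allele classes need at least one line")
    long = ammi_blues.loc[donor_lines + rec_lines].stack().rename("value").reset_index()
    long.columns = ["line", "environment", "value"]
    long["cls"] = long["line"].map(allele_of)
    long = long.dropna(subset=["value"])
    if len(long) < 4:
        raise ValueError("need >= 4 cell observations across the classes")
    y = long["value"].to_numpy(float)
    d = (long["cls"] == "donor").to_numpy(float)
    env = pd.get_dummies(long["environment"], drop_first=True).to_numpy(float)
    ones = np.ones((len(y), 1))
    X0 = np.hstack([ones, env])                    # environment only
    X1 = np.hstack([ones, env, d[:, None]])        # + allele class
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(((y - X0 @ beta0) ** 2).sum())
    rss1 = float(((y - X1 @ beta1) ** 2).sum())
    df1 = len(y) - X1.shape[1]
    if df1 <= 0:
        raise ValueError("not enough observations for the class + environment model")
    f = max(0.0, (rss0 - rss1) / 1.0) / (rss1 / df1) if rss1 > 0 else np.inf
    p = float(stats.f.sf(f, 1, df1)) if np.isfinite(f) else 0.0
    effect = float(beta1[-1])  # adjusted donor - recurrent difference
    rec_mean = float(long.loc[long["cls"] == "recurrent", "value"].mean())
    pct = effect / rec_mean * 100.0 if rec_mean != 0 else np.nan
    return AlleleEffect(family, trait, effect, pct, float(f), p,
                        bool(p < alpha), len(donor_lines), len(rec_lines))


def tradeoff_classify(effect_a: AlleleEffect, effect_b: AlleleEffect) -> str:
    """Trade-off category of a trait pair in one family.

    antagonistic: both significant with opposite signs; synergistic: both
    significant, same sign; neutral-B / neutral-A: only one trait
    significant (a significant improvement in A with non-significant B is
    the antagonism-breaking case); both-neutral otherwise.
    """
    sa, sb = effect_a.significant, effect_b.significant
    if sa and sb:
        return "antagonistic" if effect_a.effect * effect_b.effect < 0 else "synergistic"
    if sa:
        return "neutral-B"
    if sb:
        return "neutral-A"
    return "both-neutral"


def bc2_background(families: list, unlinked: bool = False) -> dict:
    """Summary of recurrent-parent genome fraction over simulated families.

    ``families`` are :class:`hapweave.simulate.NILFamily`; ``unlinked``
    summarizes the fraction excluding the whole carrier chromosome instead
    of just the marker-selected interval.
    """
    if not families:
        raise ValueError("no families")
    fr = np.array([
        f.recurrent_fraction_unlinked if unlinked else f.recurrent_fraction
        for f in families
    ])
    return {
        "n": len(fr),
        "mean": float(fr.mean()),
        "sd": float(fr.std(ddof=1)) if len(fr) > 1 else 0.0,
        "q05": float(np.quantile(fr, 0.05)),
        "median": float(np.quantile(fr, 0.5)),
        "q95": float(np.quantile(fr, 0.95)),
    }
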