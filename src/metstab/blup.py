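"""Mixed-model genotype evaluation: variance components, BLUP, WAASB.

Model (balanced two-way MET with blocks nested in environments, environments
fixed, genotype and genotype x environment random):

    y_ijr = mu + e_j + rho_jr + g_i + (ge)_ij + eps_ijr
    g ~ N(0, sigma2_g),  ge ~ N(0, sigma2_ge),  eps ~ N(0, sigma2_e)

Variance components come from the expected-mean-squares identities of the
balanced design (equal to REML there when estimates are interior):

    sigma2_e  = MS(Residuals)
    sigma2_ge = (MS(ENV:GEN) - sigma2_e) / R
    sigma2_g  = (MS(GEN) - MS(ENV:GEN)) / (R * E)

BLUP of a genotype's mean shrinks its observed mean toward the grand mean by
h = sigma2_g / (sigma2_g + sigma2_ge/E + sigma2_e/(E*R)), which is also the
entry-mean broad-sense heritability H2; selection accuracy is sqrt(H2).

WAASB is the weighted average of a genotype's absolute IPCA scores taken
from the SVD of the BLUP-scale interaction matrix (the double-centered cell
means shrunk by sigma2_ge / (sigma2_ge + sigma2_e/R)), weights proportional
to each axis's share of variance; low WAASB = stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ammi import pooled_anova, svd_interaction, _double_center
from .data import METTable, cell_means
from .exceptions import ContractError, DesignError, DomainError


@dataclass(frozen=True)
class VarianceComponents:
    """EMS variance-component estimates; negative estimates are clamped to 0
    and reported in ``clamped``."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    grand_mean: float
    clamped: tuple[str, ...] = ()


def variance_components(anova: pd.DataFrame, design: tuple[int, int, int],
                        grand_mean: float) -> VarianceComponents:
    """Method-of-moments components from a pooled ANOVA of a balanced MET."""
    for s in ("GEN", "ENV:GEN", "Residuals"):
        if s not in anova.index:
            raise ContractError(f"anova table lacks source row {s!r}")
    _, e, r = design
    ms_g = float(anova.loc["GEN", "ms"])
    ms_ge = float(anova.loc["ENV:GEN", "ms"])
    ms_e = float(anova.loc["Residuals", "ms"])
    clamped = []
    s2e = ms_e
    s2ge = (ms_ge - ms_e) / r
    if s2ge < 0:
        s2ge = 0.0
        clamped.append("sigma2_ge")
    s2g = (ms_g - ms_ge) / (r * e)
    if s2g < 0:
        s2g = 0.0
        clamped.append("sigma2_g")
    return VarianceComponents(sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
                              grand_mean=grand_mean, clamped=tuple(clamped))


def blup_shrinkage(vc: VarianceComponents, n_envs: int, n_reps: int) -> float:
    """Shrinkage factor h in [0, 1] for genotype entry means."""
    denom = vc.sigma2_g + vc.sigma2_ge / n_envs + vc.sigma2_e / (n_envs * n_reps)
    if denom == 0:
        return 0.0
    return vc.sigma2_g / denom


def blup_predicted_means(vc: VarianceComponents, means: pd.DataFrame,
                         design: tuple[int, int, int]) -> pd.Series:
    """BLUP of genotype means: mu + h * (observed mean - mu)."""
    _, e, r = design
    h = blup_shrinkage(vc, e, r)
    obs = means.mean(axis=1)
    pred = vc.grand_mean + h * (obs - vc.grand_mean)
    pred.name = "predicted_mean"
    return pred


def genetic_stats(vc: VarianceComponents,
                  design: tuple[int, int, int]) -> tuple[float, float, float]:
    """(H2, As, CV): entry-mean heritability, selection accuracy, CV%."""
    _, e, r = design
    h2 = blup_shrinkage(vc, e, r)
    acc = float(np.sqrt(h2))
    if vc.grand_mean == 0:
        raise DomainError("CV undefined for zero grand mean")
    cv = 100.0 * float(np.sqrt(vc.sigma2_e)) / abs(vc.grand_mean)
    return h2, acc, cv


def interaction_blup_matrix(means: pd.DataFrame, vc: VarianceComponents,
                            n_reps: int) -> pd.DataFrame:
    """BLUPs of the genotype x environment deviations.

    In the balanced design the BLUP of (ge)_ij is the double-centered cell
    mean shrunk by sigma2_ge / (sigma2_ge + sigma2_e / R).
    """
    denom = vc.sigma2_ge + vc.sigma2_e / n_reps
    shrink = vc.sigma2_ge / denom if denom > 0 else 0.0
    centered = _double_center(means.to_numpy(float))
    return pd.DataFrame(shrink * centered, index=means.index,
                        columns=means.columns)


def waasb_scores(means: pd.DataFrame, vc: VarianceComponents,
                 n_reps: int) -> pd.Series:
    """Weighted average of absolute IPCA scores of the BLUP interaction.

    WAASB_i = sum_k |score_ik| * w_k / sum_k w_k over *all* axes, with w_k
    the percent of interaction variance on axis k.  Zero for every genotype
    when the interaction variance component is zero.
    """
    if min(means.shape) < 2:
        raise DesignError("waasb needs >= 2 genotypes and >= 2 environments")
    blup_ge = interaction_blup_matrix(means, vc, n_reps)
    u, s, v = svd_interaction(blup_ge)
    lam = s ** 2
    tot = lam.sum()
    if tot == 0:
        return pd.Series(0.0, index=means.index, name="WAASB")
    w = 100.0 * lam / tot
    scores = np.abs(u * np.sqrt(s))
    vals = (scores * w).sum(axis=1) / w.sum()
    return pd.Series(vals, index=means.index, name="WAASB")


def quadrant_classify(means: pd.Series, waasb: pd.Series,
                      mean_threshold: float | None = None,
                      waasb_threshold: float | None = None) -> pd.Series:
    """Mean x WAASB biplot quadrants.

    I   below-threshold mean, above-threshold WAASB (poor, unstable)
    II  above-threshold mean, above-threshold WAASB (productive, unstable)
    III below-threshold mean, below-threshold WAASB (poor, stable)
    IV  above-threshold mean, below-threshold WAASB (productive, stable)

    Thresholds default to the across-genotype means of each axis.  A point
    exactly on a threshold is resolved toward the favourable side (counts as
    above-mean performance / below-mean WAASB), so a genotype on both
    thresholds lands in IV.
    """
    means, waasb = means.align(waasb, join="inner")
    mt = float(means.mean()) if mean_threshold is None else mean_threshold
    wt = float(waasb.mean()) if waasb_threshold is None else waasb_threshold
    if not (np.isfinite(mt) and np.isfinite(wt)):
        raise ValueError("thresholds must be finite")
    productive = means >= mt
    stable = waasb <= wt
    out = pd.Series(
        np.select(
            [productive & stable, productive & ~stable, ~productive & stable],
            ["IV", "II", "III"], default="I"),
        index=means.index, name="quadrant")
    return out


class BLUPResults:
    """Fitted mixed-model evaluation of one trait.

    Carries the variance components, per-genotype observed and predicted
    means, entry-mean heritability / selection accuracy / CV, WAASB scores
    and mean x WAASB quadrant labels.
    """

    def __init__(self, *, anova, means, vc, design, trait):
        self.anova = anova
        self.means = means
        self.variance_components = vc
        self.design = design
        self.trait = trait
        self.observed_means = means.mean(axis=1).rename("observed_mean")
        self.predicted_means = blup_predicted_means(vc, means, design)
        self.blup_effects = (self.predicted_means - vc.grand_mean).rename("blup_effect")
        self.shrinkage = blup_shrinkage(vc, design[1], design[2])
        self.heritability, self.accuracy, self.cv = genetic_stats(vc, design)
        self.waasb = waasb_scores(means, vc, design[2])
        self.quadrants = quadrant_classify(self.observed_means, self.waasb)

    def genotype_table(self) -> pd.DataFrame:
        """Per-genotype observed/predicted mean, WAASB and quadrant."""
        out = pd.concat([self.observed_means, self.predicted_means,
                         self.blup_effects, self.waasb, self.quadrants], axis=1)
        out.index.name = "genotype"
        return out

    def plot_mean_vs_waasb(self, ax=None):  # pragma: no cover - convenience
        """Mean x WAASB quadrant plot; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.observed_means, self.waasb)
        for name in self.observed_means.index:
            ax.annotate(str(name),
                        (self.observed_means[name], self.waasb[name]), fontsize=7)
        ax.axvline(float(self.observed_means.mean()), color="grey", lw=0.8)
        ax.axhline(float(self.waasb.mean()), color="grey", lw=0.8)
        ax.set_xlabel(f"{self.trait} mean")
        ax.set_ylabel("WAASB")
        return ax

    def summary(self) -> str:
        vc = self.variance_components
        lines = [f"BLUP evaluation of {self.trait}", "=" * 60]
        g, e, r = self.design
        lines.append(f"design: {g} genotypes x {e} environments x {r} replicates")
        lines.append(f"grand mean        : {vc.grand_mean:.4f}")
        lines.append(f"sigma2_g          : {vc.sigma2_g:.4f}")
        lines.append(f"sigma2_ge         : {vc.sigma2_ge:.4f}")
        lines.append(f"sigma2_e          : {vc.sigma2_e:.4f}"
                     + (f"   [clamped: {', '.join(vc.clamped)}]" if vc.clamped else ""))
        lines.append(f"shrinkage h       : {self.shrinkage:.4f}")
        lines.append(f"heritability H2   : {self.heritability:.4f} (entry-mean)")
        lines.append(f"accuracy As       : {self.accuracy:.4f}")
        lines.append(f"CV%               : {self.cv:.2f}")
        lines.append("")
        lines.append(self.genotype_table().round(4).to_string())
        return "\n".join(lines)


class BLUP:
    """Mixed-model (BLUP) evaluation of one trait of a balanced MET.

    Examples
    --------
    >>> res = BLUP(table, "HPW").fit()
    >>> res.heritability, res.accuracy
    >>> res.genotype_table().head()
    """

    def __init__(self, table: METTable, trait: str):
        self.table = table
        self.trait = trait

    def fit(self) -> BLUPResults:
        anova = pooled_anova(self.table, self.trait)
        means = cell_means(self.table, self.trait)
        design = self.table.design(self.trait)
        grand = float(means.to_numpy().mean())
        vc = variance_components(anova, design, grand)
        return BLUPResults(anova=anova, means=means, vc=vc, design=design,
                           trait=self.trait)
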