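"""Pooled ANOVA and AMMI decomposition of genotype x environment interaction.

The AMMI (Additive Main effects and Multiplicative Interaction) model for a
balanced trial over G genotypes, E environments and R replicate blocks is

    y_ijr = mu + g_i + e_j + sum_k sqrt(lambda_k) * alpha_ik * gamma_jk
            + rho_jr + eps_ijr

The additive part is estimated by the standard balanced two-way ANOVA with
blocks nested in environments; the multiplicative part by the SVD of the
double-centered genotype x environment means matrix.  Each interaction
principal component axis (IPCA) is tested with Gollob's F test, and the
interaction sum of squares is split into a low-rank "signal" kept by the
retained axes and a "noise" floor equal to the interaction df times the
pooled error mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import stability
from .data import METTable, cell_means
from .exceptions import ContractError, DesignError

ANOVA_SOURCES = ("ENV", "REP(ENV)", "GEN", "ENV:GEN", "Residuals")


def pooled_anova(table: METTable, trait: str) -> pd.DataFrame:
    """Combined ANOVA over environments for one trait of a balanced MET.

    Returns a DataFrame indexed by source (ENV, REP(ENV), GEN, ENV:GEN,
    Residuals) with columns ``df, ss, ms, F, p, pct_ss``.  Genotype and
    interaction are tested against the pooled residual; environments against
    replicates-within-environments.  ``pct_ss`` is each source's share of the
    total (corrected) sum of squares and adds to 100.
    """
    if not table.is_balanced(trait):
        raise DesignError(f"pooled_anova requires a balanced table for {trait!r}")
    sub = table._trait_frame(trait)
    g, e, r = table.design(trait)
    if g < 2 or e < 2:
        raise DesignError("pooled_anova needs G >= 2 and E >= 2")
    if r < 2:
        raise DesignError("pooled_anova needs R >= 2 for a residual term")

    y = sub.pivot_table(index="genotype", columns=["env", "rep"],
                        values="value", observed=True)
    y = y.sort_index(axis=0).sort_index(axis=1)
    arr = y.to_numpy(float).reshape(g, e, r)

    grand = arr.mean()
    gen_m = arr.mean(axis=(1, 2))
    env_m = arr.mean(axis=(0, 2))
    rep_m = arr.mean(axis=0)              # E x R block means
    cell_m = arr.mean(axis=2)             # G x E

    ss_env = g * r * np.sum((env_m - grand) ** 2)
    ss_rep = g * np.sum((rep_m - env_m[:, None]) ** 2)
    ss_gen = e * r * np.sum((gen_m - grand) ** 2)
    inter = cell_m - gen_m[:, None] - env_m[None, :] + grand
    ss_ge = r * np.sum(inter ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_res = ss_tot - ss_env - ss_rep - ss_gen - ss_ge

    dfs = {
        "ENV": e - 1,
        "REP(ENV)": e * (r - 1),
        "GEN": g - 1,
        "ENV:GEN": (g - 1) * (e - 1),
        "Residuals": e * (g - 1) * (r - 1),
    }
    sss = {"ENV": ss_env, "REP(ENV)": ss_rep, "GEN": ss_gen,
           "ENV:GEN": ss_ge, "Residuals": ss_res}

    rows = []
    ms = {s: sss[s] / dfs[s] for s in ANOVA_SOURCES}
    for s in ANOVA_SOURCES:
        if s == "ENV":
            fval = ms["ENV"] / ms["REP(ENV)"] if ms["REP(ENV)"] > 0 else np.nan
            pval = stats.f.sf(fval, dfs["ENV"], dfs["REP(ENV)"])
        elif s in ("GEN", "ENV:GEN"):
            fval = ms[s] / ms["Residuals"] if ms["Residuals"] > 0 else np.nan
            pval = stats.f.sf(fval, dfs[s], dfs["Residuals"])
        else:
            fval, pval = np.nan, np.nan
        rows.append({"source": s, "df": dfs[s], "ss": sss[s], "ms": ms[s],
                     "F": fval, "p": pval,
                     "pct_ss": 100.0 * sss[s] / ss_tot if ss_tot > 0 else 0.0})
    return pd.DataFrame(rows).set_index("source")


def anova_from_mean_squares(df_map: dict, ms_map: dict) -> pd.DataFrame:
    """Assemble an ANOVA table from published df and mean squares.

    Lets downstream arithmetic (signal/noise partition, variance components)
    be reproduced from printed summary tables when raw plot data are not
    available; SS is reconstructed as df * MS.
    """
    rows = []
    total_ss = sum(df_map[s] * ms_map[s] for s in df_map)
    for s in df_map:
        ss = df_map[s] * ms_map[s]
        rows.append({"source": s, "df": int(df_map[s]), "ss": ss,
                     "ms": ms_map[s], "F": np.nan, "p": np.nan,
                     "pct_ss": 100.0 * ss / total_ss if total_ss else np.nan})
    return pd.DataFrame(rows).set_index("source")


@dataclass(frozen=True)
class SignalNoise:
    """Split of interaction SS into a repeatable signal and a noise floor.

    noise_ss = df(ENV:GEN) * MS(Residuals); signal_ss is the remainder,
    clamped at zero (``clamped`` flags when the interaction carried less SS
    than its noise expectation).
    """

    gsi_ss: float
    noise_ss: float
    signal_ss: float
    pct_signal: float
    pct_noise: float
    clamped: bool


def partition_signal_noise(anova: pd.DataFrame) -> SignalNoise:
    """Partition genotype x environment interaction SS into signal and noise."""
    for s in ("ENV:GEN", "Residuals"):
        if s not in anova.index:
            raise ContractError(f"anova table lacks source row {s!r}")
    gsi_ss = float(anova.loc["ENV:GEN", "ss"])
    noise = float(anova.loc["ENV:GEN", "df"] * anova.loc["Residuals", "ms"])
    signal = gsi_ss - noise
    clamped = signal < 0
    if clamped:
        signal = 0.0
    if gsi_ss > 0:
        pct_n = 100.0 * noise / gsi_ss
        pct_s = 100.0 * signal / gsi_ss
    else:
        pct_n = pct_s = np.nan
    return SignalNoise(gsi_ss=gsi_ss, noise_ss=noise, signal_ss=signal,
                       pct_signal=pct_s, pct_noise=pct_n, clamped=clamped)


def _double_center(mat: np.ndarray) -> np.ndarray:
    return (mat - mat.mean(axis=1, keepdims=True)
            - mat.mean(axis=0, keepdims=True) + mat.mean())


def svd_interaction(means: pd.DataFrame):
    """Sign-fixed SVD of the double-centered means matrix.

    Returns (u, s, v) with orthonormal columns in u (genotypes) and v
    (environments).  Each axis's sign is fixed so that its largest-magnitude
    environment loading is positive, making scores reproducible across
    linear-algebra backends.
    """
    mat = means.to_numpy(float)
    centered = _double_center(mat)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T
    k = min(mat.shape[0] - 1, mat.shape[1] - 1)
    u, s, v = u[:, :k], s[:k], v[:, :k]
    for j in range(k):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    return u, s, v


class AMMIResults:
    """Fitted AMMI decomposition.

    Attributes
    ----------
    anova : DataFrame
        Pooled ANOVA (``pooled_anova`` layout).
    means : DataFrame
        Genotype x environment cell means the SVD was taken of.
    eigenvalues : ndarray
        lambda_k = s_k**2 from the SVD of the centered means, descending.
    genotype_scores, env_scores : DataFrame
        IPCA scores on the symmetric biplot scale (eigenvector *
        sqrt(singular value)); the k-th multiplicative term of a cell mean is
        the product of the two k-th scores.
    pct_interaction : ndarray
        theta_k, percent of interaction SS captured by each axis.
    pc_table : DataFrame
        Per-axis Gollob df, SS (replicate scale), MS, F, p.
    n_significant : int
        Number of axes retained for stability indices.
    signal_noise : SignalNoise
    """

    def __init__(self, *, anova, means, u, s, v, n_reps, alpha, max_significant):
        self.anova = anova
        self.means = means
        self.n_reps = n_reps
        self.alpha = alpha
        g, e = means.shape
        self.design = (g, e, n_reps)
        self.eigenvalues = s ** 2
        self.singular_values = s
        self.genotype_eigenvectors = pd.DataFrame(
            u, index=means.index, columns=self._pc_names(len(s)))
        self.env_eigenvectors = pd.DataFrame(
            v, index=means.columns, columns=self._pc_names(len(s)))
        root = np.sqrt(s)
        self.genotype_scores = pd.DataFrame(
            u * root, index=means.index, columns=self._pc_names(len(s)))
        self.env_scores = pd.DataFrame(
            v * root, index=means.columns, columns=self._pc_names(len(s)))
        tot = self.eigenvalues.sum()
        self.pct_interaction = (100.0 * self.eigenvalues / tot
                                if tot > 0 else np.zeros_like(self.eigenvalues))

        ms_res = float(anova.loc["Residuals", "ms"])
        df_res = int(anova.loc["Residuals", "df"])
        rows = []
        for k, lam in enumerate(self.eigenvalues, start=1):
            dfk = g + e - 1 - 2 * k
            ss_k = n_reps * lam
            if dfk > 0 and ms_res > 0:
                fval = (ss_k / dfk) / ms_res
                pval = float(stats.f.sf(fval, dfk, df_res))
            else:
                fval, pval = np.nan, np.nan
            rows.append({"pc": f"PC{k}", "df": dfk, "ss": ss_k,
                         "ms": ss_k / dfk if dfk > 0 else np.nan,
                         "F": fval, "p": pval,
                         "pct_gsi": self.pct_interaction[k - 1]})
        self.pc_table = pd.DataFrame(rows).set_index("pc")
        n_sig = int((self.pc_table["p"] < alpha).sum())
        self.n_significant = max(1, min(n_sig, max_significant, len(s)))
        self.signal_noise = partition_signal_noise(anova)

    @staticmethod
    def _pc_names(k):
        return [f"PC{i}" for i in range(1, k + 1)]

    # ------------------------------------------------------------ stability
    def asi(self, n_pcs: int | None = None) -> pd.Series:
        """AMMI stability index per genotype (lower = more stable)."""
        if n_pcs is None:
            n_pcs = self.n_significant
        return stability.asi(self.genotype_scores, self.pct_interaction, n_pcs)

    def stability_table(self, n_pcs: int | None = None,
                        direction: str = "desc") -> pd.DataFrame:
        """ASI, ranks and the simultaneous selection index per genotype."""
        asi_vals = self.asi(n_pcs)
        means = self.means.mean(axis=1)
        return stability.stability_table(asi_vals, means, direction=direction)

    def biplot_coordinates(self, stability_band: float = 0.0) -> pd.DataFrame:
        """AMMI1 biplot points: (marginal mean, IPCA1 score) per entity.

        Genotypes/environments with |IPCA1| <= ``stability_band`` are flagged
        ``on_pc1_line`` (visually "on the zero-PC1 line", i.e. stable /
        non-interacting).
        """
        rows = []
        gmeans = self.means.mean(axis=1)
        emeans = self.means.mean(axis=0)
        for name, mean in gmeans.items():
            sc = float(self.genotype_scores.loc[name, "PC1"])
            rows.append({"entity": name, "type": "genotype", "mean": mean,
                         "ipca1": sc, "on_pc1_line": abs(sc) <= stability_band})
        for name, mean in emeans.items():
            sc = float(self.env_scores.loc[name, "PC1"])
            rows.append({"entity": name, "type": "environment", "mean": mean,
                         "ipca1": sc, "on_pc1_line": abs(sc) <= stability_band})
        out = pd.DataFrame(rows).set_index("entity")
        return out

    def reconstruct_interaction(self, n_pcs: int | None = None) -> pd.DataFrame:
        """Sum of the first ``n_pcs`` multiplicative terms (all by default)."""
        if n_pcs is None:
            n_pcs = len(self.singular_values)
        u = self.genotype_scores.to_numpy()[:, :n_pcs]
        v = self.env_scores.to_numpy()[:, :n_pcs]
        return pd.DataFrame(u @ v.T, index=self.means.index,
                            columns=self.means.columns)

    def plot_biplot(self, ax=None):  # pragma: no cover - convenience plotting
        """AMMI1 biplot (mean vs IPCA1); requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.biplot_coordinates()
        for typ, marker in (("genotype", "o"), ("environment", "^")):
            sub = coords[coords["type"] == typ]
            ax.scatter(sub["mean"], sub["ipca1"], marker=marker, label=typ)
            for name, row in sub.iterrows():
                ax.annotate(str(name), (row["mean"], row["ipca1"]), fontsize=7)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("trait mean")
        ax.set_ylabel("IPCA1 score")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["AMMI decomposition", "=" * 60]
        g, e, r = self.design
        lines.append(f"design: {g} genotypes x {e} environments x {r} replicates")
        lines.append("")
        lines.append("Pooled ANOVA")
        lines.append(self.anova.round(4).to_string())
        lines.append("")
        lines.append("Interaction principal components (Gollob F tests)")
        lines.append(self.pc_table.round(4).to_string())
        lines.append(f"significant axes retained: {self.n_significant} "
                     f"(alpha = {self.alpha})")
        sn = self.signal_noise
        lines.append("")
        lines.append(f"interaction SS {sn.gsi_ss:.2f} = "
                     f"signal {sn.signal_ss:.2f} ({sn.pct_signal:.2f}%) + "
                     f"noise {sn.noise_ss:.2f} ({sn.pct_noise:.2f}%)"
                     + ("  [signal clamped at 0]" if sn.clamped else ""))
        return "\n".join(lines)


class AMMI:
    """AMMI model for one trait of a balanced multi-environment trial.

    Examples
    --------
    >>> res = AMMI(table, "HPW").fit()
    >>> res.pct_interaction[0]        # % of interaction SS on IPCA1
    >>> res.stability_table().head()
    """

    def __init__(self, table: METTable, trait: str):
        self.table = table
        self.trait = trait

    def fit(self, alpha: float = 0.05, max_significant: int = 2) -> AMMIResults:
        anova = pooled_anova(self.table, self.trait)
        means = cell_means(self.table, self.trait)
        _, _, r = self.table.design(self.trait)
        u, s, v = svd_interaction(means)
        return AMMIResults(anova=anova, means=means, u=u, s=s, v=v,
                           n_reps=r, alpha=alpha, max_significant=max_significant)


def ammi_decompose(means: pd.DataFrame, anova: pd.DataFrame, n_reps: int,
                   alpha: float = 0.05, max_significant: int = 2) -> AMMIResults:
    """Decompose a means matrix against an already-computed ANOVA table."""
    if min(means.shape) < 2:
        raise DesignError("ammi_decompose needs at least 2 genotypes and 2 environments")
    u, s, v = svd_interaction(means)
    return AMMIResults(anova=anova, means=means, u=u, s=s, v=v, n_reps=n_reps,
                       alpha=alpha, max_significant=max_significant)
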