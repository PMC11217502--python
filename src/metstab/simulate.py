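"""Synthetic multi-environment trial data with known ground truth.

Generates balanced RCBD phenotype tables, cumulative germination counts and
marker panels so every analysis stage can be exercised and its recovery of
planted truth measured, without any external data.

The phenotype model mirrors the AMMI decomposition itself:

    y_ijr = mu + g_i + e_j + sum_k sqrt(lambda_k) alpha_ik gamma_jk
            + eta_ij + eps_ijr

with g_i ~ N(0, sigma_g^2), random orthonormal interaction axes alpha/gamma
(orthogonal to the all-ones vector, so the planted term is exactly the
rank-k "signal"), unstructured interaction noise eta ~ N(0,
sigma_ge_noise^2) and plot error eps ~ N(0, sigma_e^2).  The truth record
carries every realised effect plus the implied signal fraction and
entry-mean heritability, so parameter-recovery tests have exact targets.

Default design and effect sizes emulate a 32-genotype x 3-season x
3-replicate groundnut trial in its high-signal regime (genotype main effect
dominating, one dominant interaction axis carrying ~90% of the interaction
SS above the noise floor).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import METTable

#: Germination-probability schedules (P[still dormant] by day) per class.
DEFAULT_SCHEDULES = {
    "dormant": {15: 0.97, 21: 0.95},
    "non_dormant": {15: 0.15, 21: 0.05},
    "intermediate": {15: 0.60, 21: 0.45},
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the package's reference conditions.

    lambdas are the singular values (on the cell-mean scale, SS units) of
    the planted rank-k interaction; with the defaults the planted signal
    fraction of interaction SS is ~90% and entry-mean heritability ~0.84.
    Donors (first ``n_donors`` genotypes) get a genotype effect of
    ``donor_lift`` genotypic SDs and are excluded from the structured
    interaction axes — stable, high-value truth for end-to-end recovery.
    """

    n_genotypes: int = 32
    n_envs: int = 3
    n_reps: int = 3
    mu: float = 70.0
    sigma_g: float = 12.0
    sigma_ge_noise: float = 0.5
    sigma_e: float = 5.0
    interaction_rank: int = 1
    lambdas: tuple[float, ...] = (4800.0,)
    env_effects: tuple[float, ...] = (4.0, -3.0, -1.0)
    trait: str = "yield"
    percent: bool = False
    n_donors: int = 0
    donor_lift: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genotypes, self.n_envs) < 2 or self.n_reps < 1:
            raise ValueError("need G >= 2, E >= 2, R >= 1")
        if len(self.env_effects) != self.n_envs:
            raise ValueError("env_effects length must equal n_envs")
        if len(self.lambdas) != self.interaction_rank:
            raise ValueError("lambdas length must equal interaction_rank")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be >= 0")
        if min(self.sigma_g, self.sigma_ge_noise, self.sigma_e) < 0:
            raise ValueError("standard deviations must be >= 0")
        free = self.n_genotypes - self.n_donors
        if self.interaction_rank > min(free - 1, self.n_envs - 1):
            raise ValueError("interaction_rank exceeds min(G - n_donors - 1, E - 1)")
        if not 0 <= self.n_donors < self.n_genotypes:
            raise ValueError("n_donors must be in [0, G)")


@dataclass(frozen=True)
class METTruth:
    """Realised effects and implied recovery targets of one simulation."""

    mu: float
    genotype_effects: pd.Series
    env_effects: pd.Series
    interaction: pd.DataFrame        # structured (signal) part, per cell
    interaction_noise: pd.DataFrame  # unstructured eta, per cell
    lambdas: tuple[float, ...]
    donors: tuple[str, ...]
    pct_signal: float
    heritability: float
    clipping_rate: float


def _genotype_names(cfg: SimConfig) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(cfg.n_genotypes)]


def _env_names(cfg: SimConfig) -> list[str]:
    return [f"env{j + 1}" for j in range(cfg.n_envs)]


def _orthonormal_interaction(rng, cfg: SimConfig):
    """Random orthonormal alpha (G x k) and gamma (E x k), orthogonal to the
    ones vector; donor rows of alpha are exactly zero."""
    g, e, k = cfg.n_genotypes, cfg.n_envs, cfg.interaction_rank
    nd = cfg.n_donors
    a = rng.standard_normal((g - nd, k))
    a -= a.mean(axis=0, keepdims=True)
    alpha_free, _ = np.linalg.qr(a)
    alpha = np.zeros((g, k))
    alpha[nd:, :] = alpha_free[:, :k]
    b = rng.standard_normal((e, k))
    b -= b.mean(axis=0, keepdims=True)
    gamma, _ = np.linalg.qr(b)
    gamma = gamma[:, :k]
    return alpha, gamma


def planted_pct_signal(cfg: SimConfig) -> float:
    """Expected signal share of interaction SS at the configured effects."""
    df_ge = (cfg.n_genotypes - 1) * (cfg.n_envs - 1)
    sig = cfg.n_reps * sum(cfg.lambdas)
    noise = df_ge * (cfg.sigma_e ** 2 + cfg.n_reps * cfg.sigma_ge_noise ** 2)
    if sig + noise == 0:
        return float("nan")
    return 100.0 * sig / (sig + noise)


def planted_heritability(cfg: SimConfig) -> float:
    """Entry-mean H2 implied by the configured variance structure."""
    df_ge = (cfg.n_genotypes - 1) * (cfg.n_envs - 1)
    s2ge = sum(cfg.lambdas) / df_ge + cfg.sigma_ge_noise ** 2
    s2g = cfg.sigma_g ** 2
    denom = (s2g + s2ge / cfg.n_envs
             + cfg.sigma_e ** 2 / (cfg.n_envs * cfg.n_reps))
    return s2g / denom if denom > 0 else float("nan")


def simulate_met(cfg: SimConfig = SimConfig(),
                 seed: int | None = None) -> tuple[METTable, METTruth]:
    """Draw one balanced MET table plus its truth record.

    Fully reproducible: one integer seed drives a single generator stream
    in a documented order (genotype effects, then interaction axes, then
    eta, then eps).  ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    g, e, r = cfg.n_genotypes, cfg.n_envs, cfg.n_reps
    genos, envs = _genotype_names(cfg), _env_names(cfg)

    gen_eff = rng.standard_normal(g) * cfg.sigma_g
    if cfg.n_donors:
        lift = cfg.donor_lift * cfg.sigma_g
        gen_eff[: cfg.n_donors] = lift + 0.3 * cfg.sigma_g * np.abs(
            rng.standard_normal(cfg.n_donors))
    alpha, gamma = _orthonormal_interaction(rng, cfg)
    signal = (alpha * np.sqrt(np.asarray(cfg.lambdas))) @ gamma.T  # G x E
    eta = rng.standard_normal((g, e)) * cfg.sigma_ge_noise
    eps = rng.standard_normal((g, e, r)) * cfg.sigma_e

    env_eff = np.asarray(cfg.env_effects, dtype=float)
    latent = (cfg.mu + gen_eff[:, None, None] + env_eff[None, :, None]
              + signal[:, :, None] + eta[:, :, None] + eps)
    if cfg.percent:
        clipped = np.clip(latent, 0.0, 100.0)
        clipping_rate = float(np.mean(clipped != latent))
        if clipping_rate > 0.05:
            import warnings
            warnings.warn(f"{100 * clipping_rate:.1f}% of values clipped to [0, 100]; "
                          "ANOVA assumptions degrade at high clipping rates")
        values = clipped
    else:
        values = latent
        clipping_rate = 0.0

    frame = pd.DataFrame({
        "genotype": np.repeat(genos, e * r),
        "env": np.tile(np.repeat(envs, r), g),
        "rep": np.tile(np.arange(1, r + 1), g * e),
        "trait": cfg.trait,
        "value": values.ravel(),
    })
    table = METTable(frame, percent_traits=(cfg.trait,) if cfg.percent else ())
    truth = METTruth(
        mu=cfg.mu,
        genotype_effects=pd.Series(gen_eff, index=genos, name="g"),
        env_effects=pd.Series(env_eff, index=envs, name="e"),
        interaction=pd.DataFrame(signal, index=genos, columns=envs),
        interaction_noise=pd.DataFrame(eta, index=genos, columns=envs),
        lambdas=cfg.lambdas,
        donors=tuple(genos[: cfg.n_donors]),
        pct_signal=planted_pct_signal(cfg),
        heritability=planted_heritability(cfg),
        clipping_rate=clipping_rate,
    )
    return table, truth


def simulate_germination(classes: dict[str, str],
                         schedules: dict[str, dict[int, float]] | None = None,
                         total: int = 50, n_reps: int = 3, env: str = "env1",
                         assays: tuple[str, ...] = ("field", "lab"),
                         seed: int = 0) -> pd.DataFrame:
    """Cumulative binomial germination counts per genotype.

    ``classes`` maps genotype -> schedule key (dormant / non_dormant /
    intermediate, or any key of ``schedules``).  The schedule gives the
    probability a seed is still dormant at each recorded day; cumulative
    germinated counts are built by binomial thinning of the remaining
    dormant seeds, so counts are non-decreasing in day by construction.
    """
    schedules = dict(DEFAULT_SCHEDULES) if schedules is None else schedules
    rng = np.random.default_rng(seed)
    rows = []
    for geno in sorted(classes):
        sched = schedules[classes[geno]]
        days = sorted(sched)
        if any(not 0 <= sched[d] <= 1 for d in days):
            raise ValueError("dormancy probabilities must be in [0, 1]")
        for assay in assays:
            for rep in range(1, n_reps + 1):
                germinated = 0
                p_prev = 1.0
                for day in days:
                    p_day = sched[day]
                    # each still-dormant seed germinates in (prev, day] w.p.
                    # 1 - p_day/p_prev (clamped if the schedule rises)
                    p_g = 0.0 if p_prev == 0 else max(0.0, 1.0 - p_day / p_prev)
                    germinated += rng.binomial(total - germinated, p_g)
                    p_prev = min(p_prev, p_day)
                    rows.append({"genotype": geno, "env": env, "rep": rep,
                                 "assay": assay, "day": day,
                                 "germinated": germinated, "total": total})
    return pd.DataFrame(rows)


def simulate_marker_panel(classes: dict[str, str], error_rate: float = 0.0,
                          seed: int = 0) -> pd.Series:
    """Allele-specific marker calls from true dormancy classes.

    Dormant genotypes carry the positive allele, others the negative one;
    ``error_rate`` flips each call independently (assay failures /
    recombinants).
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = {}
    for geno in sorted(classes):
        call = "positive" if classes[geno] == "dormant" else "negative"
        if rng.random() < error_rate:
            call = "negative" if call == "positive" else "positive"
        calls[geno] = call
    out = pd.Series(calls, name="marker_call")
    out.index.name = "genotype"
    return out


def met_to_csv(table: METTable) -> str:
    """Canonical CSV serialisation (fixed column order, '%.10g' floats) so
    identical seeds give byte-identical files."""
    buf = io.StringIO()
    table.frame.to_csv(buf, index=False, float_format="%.10g")
    return buf.getvalue()
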