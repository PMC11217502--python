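"""Selection statistics on AMMI output: ASI, ranks, SSI, YREM.

ASI condenses a genotype's interaction scores into one distance; SSI adds
the ASI rank to the mean-performance rank so a single number rewards both
stability and level; YREM re-expresses each cell mean relative to the best
genotype of its environment, so a genotype's across-season average directly
measures the share of attainable performance lost to crossover interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError, DomainError


def rank_genotypes(values: pd.Series, direction: str = "asc") -> pd.Series:
    """Fractional (average-tie) ranks of per-genotype values.

    ``asc``: rank 1 = smallest (used for ASI, where low means stable).
    ``desc``: rank 1 = largest (used for trait means, where high is good).
    Tied values share the average of the ranks they span (6.5, 2.5, ...).
    """
    if len(values) == 0:
        raise ContractError("rank_genotypes: empty input")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ContractError("rank_genotypes: values must be finite")
    if direction == "asc":
        ranks = stats.rankdata(arr, method="average")
    elif direction == "desc":
        ranks = stats.rankdata(-arr, method="average")
    else:
        raise ValueError("direction must be 'asc' or 'desc'")
    return pd.Series(ranks, index=values.index, name="rank")


def asi(genotype_scores: pd.DataFrame, pct_interaction: np.ndarray,
        n_pcs: int) -> pd.Series:
    """AMMI stability index: sqrt(sum_k score_ik^2 * theta_k^2).

    ``theta_k`` enters as the fraction (0-1) of interaction SS on axis k;
    the sum runs over the first ``n_pcs`` (significant) axes.  Lower = more
    stable.  Invariant to axis sign flips since only squares enter.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if n_pcs > genotype_scores.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available axes "
                         f"({genotype_scores.shape[1]})")
    theta = np.asarray(pct_interaction, dtype=float)[:n_pcs] / 100.0
    sc = genotype_scores.to_numpy(float)[:, :n_pcs]
    vals = np.sqrt(np.sum(sc ** 2 * theta ** 2, axis=1))
    return pd.Series(vals, index=genotype_scores.index, name="ASI")


def ssi(r_asi, r_y):
    """Simultaneous selection index: the exact sum of the two ranks.

    Accepts scalars or aligned Series; least SSI = stable *and* high mean.
    """
    if np.any(np.asarray(r_asi) <= 0) or np.any(np.asarray(r_y) <= 0):
        raise ValueError("ranks must be positive")
    return r_asi + r_y


def stability_table(asi_values: pd.Series, means: pd.Series,
                    direction: str = "desc") -> pd.DataFrame:
    """Per-genotype ASI, mean, their ranks and SSI.

    ``direction`` ranks the means ("desc" = high mean gets rank 1, the
    default for every trait here including dormancy intensity).
    """
    asi_values, means = asi_values.align(means, join="inner")
    if asi_values.empty:
        raise ContractError("stability_table: no common genotypes")
    r_asi = rank_genotypes(asi_values, "asc")
    r_y = rank_genotypes(means, direction)
    out = pd.DataFrame({
        "ASI": asi_values, "rASI": r_asi,
        "mean": means, "rY": r_y,
        "SSI": ssi(r_asi, r_y),
    })
    out.index.name = "genotype"
    return out


def yrem(means: pd.DataFrame) -> pd.DataFrame:
    """Value relative to the environment maximum, Y_ij = X_ij / max_i X_ij.

    Input is the genotype x environment cell-means matrix (positive values).
    Output has one column per environment plus ``avg`` (across-environment
    mean YREM) and ``crossover_loss`` = 1 - avg, the fraction of attainable
    performance lost to crossover interaction.  The best genotype of each
    environment scores exactly 1 there.
    """
    mat = means.to_numpy(float)
    if np.any(mat <= 0):
        bad = means.stack()
        bad = bad[bad <= 0].index[0]
        raise DomainError(f"YREM undefined: non-positive cell mean at {bad}")
    rel = mat / mat.max(axis=0, keepdims=True)
    out = pd.DataFrame(rel, index=means.index, columns=means.columns)
    out["avg"] = out.mean(axis=1)
    out["crossover_loss"] = 1.0 - out["avg"]
    out.index.name = "genotype"
    return out
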