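"""Replicated multi-environment trial (MET) tables.

A MET table holds long-format phenotype records — one row per (genotype,
environment, replicate, trait) — from a randomized complete block design
repeated over environments (here: crop seasons).  It is the unit of input
for every downstream analysis: pooled ANOVA, AMMI, stability indices, BLUP.

The container wraps a :class:`pandas.DataFrame` with the canonical columns
``genotype, env, rep, trait, value`` and validates the design on
construction: key uniqueness, finite values, percentage bounds for declared
percentage traits, and balance (every genotype x environment cell of a trait
observed in every replicate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DesignError,
    DomainError,
    IntegrityError,
    ParseError,
    SchemaError,
)

CANONICAL_COLUMNS = ("genotype", "env", "rep", "trait", "value")

#: Default column-name mapping accepted by :func:`read_met_table`.
DEFAULT_SCHEMA = {c: c for c in CANONICAL_COLUMNS}


@dataclass(frozen=True)
class LeveneResult:
    """Levene homogeneity test of error variances across environments."""

    statistic: float
    pvalue: float
    df: tuple[int, int]
    center: str
    residual_method: str


class METTable:
    """Validated long-format MET phenotype table.

    Parameters
    ----------
    frame
        DataFrame with columns ``genotype, env, rep, trait, value``.
    percent_traits
        Trait names whose values must lie in [0, 100].
    provenance
        Transformation history, extended by :func:`log_transform`.
    """

    def __init__(self, frame: pd.DataFrame, percent_traits: tuple[str, ...] = (),
                 provenance: tuple[str, ...] = ()):
        missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        frame = frame.loc[:, list(CANONICAL_COLUMNS)].copy()
        frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
        bad = frame.index[~np.isfinite(frame["value"])]
        if len(bad):
            raise ParseError(f"non-numeric or non-finite value at rows {list(bad[:5])}")
        frame["rep"] = frame["rep"].astype(int)
        if (frame["rep"] < 1).any():
            raise IntegrityError("replicate numbers must be >= 1")
        dup = frame.duplicated(subset=["genotype", "env", "rep", "trait"])
        if dup.any():
            key = frame.loc[dup.idxmax(), ["genotype", "env", "rep", "trait"]]
            raise IntegrityError(
                "duplicate (genotype, env, rep, trait) key: " + ", ".join(map(str, key))
            )
        for t in percent_traits:
            vals = frame.loc[frame["trait"] == t, "value"]
            if ((vals < 0) | (vals > 100)).any():
                raise DomainError(f"percentage trait {t!r} has values outside [0, 100]")
        self._frame = frame.reset_index(drop=True)
        self.percent_traits = tuple(percent_traits)
        self.provenance = tuple(provenance)

    # ------------------------------------------------------------------ views
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genotypes(self) -> list:
        return sorted(self._frame["genotype"].unique().tolist())

    @property
    def environments(self) -> list:
        return sorted(self._frame["env"].unique().tolist())

    @property
    def traits(self) -> list:
        return sorted(self._frame["trait"].unique().tolist())

    def design(self, trait: str) -> tuple[int, int, int]:
        """(G, E, R) for one trait; R is the modal replicate count."""
        sub = self._trait_frame(trait)
        g = sub["genotype"].nunique()
        e = sub["env"].nunique()
        counts = sub.groupby(["genotype", "env"], observed=True).size()
        r = int(counts.mode().iat[0])
        return g, e, r

    def is_balanced(self, trait: str) -> bool:
        sub = self._trait_frame(trait)
        g, e, r = self.design(trait)
        counts = sub.groupby(["genotype", "env"], observed=True).size()
        return len(counts) == g * e and bool((counts == r).all())

    def unbalanced_cells(self, trait: str) -> list[tuple]:
        """(genotype, env) cells whose replicate count differs from the mode."""
        sub = self._trait_frame(trait)
        _, _, r = self.design(trait)
        counts = sub.groupby(["genotype", "env"], observed=True).size()
        full = pd.MultiIndex.from_product(
            [sorted(sub["genotype"].unique()), sorted(sub["env"].unique())]
        )
        counts = counts.reindex(full, fill_value=0)
        return [tuple(ix) for ix, n in counts.items() if n != r]

    def _trait_frame(self, trait: str) -> pd.DataFrame:
        sub = self._frame[self._frame["trait"] == trait]
        if sub.empty:
            raise SchemaError(f"trait {trait!r} not present in table")
        return sub

    def validation_report(self) -> dict:
        """JSON-serialisable summary: per-trait design, balance, offenders."""
        report: dict = {"n_records": int(len(self._frame)), "traits": {}}
        for t in self.traits:
            g, e, r = self.design(t)
            balanced = self.is_balanced(t)
            entry = {"G": g, "E": e, "R": r, "balanced": balanced}
            if not balanced:
                entry["offending_cells"] = [list(map(str, c)) for c in self.unbalanced_cells(t)]
            report["traits"][t] = entry
        report["provenance"] = list(self.provenance)
        return report

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"METTable({len(self._frame)} records, "
                f"{len(self.genotypes)} genotypes, {len(self.environments)} environments, "
                f"traits={self.traits})")


def read_met_table(path, schema: dict | None = None,
                   percent_traits: tuple[str, ...] = ()) -> METTable:
    """Read a long-format MET CSV into a validated :class:`METTable`.

    ``schema`` maps canonical names to the file's column names, e.g.
    ``{"env": "season"}``; unmapped names are taken verbatim.
    """
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(CANONICAL_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical columns: {sorted(unknown)}")
        mapping.update(schema)
    raw = pd.read_csv(path)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"input file lacks columns {missing}; present: {list(raw.columns)}")
    frame = raw.rename(columns={src: dst for dst, src in mapping.items()})
    return METTable(frame, percent_traits=percent_traits)


def log_transform(table: METTable, offset: float = 1.0) -> METTable:
    """Natural-log transform ``value -> ln(value + offset)`` record-wise.

    Applied before any analysis when traits need variance stabilisation; the
    transform is recorded in the table's provenance so outputs are traceable.
    """
    frame = table.frame.copy()
    shifted = frame["value"] + offset
    if (shifted <= 0).any():
        row = frame.loc[shifted.le(0).idxmax()]
        raise DomainError(
            f"value + offset <= 0 for record (genotype={row['genotype']}, "
            f"env={row['env']}, rep={row['rep']}, trait={row['trait']})"
        )
    frame["value"] = np.log(shifted)
    return METTable(frame, percent_traits=(),
                    provenance=table.provenance + (f"log(value + {offset})",))


def cell_means(table: METTable, trait: str) -> pd.DataFrame:
    """Genotype x environment matrix of replicate means X_ij.

    Requires a complete grid with equal replicate counts (the balanced RCBD
    the downstream AMMI/BLUP algebra assumes).
    """
    if not table.is_balanced(trait):
        raise DesignError(
            f"trait {trait!r} is not balanced; offending cells: "
            f"{table.unbalanced_cells(trait)[:5]}"
        )
    sub = table._trait_frame(trait)
    mat = sub.pivot_table(index="genotype", columns="env", values="value",
                          aggfunc="mean", observed=True)
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "genotype"
    mat.columns.name = "env"
    return mat


def _rcbd_residuals(values: np.ndarray) -> np.ndarray:
    """Within-environment RCBD residuals for a G x R block of data."""
    return (values
            - values.mean(axis=1, keepdims=True)
            - values.mean(axis=0, keepdims=True)
            + values.mean())


def _error_contrasts(values: np.ndarray) -> np.ndarray:
    """Project a G x R block onto its (G-1)(R-1) orthonormal error contrasts.

    The contrasts are iid N(0, sigma_j^2) under normality, which makes the
    subsequent Levene F calibrated; raw RCBD residuals are correlated and
    inflate the test.
    """
    def _basis(n: int) -> np.ndarray:
        q, _ = np.linalg.qr(np.eye(n) - 1.0 / n)
        return q[:, : n - 1]

    bg = _basis(values.shape[0])
    br = _basis(values.shape[1])
    return (bg.T @ values @ br).ravel()


def levene_homogeneity(table: METTable, trait: str, center: str = "mean",
                       residual_method: str = "contrasts") -> LeveneResult:
    """Levene test of homogeneity of error variances across environments.

    Within each environment the RCBD error is extracted (value minus genotype
    and replicate means plus the environment mean) and the classic Levene
    one-way ANOVA on absolute deviations compares environments.  With
    ``residual_method="contrasts"`` (default) each environment's residual
    space is first mapped to its orthonormal error contrasts so the group
    values are independent; ``"pooled"`` uses the raw residuals directly.
    A large p-value licenses pooling seasons into one combined analysis.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    if residual_method not in ("contrasts", "pooled"):
        raise ValueError("residual_method must be 'contrasts' or 'pooled'")
    sub = table._trait_frame(trait)
    envs = sorted(sub["env"].unique())
    if len(envs) < 2:
        raise DesignError("levene_homogeneity needs >= 2 environments")
    groups = []
    for env in envs:
        block = sub[sub["env"] == env].pivot_table(
            index="genotype", columns="rep", values="value", observed=True)
        if block.isna().any().any() or min(block.shape) < 2:
            raise DesignError(
                f"environment {env!r} lacks a complete genotype x replicate grid "
                "with >= 2 levels each")
        vals = block.to_numpy(float)
        if residual_method == "contrasts":
            groups.append(_error_contrasts(vals))
        else:
            groups.append(_rcbd_residuals(vals).ravel())
    w, p = stats.levene(*groups, center=center)
    n_total = sum(len(g) for g in groups)
    return LeveneResult(statistic=float(w), pvalue=float(p),
                        df=(len(groups) - 1, n_total - len(groups)),
                        center=center, residual_method=residual_method)
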