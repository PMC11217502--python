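"""Fresh-seed-dormancy screening: IOD, classification, marker concordance,
donor selection.

Intensity of dormancy (IOD) is the percentage of freshly harvested seeds
that have *not* germinated by a given day after sowing (day 15 or 21), in a
field or laboratory (petriplate) assay.  Genotypes are classed dormant /
non-dormant / intermediate from IOD at 21 days; an allele-specific marker
call can then be checked for concordance with the phenotypic class, and a
combined donor report selects genotypes that are dormant, stable and
superior for at least one economic trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ContractError, DomainError, IntegrityError

GERMINATION_COLUMNS = ("genotype", "env", "rep", "assay", "day",
                       "germinated", "total")

#: Dormancy classification cut-offs on IOD at 21 days after sowing (%).
DEFAULT_THRESHOLDS = (20.0, 80.0)


def _check_germination(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GERMINATION_COLUMNS if c not in records.columns]
    if missing:
        raise ContractError(f"germination table lacks columns {missing}")
    rec = records.copy()
    if (rec["germinated"] < 0).any() or (rec["germinated"] > rec["total"]).any():
        raise IntegrityError("germinated counts must satisfy 0 <= germinated <= total")
    key = ["genotype", "env", "rep", "assay"]
    for _, grp in rec.sort_values("day").groupby(key, observed=True):
        if not grp["germinated"].is_monotonic_increasing:
            name = tuple(grp.iloc[0][key])
            raise IntegrityError(
                f"cumulative germinated counts decrease over days for {name}")
    return rec


def iod(records: pd.DataFrame, day: int, assay: str | None = None) -> pd.Series:
    """Per-genotype intensity of dormancy (%) at the requested day.

    IOD = 100 * (1 - sum(germinated) / sum(total)), counts pooled over
    replicates and environments at the latest recorded day <= ``day`` (so a
    day-21 request served by day-21 records, or day-15 ones if the assay
    stopped earlier).  Pooling counts rather than averaging percentages
    keeps unequal seed totals weighted correctly.
    """
    rec = _check_germination(records)
    if assay is not None:
        rec = rec[rec["assay"] == assay]
    rec = rec[rec["day"] <= day]
    if rec.empty:
        raise ContractError(f"no germination records at or before day {day}")

    def _one(grp: pd.DataFrame) -> float:
        last = grp[grp["day"] == grp["day"].max()]
        tot = last["total"].sum()
        if tot == 0:
            raise DomainError("zero total seeds for a genotype")
        return 100.0 * (1.0 - last["germinated"].sum() / tot)

    out = rec.groupby("genotype", observed=True).apply(_one, include_groups=False)
    out.name = f"IOD{day}" + (assay[0].upper() if assay else "")
    return out


def iod_table(records: pd.DataFrame, days: tuple[int, ...] = (15, 21),
              assays: tuple[str, ...] = ("field", "lab")) -> pd.DataFrame:
    """Wide per-genotype table of IOD columns (IOD15F, IOD21F, IOD15L, ...)."""
    cols = {}
    for assay in assays:
        for day in days:
            cols[f"IOD{day}{assay[0].upper()}"] = iod(records, day, assay)
    out = pd.DataFrame(cols)
    out.index.name = "genotype"
    return out


def classify_dormancy(iod21, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS):
    """Dormancy class from IOD at 21 days after sowing.

    dormant if IOD21 > upper (default 80), non_dormant if IOD21 < lower
    (default 20), else intermediate.  Works on scalars or Series.
    """
    lower, upper = thresholds
    if not lower < upper:
        raise ValueError("thresholds must satisfy lower < upper")
    if isinstance(iod21, pd.Series):
        return pd.Series(
            np.select([iod21 > upper, iod21 < lower],
                      ["dormant", "non_dormant"], default="intermediate"),
            index=iod21.index, name="dormancy_class")
    if iod21 > upper:
        return "dormant"
    if iod21 < lower:
        return "non_dormant"
    return "intermediate"


@dataclass(frozen=True)
class ConcordanceSummary:
    """Marker vs phenotype agreement over the testable genotypes.

    Positive marker calls are expected in dormant genotypes, negative calls
    in non-dormant ones; intermediate phenotypes are untestable.  The two
    discordant directions are listed by name because they are the candidate
    recombinants / assay failures a breeder wants to inspect.
    """

    n_concordant: int
    n_discordant_marker_negative: int
    n_discordant_marker_positive: int
    n_untestable: int
    concordance: float
    discordant_marker_negative: tuple[str, ...]
    discordant_marker_positive: tuple[str, ...]


def marker_concordance(marker_calls: pd.Series,
                       dormancy_class: pd.Series) -> ConcordanceSummary:
    """Cross-classify marker calls (positive/negative) with dormancy classes."""
    calls, classes = marker_calls.align(dormancy_class, join="inner")
    if calls.empty:
        raise ContractError("no genotypes with both a marker call and a class")
    testable = classes != "intermediate"
    agree = ((calls == "positive") & (classes == "dormant")) | \
            ((calls == "negative") & (classes == "non_dormant"))
    disc_neg = testable & (calls == "negative") & (classes == "dormant")
    disc_pos = testable & (calls == "positive") & (classes == "non_dormant")
    n_testable = int(testable.sum())
    return ConcordanceSummary(
        n_concordant=int((agree & testable).sum()),
        n_discordant_marker_negative=int(disc_neg.sum()),
        n_discordant_marker_positive=int(disc_pos.sum()),
        n_untestable=int((~testable).sum()),
        concordance=float((agree & testable).sum() / n_testable) if n_testable else np.nan,
        discordant_marker_negative=tuple(sorted(calls.index[disc_neg])),
        discordant_marker_positive=tuple(sorted(calls.index[disc_pos])),
    )


@dataclass(frozen=True)
class DonorCriteria:
    """Thresholds for the combined donor report.

    min_iod
        Required IOD (%) at both day 15 and day 21 in both assays; the
        default 90 operationalises "2-3 weeks of > 90% dormancy" as
        min(IOD15, IOD21) >= 90 across field and lab.
    min_yrem
        Required across-season average YREM for the dormancy trait(s).
    max_ssi_rank
        The genotype must be within the top ``max_ssi_rank`` SSI ranks for
        at least one economic trait.
    """

    min_iod: float = 90.0
    min_yrem: float = 0.95
    max_ssi_rank: float = 10.0
    dormancy_thresholds: tuple[float, float] = DEFAULT_THRESHOLDS


def select_donors(iod_summary: pd.DataFrame,
                  stability_tables: dict[str, pd.DataFrame] | None = None,
                  yrem_tables: dict[str, pd.DataFrame] | None = None,
                  criteria: DonorCriteria = DonorCriteria()) -> pd.DataFrame:
    """Combined donor-selection report.

    Parameters
    ----------
    iod_summary
        Per-genotype IOD columns (``iod_table`` layout).
    stability_tables
        Per economic trait, a ``stability_table`` DataFrame with an ``SSI``
        column; a genotype passes if rank(SSI) <= max_ssi_rank for >= 1 trait.
    yrem_tables
        Per dormancy trait, a ``yrem`` DataFrame with an ``avg`` column; the
        minimum across the supplied traits must reach min_yrem.

    Returns one row per genotype with the per-criterion evidence and a
    boolean ``selected`` = all active criteria passed.  Criteria whose
    input is not supplied are inactive.
    """
    genos = set(iod_summary.index)
    for tbl in (stability_tables or {}).values():
        genos &= set(tbl.index)
    for tbl in (yrem_tables or {}).values():
        genos &= set(tbl.index)
    if not genos:
        raise ContractError("no genotypes common to all inputs")
    genos = sorted(genos)

    out = pd.DataFrame(index=pd.Index(genos, name="genotype"))
    iod_cols = [c for c in iod_summary.columns if c.upper().startswith("IOD")]
    min_iod = iod_summary.loc[genos, iod_cols].min(axis=1)
    iod21_cols = [c for c in iod_cols if "21" in c]
    mean_iod21 = iod_summary.loc[genos, iod21_cols].mean(axis=1)
    out["min_iod"] = min_iod
    out["mean_iod21"] = mean_iod21
    out["dormancy_class"] = classify_dormancy(mean_iod21,
                                              criteria.dormancy_thresholds)
    out["pass_dormancy"] = (out["dormancy_class"] == "dormant") & \
                           (min_iod >= criteria.min_iod)
    passes = [out["pass_dormancy"]]

    if yrem_tables:
        avg = pd.concat({t: tbl.loc[genos, "avg"] for t, tbl in yrem_tables.items()},
                        axis=1)
        out["min_avg_yrem"] = avg.min(axis=1)
        out["pass_yrem"] = out["min_avg_yrem"] >= criteria.min_yrem
        passes.append(out["pass_yrem"])
    if stability_tables:
        ranks = {}
        for t, tbl in stability_tables.items():
            from .stability import rank_genotypes
            ranks[t] = rank_genotypes(tbl.loc[genos, "SSI"], "asc")
        rank_frame = pd.concat(ranks, axis=1)
        out["best_ssi_rank"] = rank_frame.min(axis=1)
        out["best_ssi_trait"] = rank_frame.idxmin(axis=1)
        out["pass_ssi"] = out["best_ssi_rank"] <= criteria.max_ssi_rank
        passes.append(out["pass_ssi"])

    out["selected"] = np.logical_and.reduce(passes)
    return out


def donor_report_markdown(report: pd.DataFrame) -> str:
    """Render the donor report as a Markdown table (selected rows first)."""
    ordered = report.sort_values(["selected"], ascending=False).reset_index()

    def _fmt(x):
        if isinstance(x, (float, np.floating)):
            return f"{x:.2f}"
        return str(x)

    header = "| " + " | ".join(ordered.columns) + " |"
    sep = "| " + " | ".join("---" for _ in ordered.columns) + " |"
    body = ["| " + " | ".join(_fmt(v) for v in row) + " |"
            for row in ordered.itertuples(index=False)]
    return "\n".join([header, sep, *body])
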