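"""End-to-end analysis pipeline and report assembly.

Sequences the full analysis on a conforming input bundle: validation ->
(optional) log transform -> Levene homogeneity -> pooled ANOVA + AMMI +
signal/noise -> ASI/SSI stability table -> YREM -> BLUP/WAASB/quadrants per
trait, then the combined donor report when germination (and marker) data are
supplied.  Every stage writes plain CSV/JSON files and the run ends with a
machine-readable manifest carrying sha256 checksums of all inputs and
outputs, so a rerun with the same inputs and config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dormancy
from .ammi import AMMI
from .blup import BLUP
from .data import METTable, levene_homogeneity, log_transform, read_met_table
from .exceptions import MetstabError
from .simulate import (SimConfig, met_to_csv, simulate_germination,
                       simulate_marker_panel, simulate_met)
from .stability import yrem


@dataclass
class PipelineConfig:
    """Pipeline settings; round-trips losslessly through YAML."""

    met_path: str | None = None
    germination_path: str | None = None
    marker_path: str | None = None
    out_dir: str = "metstab_out"
    traits: list[str] = field(default_factory=list)  # empty = all in input
    transform: str = "none"                          # none | log1p
    alpha: float = 0.05
    asi_pcs: str = "significant"                     # significant | "2" | all
    rank_direction: str = "desc"
    donor_min_iod: float = 90.0
    donor_min_yrem: float = 0.95
    donor_max_ssi_rank: float = 10.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, index=True) -> None:
    frame.to_csv(path, index=index, float_format="%.10g")


def _asi_npcs(policy: str, result) -> int | None:
    if policy == "significant":
        return None
    if policy == "all":
        return len(result.singular_values)
    return int(policy)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json).

    Any stage failure aborts with the stage name and trait in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "inputs": {}, "outputs": {}, "stages": {}}

    if config.met_path is None:
        raise MetstabError("pipeline: no MET input path configured")
    met_path = Path(config.met_path)
    manifest["inputs"]["met"] = _sha256(met_path)
    table = read_met_table(met_path)
    traits = config.traits or table.traits

    (out / "validation.json").write_text(
        json.dumps(table.validation_report(), indent=2, sort_keys=True))

    if config.transform == "log1p":
        table = log_transform(table, offset=1.0)
    elif config.transform != "none":
        raise MetstabError(f"unknown transform {config.transform!r}")

    stability_tables: dict[str, pd.DataFrame] = {}
    yrem_tables: dict[str, pd.DataFrame] = {}
    for trait in traits:
        tdir = out / trait
        tdir.mkdir(exist_ok=True)
        stage = "levene"
        try:
            lev = levene_homogeneity(table, trait)
            res = AMMI(table, trait).fit(alpha=config.alpha)
            stage = "ammi"
            _write_csv(res.anova, tdir / "anova.csv")
            _write_csv(res.pc_table, tdir / "ammi_pcs.csv")
            scores = pd.concat([
                res.genotype_scores.assign(type="genotype"),
                res.env_scores.assign(type="environment")])
            scores.index.name = "entity"
            _write_csv(scores, tdir / "ammi_scores.csv")
            _write_csv(res.biplot_coordinates(), tdir / "biplot.csv")
            sn = res.signal_noise
            (tdir / "signal_noise.json").write_text(json.dumps({
                "levene_W": lev.statistic, "levene_p": lev.pvalue,
                "gsi_ss": sn.gsi_ss, "signal_ss": sn.signal_ss,
                "noise_ss": sn.noise_ss, "pct_signal": sn.pct_signal,
                "pct_noise": sn.pct_noise, "clamped": sn.clamped,
                "n_significant_pcs": res.n_significant}, indent=2, sort_keys=True))
            stage = "stability"
            stab = res.stability_table(n_pcs=_asi_npcs(config.asi_pcs, res),
                                       direction=config.rank_direction)
            _write_csv(stab, tdir / "stability.csv")
            stability_tables[trait] = stab
            stage = "yrem"
            ytab = yrem(res.means)
            _write_csv(ytab, tdir / "yrem.csv")
            yrem_tables[trait] = ytab
            stage = "blup"
            bres = BLUP(table, trait).fit()
            _write_csv(bres.genotype_table(), tdir / "blup.csv")
            (tdir / "genetic_stats.json").write_text(json.dumps({
                "sigma2_g": bres.variance_components.sigma2_g,
                "sigma2_ge": bres.variance_components.sigma2_ge,
                "sigma2_e": bres.variance_components.sigma2_e,
                "grand_mean": bres.variance_components.grand_mean,
                "H2": bres.heritability, "As": bres.accuracy, "CV": bres.cv},
                indent=2, sort_keys=True))
        except MetstabError as err:
            raise MetstabError(f"stage {stage!r} failed for trait {trait!r}: {err}") from err
        manifest["stages"][trait] = ["levene", "ammi", "stability", "yrem", "blup"]

    if config.germination_path:
        germ_path = Path(config.germination_path)
        manifest["inputs"]["germination"] = _sha256(germ_path)
        germ = pd.read_csv(germ_path)
        iod_tbl = dormancy.iod_table(germ)
        _write_csv(iod_tbl, out / "iod.csv")
        criteria = dormancy.DonorCriteria(
            min_iod=config.donor_min_iod, min_yrem=config.donor_min_yrem,
            max_ssi_rank=config.donor_max_ssi_rank)
        iod_traits = [t for t in yrem_tables if t.upper().startswith("IOD")]
        report = dormancy.select_donors(
            iod_tbl,
            stability_tables=stability_tables or None,
            yrem_tables={t: yrem_tables[t] for t in iod_traits} or None,
            criteria=criteria)
        if config.marker_path:
            marker_path = Path(config.marker_path)
            manifest["inputs"]["marker"] = _sha256(marker_path)
            marker = pd.read_csv(marker_path).set_index("genotype")["call"]
            calls = marker.map({1: "positive", 0: "negative"}).rename("marker_call")
            report = report.join(calls)
            conc = dormancy.marker_concordance(calls, report["dormancy_class"])
            (out / "concordance.json").write_text(json.dumps(
                dataclasses.asdict(conc), indent=2, sort_keys=True))
        _write_csv(report, out / "donor_report.csv")
        (out / "donor_report.md").write_text(
            dormancy.donor_report_markdown(report) + "\n")
        manifest["stages"]["screen"] = ["iod", "donors"]

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def simulate_bundle(out_dir, config: SimConfig = SimConfig(),
                    seed: int | None = None) -> dict:
    """Write a synthetic MET + germination + marker bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_met(config, seed=seed)
    (out / "met.csv").write_text(met_to_csv(table))
    classes = {g: ("dormant" if g in truth.donors else "non_dormant")
               for g in table.genotypes}
    germ = simulate_germination(classes, seed=(config.seed if seed is None else seed))
    germ.to_csv(out / "germination.csv", index=False)
    calls = simulate_marker_panel(classes,
                                  seed=(config.seed if seed is None else seed))
    pd.DataFrame({"genotype": calls.index,
                  "call": (calls == "positive").astype(int)}).to_csv(
        out / "marker.csv", index=False)
    truth_json = {
        "mu": truth.mu,
        "donors": list(truth.donors),
        "lambdas": list(truth.lambdas),
        "pct_signal": truth.pct_signal,
        "heritability": truth.heritability,
        "clipping_rate": truth.clipping_rate,
        "genotype_effects": truth.genotype_effects.round(10).to_dict(),
        "env_effects": truth.env_effects.round(10).to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2,
                                               sort_keys=True))
    return truth_json
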