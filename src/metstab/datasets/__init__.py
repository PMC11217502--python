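"""Bundled published summary statistics of a groundnut fresh-seed-dormancy
multi-season trial (32 genotypes — 29 Spanish-type advanced breeding lines
plus three dormant checks — over three seasons, three replicates).

Raw plot-level data for the trial were never deposited; what is bundled are
the published *summary* tables, which suffice to reproduce all inter-table
arithmetic (signal/noise partition, SSI sums, YREM averages):

``anova_summary``
    Combined AMMI ANOVA skeleton per trait: source, df, mean square and
    published percent-of-SS (main-effect rows as % of total SS, PC rows as
    % of interaction SS, as published).
``stability_ranks``
    Per genotype x dormancy trait: stability rank (rASI), mean-performance
    rank (rY) and the simultaneous selection index SSI.
``yrem_summary``
    Per genotype x trait: the three season YREM values and their published
    average.

Traits: IOD15F/IOD21F/IOD15L/IOD21L (intensity of dormancy, % not
germinated at 15/21 days after sowing, field/lab), PYLP (pod yield per
plant, g), HPW/HKW (hundred pod/kernel weight, g), SP (shelling %).
"""

from importlib import resources

import pandas as pd

__all__ = ["load_anova_summary", "load_stability_ranks", "load_yrem_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_anova_summary() -> pd.DataFrame:
    """ANOVA df / mean squares / published %SS per trait and source."""
    return _read("anova_summary.csv")


def load_stability_ranks() -> pd.DataFrame:
    """Published rASI, rY and SSI per genotype and dormancy trait."""
    return _read("stability_ranks.csv")


def load_yrem_summary() -> pd.DataFrame:
    """Published per-season YREM values and their averages."""
    return _read("yrem_summary.csv")
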