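"""Contamination-guarding OTU table filters and the final filter report.

Three filters run in a fixed order: (11) any OTU observed in a PCR
negative control is removed from the whole dataset and the control columns
dropped; (12) per-sample counts must exceed a minimum (default 2) or the
cell is zeroed; (13) an OTU's total count across the dataset must exceed a
minimum (default 5) or the OTU is dropped. "Exceed" is strict (> N) by
default; an inclusive (>= N) reading is selectable. The order matters:
zeroing small cells in step 12 lowers row totals and can push an OTU under
the step-13 cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cluster import OTUTable
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    per_sample_min: int = 2   # an OTU must EXCEED this in a sample to stay there
    dataset_min: int = 5      # an OTU must EXCEED this across all samples
    inclusive: bool = False   # True switches "exceed N" to ">= N"

    def __post_init__(self) -> None:
        if self.per_sample_min < 0 or self.dataset_min < 0:
            raise ParameterError("filter minima must be >= 0")


@dataclass
class FilterStep:
    name: str
    otus_before: int
    otus_after: int
    reads_before: int
    reads_after: int
    removed_otus: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    marker: str
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: OTUTable, after: OTUTable,
            removed: list[str]) -> None:
        self.steps.append(FilterStep(
            name, before.n_otus, after.n_otus,
            before.n_reads, after.n_reads, sorted(removed)))


def drop_negative_control_otus(table: OTUTable,
                               controls: set[str]) -> OTUTable:
    """Remove every OTU seen in any control sample; drop control columns.

    The removal is global — a single control read disqualifies the OTU in
    all samples — matching a design in which control libraries flag
    reagent or tag-jump contamination rather than quantify it.
    """
    unknown = controls - set(table.df.columns)
    if unknown:
        raise InputError(f"unknown control samples: {sorted(unknown)}")
    if not controls:
        logger.warning("%s: no negative controls supplied; step skipped",
                       table.marker)
        return table.copy_with(table.df.copy(), "negative-control filter: no controls")
    ctrl_cols = sorted(controls)
    contaminated = table.df.index[(table.df[ctrl_cols] >= 1).any(axis=1)]
    kept = table.df.drop(index=contaminated).drop(columns=ctrl_cols)
    return table.copy_with(
        kept, f"negative-control filter: removed {len(contaminated)} OTUs, "
              f"dropped columns {ctrl_cols}")


def per_sample_min_filter(table: OTUTable, per_sample_min: int,
                          inclusive: bool = False) -> OTUTable:
    """Zero cells whose count does not exceed the per-sample minimum."""
    df = table.df.copy()
    mask = df < per_sample_min if inclusive else df <= per_sample_min
    df[mask] = 0
    df = df.loc[(df.sum(axis=1) > 0)]
    return table.copy_with(
        df, f"per-sample min filter ({'>=' if inclusive else '>'}"
            f"{per_sample_min}): {table.n_otus - len(df)} OTUs emptied")


def dataset_min_filter(table: OTUTable, dataset_min: int,
                       inclusive: bool = False) -> OTUTable:
    """Drop OTUs whose dataset-wide total does not exceed the minimum."""
    totals = table.df.sum(axis=1)
    keep = totals >= dataset_min if inclusive else totals > dataset_min
    df = table.df.loc[keep]
    return table.copy_with(
        df, f"dataset min filter ({'>=' if inclusive else '>'}"
            f"{dataset_min}): removed {table.n_otus - len(df)} OTUs")


def apply_filters(table: OTUTable, controls: set[str],
                  params: FilterParams) -> tuple[OTUTable, FilterReport]:
    """Run the full 11 -> 12 -> 13 chain and build the report."""
    report = FilterReport(marker=table.marker)

    t1 = drop_negative_control_otus(table, controls)
    report.add("negative_controls", table, t1,
               [o for o in table.df.index if o not in t1.df.index])
    t2 = per_sample_min_filter(t1, params.per_sample_min, params.inclusive)
    report.add("per_sample_min", t1, t2,
               [o for o in t1.df.index if o not in t2.df.index])
    t3 = dataset_min_filter(t2, params.dataset_min, params.inclusive)
    report.add("dataset_min", t2, t3,
               [o for o in t2.df.index if o not in t3.df.index])
    return t3, report


def summarize(table_initial: OTUTable, table_final: OTUTable) -> dict:
    """Final table statistics: per-step ledger plus per-sample depths."""
    if table_initial.marker != table_final.marker:
        raise InputError("summary requires tables of the same marker")
    return {
        "marker": table_final.marker,
        "otus_initial": table_initial.n_otus,
        "otus_final": table_final.n_otus,
        "reads_initial": table_initial.n_reads,
        "reads_final": table_final.n_reads,
        "per_sample_depth": {
            s: int(table_final.df[s].sum()) for s in table_final.df.columns
        },
        "filter_log": list(table_final.log),
    }
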