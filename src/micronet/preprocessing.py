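"""Abundance tables: prevalence filtering, closure to proportions, kingdom merging.

The analysis operates on OTU-by-sample tables. Counts from different
amplicons (16S bacterioplankton, 18S microeukaryotes) are not comparable in
depth, so proportions are closed *within each kingdom block*: an
inter-kingdom table is the row-concatenation of two independently closed
compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "prevalence_filter",
    "to_relative",
    "combine_kingdoms",
]

COUNTS = "counts"
RELATIVE = "relative"


@dataclass
class AbundanceTable:
    """OTU x sample abundance matrix with per-sample group and per-OTU kingdom labels.

    Parameters
    ----------
    values
        DataFrame indexed by OTU id with sample ids as columns. Non-negative.
    mode
        ``"counts"`` (raw reads) or ``"relative"`` (proportions closed to 1
        within each kingdom block of every sample).
    kingdom
        Per-OTU kingdom label (e.g. ``"bacterioplankton"`` /
        ``"microeukaryotes"``). Defaults to a single kingdom.
    groups
        Per-sample group (zone) label; optional.
    """

    values: pd.DataFrame
    mode: str = COUNTS
    kingdom: pd.Series | None = None
    groups: pd.Series | None = None
    taxonomy: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in (COUNTS, RELATIVE):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if not self.values.index.is_unique:
            raise ValueError("OTU ids are not unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids are not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.kingdom is None:
            self.kingdom = pd.Series("bacterioplankton", index=self.values.index)
        else:
            self.kingdom = self.kingdom.reindex(self.values.index)
            if self.kingdom.isna().any():
                missing = list(self.kingdom.index[self.kingdom.isna()][:5])
                raise ValueError(f"kingdom label missing for OTUs {missing}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = list(self.groups.index[self.groups.isna()][:5])
                raise ValueError(f"group label missing for samples {missing}")

    # -- convenience ------------------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_otus(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def mean_abundance(self) -> pd.Series:
        """Per-OTU mean relative abundance in percent (requires relative mode)."""
        if self.mode != RELATIVE:
            raise ValueError("mean_abundance requires a relative-mode table")
        return 100.0 * self.values.mean(axis=1)

    def select_group(self, group: str) -> "AbundanceTable":
        """Restrict to the samples of one group."""
        if self.groups is None:
            raise ValueError("table has no group labels")
        cols = self.values.columns[self.groups == group]
        if len(cols) == 0:
            known = sorted(self.groups.unique())
            raise ValueError(f"unknown group {group!r}; known groups: {known}")
        return replace(
            self,
            values=self.values[cols],
            groups=self.groups[cols],
        )

    # instance-method spellings of the module-level operations
    def prevalence_filter(self, group: str | None = None, min_prevalence: int = 8):
        return prevalence_filter(self, group=group, min_prevalence=min_prevalence)

    def to_relative(self):
        return to_relative(self)


def prevalence_filter(
    table: AbundanceTable, group: str | None = None, min_prevalence: int = 8
) -> AbundanceTable:
    """Keep only OTUs present (count > 0) in at least ``min_prevalence`` samples.

    When ``group`` is given the sample set is first restricted to that group
    and prevalence is evaluated there; this is the per-zone reliability filter
    (default 8 of 10 samples).
    """
    if table.mode != COUNTS:
        raise ValueError("prevalence_filter expects a counts-mode table")
    if group is not None:
        table = table.select_group(group)
    if min_prevalence > table.n_samples:
        raise ValueError(
            f"min_prevalence={min_prevalence} exceeds group size {table.n_samples}"
        )
    present = (table.values > 0).sum(axis=1)
    keep = present[present >= min_prevalence].index
    return replace(
        table,
        values=table.values.loc[keep],
        kingdom=table.kingdom.loc[keep],
        taxonomy=None if table.taxonomy is None else table.taxonomy.loc[
            table.taxonomy.index.intersection(keep)
        ],
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to proportions, closing to 1 within each kingdom block."""
    if table.mode != COUNTS:
        raise ValueError("to_relative expects a counts-mode table")
    values = table.values.astype(float).copy()
    for kingdom in table.kingdom.unique():
        rows = table.kingdom[table.kingdom == kingdom].index
        block = values.loc[rows]
        totals = block.sum(axis=0)
        zero = totals[totals <= 0]
        if len(zero):
            raise ValueError(
                f"zero total for kingdom {kingdom!r} in sample(s) {list(zero.index)}"
            )
        values.loc[rows] = block / totals
    return replace(table, values=values, mode=RELATIVE)


def combine_kingdoms(bact: AbundanceTable, euk: AbundanceTable) -> AbundanceTable:
    """Row-concatenate two relative-mode kingdom tables over the same samples.

    The result carries both kingdom labels so that downstream edges can be
    classified as intra- vs inter-kingdom.
    """
    for t in (bact, euk):
        if t.mode != RELATIVE:
            raise ValueError("combine_kingdoms expects relative-mode tables")
    if set(bact.sample_ids) != set(euk.sample_ids):
        only_a = sorted(set(bact.sample_ids) - set(euk.sample_ids))
        only_b = sorted(set(euk.sample_ids) - set(bact.sample_ids))
        raise ValueError(
            f"sample ids differ between tables: only in first {only_a}, only in second {only_b}"
        )
    euk_vals = euk.values[bact.sample_ids]
    overlap = bact.otu_ids.intersection(euk.otu_ids)
    if len(overlap):
        raise ValueError(f"OTU ids shared between kingdoms: {list(overlap[:5])}")
    values = pd.concat([bact.values, euk_vals])
    kingdom = pd.concat([bact.kingdom, euk.kingdom.loc[euk.otu_ids]])
    taxonomy = None
    if bact.taxonomy is not None and euk.taxonomy is not None:
        taxonomy = pd.concat([bact.taxonomy, euk.taxonomy])
    return AbundanceTable(
        values=values,
        mode=RELATIVE,
        kingdom=kingdom,
        groups=bact.groups,
        taxonomy=taxonomy,
    )
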