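"""Core in-memory containers shared across pipeline stages.

All tabular data are pandas objects: counts and expression matrices are
gene x sample DataFrames, sample metadata is a DataFrame indexed by
sample id.  Containers validate their invariants on construction so that
downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every cohort table must carry
REQUIRED_META_COLUMNS = (
    "individual_id",
    "line_id",
    "differentiation_id",
    "day",
    "form",
    "diagnosis",
    "sex",
    "batch",
)

CONTROL = "control"


@dataclass
class CohortCounts:
    """Gene x sample integer counts with nested sample metadata.

    ``samples`` is indexed by sample id; every column of ``counts`` must
    have a metadata row and vice versa.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts contain negative entries")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        missing = set(self.samples.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"metadata samples missing from counts: {sorted(missing)[:5]}")
        for col in REQUIRED_META_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        # diagnosis = control iff form = control
        is_ctrl_form = self.samples["form"] == CONTROL
        is_ctrl_dx = self.samples["diagnosis"] == CONTROL
        if (is_ctrl_form != is_ctrl_dx).any():
            raise ValueError("diagnosis must be 'control' exactly for control-form samples")
        # keep columns aligned with metadata order
        self.counts = self.counts.loc[:, self.samples.index]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids) -> "CohortCounts":
        sample_ids = list(sample_ids)
        return CohortCounts(
            counts=self.counts.loc[:, sample_ids],
            samples=self.samples.loc[sample_ids],
            warnings=list(self.warnings),
        )

    def subset_genes(self, genes) -> "CohortCounts":
        return CohortCounts(
            counts=self.counts.loc[list(genes)],
            samples=self.samples,
            warnings=list(self.warnings),
        )


@dataclass
class ExprMatrix:
    """Normalized log2-CPM expression (gene x sample) plus TMM factors."""

    values: pd.DataFrame
    norm_factors: pd.Series
    offset: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression matrix contains non-finite entries")
        gm = np.exp(np.mean(np.log(self.norm_factors.values)))
        if abs(gm - 1.0) > 1e-6:
            raise ValueError(f"norm factors must have geometric mean 1 (got {gm:.6g})")


@dataclass
class ModuleSet:
    """Gene -> module labels with eigengenes and kME.

    Label 0 denotes unassigned genes.  ``eigengenes`` is sample x module
    ("M1", "M2", ...), ``kme`` is gene x module Pearson correlation with
    each eigengene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame

    def __post_init__(self) -> None:
        mods = sorted(set(self.labels) - {0})
        expected = [f"M{m}" for m in mods]
        if list(self.eigengenes.columns) != expected:
            raise ValueError("eigengene columns must be M<label> for every non-empty module")

    def module_genes(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.labels) - {0})


@dataclass
class IpmsTable:
    """Bait x prey logFC table from IP-MS; zeros mean not detected/enriched."""

    logfc: pd.DataFrame  # baits (rows) x universe (columns)

    def __post_init__(self) -> None:
        missing = set(self.logfc.index) - set(self.logfc.columns)
        if missing:
            raise ValueError(f"baits not in detected universe: {sorted(missing)}")

    @property
    def baits(self) -> pd.Index:
        return self.logfc.index

    @property
    def universe(self) -> pd.Index:
        return self.logfc.columns


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a universe; dropped genes are counted."""

    sets: dict[str, set]
    universe: set
    n_dropped: dict[str, int] = field(default_factory=dict)

    @classmethod
    def harmonize(cls, sets: dict, universe) -> "GeneSetCollection":
        universe = set(universe)
        out, dropped = {}, {}
        for name, genes in sets.items():
            genes = set(genes)
            out[name] = genes & universe
            dropped[name] = len(genes - universe)
        return cls(sets=out, universe=universe, n_dropped=dropped)
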