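"""Core in-memory containers shared across the pipeline.

The analysis operates on a normalized log2 expression matrix with probe
biotypes (lncRNA vs mRNA) and a two-group sample design (case vs control),
genomic loci for probes, and gene-set collections. Containers validate their
invariants on construction so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LNCRNA = "lncRNA"
MRNA = "mRNA"
CASE = "case"
CONTROL = "control"

VALID_BIOTYPES = frozenset({LNCRNA, MRNA})
VALID_GROUPS = frozenset({CASE, CONTROL})
VALID_STRANDS = frozenset({"+", "-", "unknown"})


class ValidationError(ValueError):
    """Raised when an input container or file violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, probes x samples, with probe and sample labels.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities; index = probe ids (unique),
        columns = sample ids (unique).
    biotype
        Series mapping each probe id to ``"lncRNA"`` or ``"mRNA"``.
    group
        Series mapping each sample id to ``"case"`` or ``"control"``;
        each group must contain at least 2 samples.
    """

    values: pd.DataFrame
    biotype: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe id(s): {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample id(s): {list(dups[:5])}")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()][:5]
            raise ValidationError(f"probe(s) without biotype: {list(missing)}")
        bad = set(self.biotype.unique()) - VALID_BIOTYPES
        if bad:
            raise ValidationError(f"unknown biotype value(s): {sorted(bad)}")
        self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()][:5]
            raise ValidationError(f"sample(s) without group: {list(missing)}")
        bad = set(self.group.unique()) - VALID_GROUPS
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        for g in (CASE, CONTROL):
            n = int((self.group == g).sum())
            if n < 2:
                raise ValidationError(f"group {g!r} has {n} sample(s); need >= 2")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_ids(self) -> pd.Index:
        return self.group.index[self.group == CASE]

    @property
    def control_ids(self) -> pd.Index:
        return self.group.index[self.group == CONTROL]

    def probes_of(self, biotype: str) -> pd.Index:
        return self.biotype.index[self.biotype == biotype]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a probe, BED convention (0-based, half-open)."""

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError(f"{self.probe_id}: empty chromosome name")
        if self.start < 0:
            raise ValidationError(f"{self.probe_id}: negative start {self.start}")
        if not self.start < self.end:
            raise ValidationError(
                f"{self.probe_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.probe_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (one GMT line)."""

    set_id: str
    description: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)
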