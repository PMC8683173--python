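"""Readers and writers for the file formats the pipeline touches.

Expression matrices travel as TSV (probes as rows, first column the probe
id, header row the sample ids), sample metadata and results as CSV, probe
loci as BED (0-based half-open), gene sets as GMT, and networks as SIF or
GraphML for Cytoscape. Parsers reject malformed input rather than coercing
it; every error message names the offending row, column or id.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .containers import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneLocus,
    GeneSet,
    ValidationError,
)

log = logging.getLogger(__name__)

# default raw labels in sample metadata, per the two-constitution study design
DEFAULT_CASE_LABEL = "PDC"
DEFAULT_CONTROL_LABEL = "BC"


class ParseError(ValidationError):
    """Malformed input file."""


def read_expression(
    tsv_path: str | Path,
    metadata_path: str | Path,
    *,
    case_label: str = DEFAULT_CASE_LABEL,
    control_label: str = DEFAULT_CONTROL_LABEL,
    drop_incomplete_probes: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV plus sample-metadata CSV into a matrix.

    The TSV must carry a ``probe_id`` first column, a ``biotype`` column
    (``lncRNA``/``mRNA``) and one numeric column per sample. The metadata CSV
    must have ``sample_id`` and ``group`` columns covering every sample.
    Missing values are rejected unless ``drop_incomplete_probes`` is set, in
    which case probes with any missing entry are dropped with a warning.
    """
    tsv_path, metadata_path = Path(tsv_path), Path(metadata_path)
    df = pd.read_csv(tsv_path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"{tsv_path}: need probe_id, biotype and sample columns")
    first = df.columns[0]
    df = df.rename(columns={first: "probe_id"})
    if "biotype" not in df.columns:
        raise ParseError(f"{tsv_path}: missing 'biotype' column")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{tsv_path}: duplicate probe id {dup!r}")
    df = df.set_index("probe_id")
    biotype = df.pop("biotype")

    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna()
    if bad.to_numpy().any():
        probe = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[probe]][0]
        raise ParseError(
            f"{tsv_path}: non-numeric value at probe {probe!r}, sample {col!r}"
        )
    if values.isna().to_numpy().any():
        if drop_incomplete_probes:
            n0 = len(values)
            keep = values.notna().all(axis=1)
            values, biotype = values[keep], biotype[keep]
            warnings.warn(
                f"dropped {n0 - len(values)} probe(s) with missing values",
                stacklevel=2,
            )
        else:
            probe = values.index[values.isna().any(axis=1)][0]
            raise ParseError(
                f"{tsv_path}: missing value for probe {probe!r} "
                "(pass drop_incomplete_probes=True to drop such probes)"
            )

    meta = pd.read_csv(metadata_path, dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ParseError(f"{metadata_path}: missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{metadata_path}: duplicate sample id {dup!r}")
    meta = meta.set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ParseError(f"{metadata_path}: no group for sample(s) {missing[:5]}")
    mapping = {case_label: CASE, control_label: CONTROL, CASE: CASE, CONTROL: CONTROL}
    raw = meta.loc[values.columns, "group"]
    unknown = sorted(set(raw) - set(mapping))
    if unknown:
        raise ParseError(
            f"{metadata_path}: unknown group label(s) {unknown}; expected "
            f"{case_label!r} or {control_label!r}"
        )
    group = raw.map(mapping)
    return ExpressionMatrix(values=values, biotype=biotype, group=group)


def write_expression(matrix: ExpressionMatrix, tsv_path, metadata_path) -> None:
    """Write a matrix back to the TSV + metadata CSV pair (6 sig. digits)."""
    out = matrix.values.copy()
    out.insert(0, "biotype", matrix.biotype)
    out.index.name = "probe_id"
    out.to_csv(tsv_path, sep="\t", float_format="%.6g")
    meta = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.group.values})
    meta.to_csv(metadata_path, index=False)


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Read BED3+ with a name column into loci; strand from column 6 if present."""
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: need at least 4 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from None
            strand = fields[5] if len(fields) >= 6 else "unknown"
            if strand not in ("+", "-"):
                strand = "unknown"
            try:
                loci.append(GeneLocus(name, chrom, start, end, strand))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return loci


def write_bed(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            strand = loc.strand if loc.strand in ("+", "-") else "."
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.probe_id}\t0\t{strand}\n"
            )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: ``set_id<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are collapsed with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m]
            uniq = frozenset(members)
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {set_id!r} has duplicate members; collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id, desc, uniq))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def write_network(network, path: str | Path, format: str = "sif") -> None:
    """Export a coexpression network for Cytoscape.

    SIF: one ``lncID<TAB>coexp<TAB>mrnaID`` line per edge. GraphML carries
    node attributes (biotype, direction, degree) and edge attributes (pcc, p).
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for row in network.edges.itertuples(index=False):
                fh.write(f"{row.lnc_id}\tcoexp\t{row.mrna_id}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_graph(), path)
    else:
        raise ValueError(f"unknown network format {format!r}; use 'sif' or 'graphml'")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table CSV with columns sample_id, group, gene, ct."""
    df = pd.read_csv(path)
    required = ["sample_id", "group", "gene", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or not (ct > 0).all():
        row = df.index[~(ct > 0)][0]
        raise ParseError(f"{path}: row {row}: ct must be a positive number")
    df = df.copy()
    df["ct"] = ct
    dup = df.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pair = df.loc[dup, ["sample_id", "gene"]].iloc[0]
        raise ParseError(
            f"{path}: duplicate record for sample {pair.sample_id!r}, "
            f"gene {pair.gene!r} (average technical replicates upstream)"
        )
    return df[required]
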