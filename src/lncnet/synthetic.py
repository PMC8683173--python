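"""Synthetic two-group expression study generator with known ground truth.

Emulates the design of a 13-case vs 9-control peripheral-blood array study
profiling lncRNA and mRNA probes on the log2 scale: null probes are i.i.d.
Normal(baseline, noise_sd^2) in both groups, planted DE probes have group
means differing by ``planted_log2fc`` with a recorded sign, and planted
lncRNA-mRNA pairs are drawn from a bivariate normal with correlation
``planted_rho`` (correlation induced across all samples BEFORE group effects
are added, so it is a within-population correlation, not an artifact of the
group shift). A subset of the linked pairs is additionally co-located within
the cis window on the same chromosome; every other gene is placed with
inter-gene spacing strictly greater than the window, so the truth table's
cis labels agree exactly with a brute-force distance scan.

All randomness flows from the single config seed; each generator consumes
its own child stream (expression 0, annotation 1, qPCR 2, gene sets 3) in a
fixed documented order, so outputs are bit-identical for a given seed
regardless of which generators are called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CASE,
    CONTROL,
    LNCRNA,
    MRNA,
    ExpressionMatrix,
    GeneLocus,
    GeneSet,
    ValidationError,
)
from . import io as lio

# default probe counts: 10% of the 22,621 lncRNA / 31,860 mRNA probes of the
# emulated array, with DE counts scaled from the study's 398/437 DE calls
DEFAULT_GENOME = (("chr1", 600_000_000), ("chr2", 600_000_000), ("chr3", 600_000_000))

# validation-cohort group sizes (independent of the array cohort)
QPCR_N_CASE = 9
QPCR_N_CONTROL = 12

REFERENCE_GENE = "ACTB"


class CapacityError(ValidationError):
    """Genome too small to honor the placement constraints."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design constants for the synthetic generators (log2 scale)."""

    n_case: int = 13
    n_control: int = 9
    n_lnc: int = 2262
    n_mrna: int = 3186
    n_de_lnc: int = 40
    n_de_mrna: int = 44
    planted_log2fc: float = 1.5
    noise_sd: float = 0.5
    n_linked_pairs: int = 30
    planted_rho: float = 0.85
    n_cis_pairs: int = 5
    genome: tuple = DEFAULT_GENOME
    window_bp: int = 300_000
    baseline: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_lnc": self.n_lnc,
            "n_mrna": self.n_mrna,
            "n_de_lnc": self.n_de_lnc,
            "n_de_mrna": self.n_de_mrna,
            "n_linked_pairs": self.n_linked_pairs,
            "n_cis_pairs": self.n_cis_pairs,
            "window_bp": self.window_bp,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        if self.n_de_lnc > self.n_lnc:
            raise ValidationError("n_de_lnc exceeds n_lnc")
        if self.n_de_mrna > self.n_mrna:
            raise ValidationError("n_de_mrna exceeds n_mrna")
        if self.n_cis_pairs > self.n_linked_pairs:
            raise ValidationError("n_cis_pairs exceeds n_linked_pairs")
        if not 0 <= self.planted_rho < 1:
            raise ValidationError(f"planted_rho must be in [0, 1), got {self.planted_rho}")
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.n_linked_pairs > min(self.n_lnc, self.n_mrna):
            raise ValidationError("n_linked_pairs exceeds available probes")
        if not self.genome:
            raise ValidationError("genome must be non-empty")


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests.

    ``de``: DataFrame indexed by probe_id with columns biotype and direction
    (+1/-1). ``linked``: DataFrame with lnc_id, mrna_id, rho, is_cis.
    """

    de: pd.DataFrame
    linked: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["lnc_id", "mrna_id", "rho", "is_cis"]
        )
    )

    @property
    def cis_pairs(self) -> pd.DataFrame:
        return self.linked[self.linked["is_cis"]].reset_index(drop=True)

    def direction_of(self, probe_id: str) -> int:
        if probe_id in self.de.index:
            return int(self.de.loc[probe_id, "direction"])
        return 0


def _probe_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:06d}" for i in range(1, config.n_lnc + 1)]
    mrna = [f"MRNA{i:06d}" for i in range(1, config.n_mrna + 1)]
    return lnc, mrna


def _sample_ids(n_case: int, n_control: int, prefix: str = "") -> tuple[list, list]:
    case = [f"{prefix}PDC{i:02d}" for i in range(1, n_case + 1)]
    control = [f"{prefix}BC{i:02d}" for i in range(1, n_control + 1)]
    return case, control


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Generate the expression matrix and its ground-truth table.

    Stream-consumption order (fixed): DE lncRNA selection and directions, DE
    mRNA selection and directions, linked-pair selection, base matrix draw,
    correlated-pair draw. Linked pairs are taken from the planted DE probes
    of each biotype when enough exist (so they survive the DE screen and can
    enter the network), otherwise from null probes; paired DE probes share
    their direction so the planted positive correlation is preserved across
    the pooled sample set.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lnc_ids, mrna_ids = _probe_ids(config)
    case_ids, control_ids = _sample_ids(config.n_case, config.n_control)
    probes = lnc_ids + mrna_ids
    samples = case_ids + control_ids
    n_samples = len(samples)

    de_lnc = list(rng.choice(lnc_ids, size=config.n_de_lnc, replace=False))
    dir_lnc = rng.choice([-1, 1], size=config.n_de_lnc)
    de_mrna = list(rng.choice(mrna_ids, size=config.n_de_mrna, replace=False))
    dir_mrna = rng.choice([-1, 1], size=config.n_de_mrna)
    direction = dict(zip(de_lnc, dir_lnc)) | dict(zip(de_mrna, dir_mrna))

    # linked pairs come from the planted DE probes when both biotypes have
    # enough of them (so pairs pass the DE screen and can enter the network);
    # otherwise from null probes (pure-correlation scenarios)
    if config.n_linked_pairs:
        use_de = (
            config.n_de_lnc >= config.n_linked_pairs
            and config.n_de_mrna >= config.n_linked_pairs
        )
        lnc_pool = de_lnc if use_de else [p for p in lnc_ids if p not in direction]
        mrna_pool = de_mrna if use_de else [p for p in mrna_ids if p not in direction]
        pair_lnc = list(rng.choice(lnc_pool, size=config.n_linked_pairs, replace=False))
        pair_mrna = list(
            rng.choice(mrna_pool, size=config.n_linked_pairs, replace=False)
        )
        if use_de:  # align signs so the pooled-sample correlation stays positive
            for a, b in zip(pair_lnc, pair_mrna):
                direction[b] = direction[a]
    else:
        pair_lnc, pair_mrna = [], []

    values = rng.normal(config.baseline, config.noise_sd, size=(len(probes), n_samples))
    index = {p: i for i, p in enumerate(probes)}
    rho = config.planted_rho
    for a, b in zip(pair_lnc, pair_mrna):
        z1 = rng.standard_normal(n_samples)
        z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n_samples)
        values[index[a]] = config.baseline + config.noise_sd * z1
        values[index[b]] = config.baseline + config.noise_sd * z2

    n_case = len(case_ids)
    for probe, sign in direction.items():
        values[index[probe], :n_case] += sign * config.planted_log2fc

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        biotype=pd.Series(
            [LNCRNA] * len(lnc_ids) + [MRNA] * len(mrna_ids), index=probes
        ),
        group=pd.Series(
            [CASE] * len(case_ids) + [CONTROL] * len(control_ids), index=samples
        ),
    )
    de_table = pd.DataFrame(
        {
            "biotype": [LNCRNA if p in set(de_lnc) else MRNA for p in direction],
            "direction": list(direction.values()),
        },
        index=pd.Index(direction.keys(), name="probe_id"),
    )
    linked = pd.DataFrame(
        {
            "lnc_id": pair_lnc,
            "mrna_id": pair_mrna,
            "rho": rho,
            "is_cis": [i < config.n_cis_pairs for i in range(len(pair_lnc))],
        }
    )
    return matrix, TruthTable(de=de_table, linked=linked)


def generate_annotation(
    config: SyntheticConfig, truth: TruthTable
) -> list[GeneLocus]:
    """Assign every probe a genomic locus honoring the truth table.

    Designated cis pairs sit on one chromosome at a gap uniform in
    [0, window_bp]; non-cis linked pairs go to different chromosomes; all
    other placements keep an inter-gene gap strictly greater than the window,
    so the only within-window lncRNA-mRNA pairs anywhere in the annotation
    are the planted cis pairs.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    lnc_ids, mrna_ids = _probe_ids(config)
    chroms = [name for name, _ in config.genome]
    lengths = dict(config.genome)
    cursor = {c: 0 for c in chroms}
    loci: dict[str, GeneLocus] = {}

    def place(probe_id: str, chrom: str, extra_gap: int | None = None) -> None:
        """Place one gene at the chromosome cursor, then advance past the window."""
        length = int(rng.integers(500, 5001))
        start = cursor[chrom] if extra_gap is None else cursor[chrom] + extra_gap
        end = start + length
        if end > lengths[chrom]:
            raise CapacityError(
                f"genome too small: {chrom} exhausted at {start} bp "
                f"(length {lengths[chrom]})"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        loci[probe_id] = GeneLocus(probe_id, chrom, start, end, strand)
        # spacing > window_bp guarantees no accidental cis pair
        cursor[chrom] = end + config.window_bp + int(rng.integers(1000, 10_001))

    linked = truth.linked
    chrom_cycle = 0
    for row in linked.itertuples(index=False):
        c = chroms[chrom_cycle % len(chroms)]
        if row.is_cis:
            place(row.lnc_id, c)
            gap = int(rng.integers(0, config.window_bp + 1))
            # rewind: mrna goes gap bp after the lnc's end, inside the window
            cursor[c] = loci[row.lnc_id].end + gap
            place(row.mrna_id, c)
        else:
            c2 = chroms[(chrom_cycle + 1) % len(chroms)]
            if c2 == c:
                raise CapacityError("need >= 2 chromosomes for non-cis linked pairs")
            place(row.lnc_id, c)
            place(row.mrna_id, c2)
        chrom_cycle += 1

    placed = set(loci)
    for i, probe in enumerate(p for p in lnc_ids + mrna_ids if p not in placed):
        place(probe, chroms[(chrom_cycle + i) % len(chroms)])
    order = {p: i for i, p in enumerate(lnc_ids + mrna_ids)}
    return sorted(loci.values(), key=lambda l: order[l.probe_id])


def generate_qpcr(
    config: SyntheticConfig,
    truth: TruthTable,
    targets: Sequence[str],
    *,
    n_case: int = QPCR_N_CASE,
    n_control: int = QPCR_N_CONTROL,
    noise_sd: float = 0.0,
    base_ct: float = 25.0,
    ref_ct: float = 18.0,
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Generate a qPCR Ct table for ``targets`` plus the reference gene.

    Emulates an independent validation cohort (defaults 9 cases vs 12
    controls). A planted-DE target's Ct is shifted by -direction *
    planted_log2fc in the case group (Ct falls as abundance rises); a
    per-sample loading shift applies to every gene of that sample and
    cancels in dCt. ``noise_sd`` (cycles) adds measurement noise; at 0 the
    planted fold changes are recovered exactly.
    """
    config.validate()
    known = set(truth.de.index) | set(truth.linked["lnc_id"]) | set(
        truth.linked["mrna_id"]
    )
    lnc_ids, mrna_ids = _probe_ids(config)
    known |= set(lnc_ids) | set(mrna_ids)
    for t in targets:
        if t not in known:
            raise ValidationError(f"unknown qPCR target {t!r}")
    rng = np.random.default_rng([config.seed, 2])
    case_ids, control_ids = _sample_ids(n_case, n_control, prefix="q")
    rows = []
    for sample, group in [(s, CASE) for s in case_ids] + [
        (s, CONTROL) for s in control_ids
    ]:
        shift = rng.normal(0.0, noise_sd) if noise_sd else 0.0
        ref = ref_ct + shift + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        rows.append((sample, group, reference_gene, ref))
        for t in targets:
            ct = base_ct + shift
            if group == CASE:
                ct -= truth.direction_of(t) * config.planted_log2fc
            if noise_sd:
                ct += rng.normal(0.0, noise_sd)
            rows.append((sample, group, t, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


def generate_gene_sets(
    config: SyntheticConfig,
    truth: TruthTable,
    *,
    n_sets: int = 20,
    set_size: int = 15,
) -> list[GeneSet]:
    """Gene sets over the mRNA universe, two of them enriched in planted DE.

    ``SET_UP``/``SET_DOWN`` mix planted up-/downregulated mRNAs with random
    background genes; the remaining sets are random draws, giving the ORA
    stage both true positives and a null background.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    _, mrna_ids = _probe_ids(config)
    de_mrna = truth.de[truth.de["biotype"] == MRNA]
    up = list(de_mrna.index[de_mrna["direction"] > 0])
    down = list(de_mrna.index[de_mrna["direction"] < 0])
    sets: list[GeneSet] = []

    def planted_set(name: str, members_de: list[str]) -> GeneSet:
        core = list(
            rng.choice(members_de, size=min(len(members_de), set_size // 2), replace=False)
        )
        background = [m for m in mrna_ids if m not in core]
        filler = list(
            rng.choice(background, size=max(set_size - len(core), 0), replace=False)
        )
        return GeneSet(name, f"planted {name.lower()}", frozenset(core + filler))

    if up:
        sets.append(planted_set("SET_UP", up))
    if down:
        sets.append(planted_set("SET_DOWN", down))
    for i in range(len(sets), n_sets):
        members = rng.choice(mrna_ids, size=set_size, replace=False)
        sets.append(GeneSet(f"SET_{i + 1:03d}", "random background", frozenset(members)))
    return sets


def write_bundle(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle for the pipeline.

    Writes expression.tsv, samples.csv, loci.bed, gene_sets.gmt, qpcr.csv,
    truth_de.csv and truth_pairs.csv under ``out_dir``; qPCR targets are the
    planted cis-pair genes (the analogue of validating the final candidate
    pairs). Returns a name -> path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    loci = generate_annotation(config, truth)
    cis = truth.cis_pairs
    targets = list(cis["lnc_id"]) + list(cis["mrna_id"])
    if not targets:  # fall back to a few planted DE probes
        targets = list(truth.de.index[:4])
    qpcr = generate_qpcr(config, truth, targets)
    sets = generate_gene_sets(config, truth)

    paths = {
        "expression": out_dir / "expression.tsv",
        "metadata": out_dir / "samples.csv",
        "bed": out_dir / "loci.bed",
        "gmt": out_dir / "gene_sets.gmt",
        "qpcr": out_dir / "qpcr.csv",
        "truth_de": out_dir / "truth_de.csv",
        "truth_pairs": out_dir / "truth_pairs.csv",
    }
    lio.write_expression(matrix, paths["expression"], paths["metadata"])
    lio.write_bed(loci, paths["bed"])
    lio.write_gmt(sets, paths["gmt"])
    qpcr.to_csv(paths["qpcr"], index=False)
    truth.de.to_csv(paths["truth_de"])
    truth.linked.to_csv(paths["truth_pairs"], index=False)
    return paths
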