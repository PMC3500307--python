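"""Supermatrix occupancy auditing.

A concatenated ("supermatrix") alignment is audited against its partition
table: which taxa have data for which loci, how full the taxa x columns
grid is, and which taxa hang on a single locus.  A taxon *has* a locus iff
its slice of that partition contains at least one non-missing character.

Missing characters default to ``- ? N n X x`` (gap / unknown); IUPAC
ambiguity codes (R, Y, ...) count as data.  The set is configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "Locus",
    "OccupancyMatrix",
    "OccupancySummary",
    "load_matrix",
    "occupancy_summary",
    "summary_from_counts",
    "completeness_fraction",
    "singleton_report",
    "parse_partition_file",
    "round1",
]

DEFAULT_MISSING = frozenset("-?NnXx")


@dataclass(frozen=True)
class Locus:
    """Half-open 0-based column interval [start, end) of one partition."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OccupancyMatrix:
    """Per-(taxon, locus) counts of non-missing characters."""

    taxa: list[str]
    loci: list[Locus]
    cells: np.ndarray  # shape (n_taxa, n_loci), int counts
    n_columns: int

    def __post_init__(self):
        if self.cells.shape != (len(self.taxa), len(self.loci)):
            raise ValueError("cells shape does not match taxa x loci")
        lengths = np.array([l.length for l in self.loci])
        if (self.cells > lengths[None, :]).any():
            raise ValueError("cell count exceeds locus length")

    @property
    def presence(self) -> np.ndarray:
        """Boolean taxon-has-locus grid (>= 1 non-missing character)."""
        return self.cells > 0


@dataclass
class OccupancySummary:
    n_taxa: int
    n_columns: int
    total_cells: int
    filled_cells: int
    percent_filled: float
    mean_nucleotides_per_taxon: float
    taxa_per_locus: dict = field(default_factory=dict)
    mean_taxa_per_locus: float = float("nan")
    loci_per_taxon: dict = field(default_factory=dict)
    mean_loci_per_taxon: float = float("nan")


def round1(x: float) -> float:
    """Round half-up to one decimal, as printed summaries do."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_PARTITION_RE = re.compile(
    r"^\s*(?:[A-Za-z0-9]+)\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$"
)


def parse_partition_file(text: str, alignment_length: int | None = None) -> list[Locus]:
    """RAxML-style partition lines ``DNA, name = start-end`` (1-based inclusive).

    Intervals must tile ``[0, alignment_length)`` without overlap when the
    alignment length is supplied.
    """
    loci = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise ValueError(f"cannot parse partition line {lineno}: {raw!r}")
        name, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        if end < start:
            raise ValueError(f"partition {name!r}: end < start")
        loci.append(Locus(name, start - 1, end))  # to 0-based half-open
    loci.sort(key=lambda l: l.start)
    prev_end = 0
    for l in loci:
        if l.start < prev_end:
            raise ValueError(f"overlapping partitions at {l.name!r}")
        prev_end = l.end
    if alignment_length is not None:
        covered = sum(l.length for l in loci)
        if prev_end > alignment_length:
            raise ValueError("partition extends beyond alignment")
        if covered != alignment_length or (loci and loci[0].start != 0):
            raise ValueError(
                f"partitions cover {covered} of {alignment_length} columns; "
                "intervals must tile the alignment"
            )
    return loci


def load_matrix(
    alignment_path,
    partition_path,
    alignment_format: str = "fasta",
    missing: frozenset = DEFAULT_MISSING,
) -> OccupancyMatrix:
    """Read an alignment (FASTA or sequential NEXUS) plus partition file."""
    from Bio import SeqIO

    aln = list(SeqIO.parse(str(alignment_path), alignment_format))
    if not aln:
        raise ValueError("empty alignment")
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    n_columns = lengths.pop()
    with open(partition_path) as fh:
        loci = parse_partition_file(fh.read(), alignment_length=n_columns)
    taxa = [rec.id for rec in aln]
    chars = np.array([list(str(rec.seq)) for rec in aln])
    present = ~np.isin(chars, list(missing))
    cells = np.empty((len(taxa), len(loci)), dtype=int)
    for j, locus in enumerate(loci):
        cells[:, j] = present[:, locus.start : locus.end].sum(axis=1)
    return OccupancyMatrix(taxa=taxa, loci=loci, cells=cells, n_columns=n_columns)


def summary_from_counts(
    n_taxa: int, n_columns: int, filled_cells: int
) -> OccupancySummary:
    """Occupancy bookkeeping from aggregate counts alone.

    Used when only the printed totals of a matrix are available (e.g.
    auditing a published supermatrix without redistributing it).
    """
    if n_taxa <= 0 or n_columns <= 0:
        raise ValueError("n_taxa and n_columns must be positive")
    total = n_taxa * n_columns
    if not 0 <= filled_cells <= total:
        raise ValueError("filled_cells outside [0, total_cells]")
    return OccupancySummary(
        n_taxa=n_taxa,
        n_columns=n_columns,
        total_cells=total,
        filled_cells=filled_cells,
        percent_filled=100.0 * filled_cells / total,
        mean_nucleotides_per_taxon=filled_cells / n_taxa,
    )


def occupancy_summary(m: OccupancyMatrix) -> OccupancySummary:
    """Full occupancy statistics of a loaded matrix."""
    filled = int(m.cells.sum())
    base = summary_from_counts(len(m.taxa), m.n_columns, filled)
    presence = m.presence
    taxa_per_locus = {
        locus.name: int(presence[:, j].sum()) for j, locus in enumerate(m.loci)
    }
    loci_per_taxon = {
        taxon: int(presence[i, :].sum()) for i, taxon in enumerate(m.taxa)
    }
    base.taxa_per_locus = taxa_per_locus
    base.mean_taxa_per_locus = float(np.mean(list(taxa_per_locus.values())))
    base.loci_per_taxon = loci_per_taxon
    base.mean_loci_per_taxon = float(np.mean(list(loci_per_taxon.values())))
    return base


def completeness_fraction(sampled: int, total: int) -> float:
    """Percent of recognized species present in the tree, to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= sampled <= total:
        raise ValueError("need 0 <= sampled <= total")
    return round1(100.0 * sampled / total)


def singleton_report(m: OccupancyMatrix) -> list[tuple[str, str]]:
    """Taxa represented by exactly one locus, sorted by taxon label."""
    presence = m.presence
    out = []
    for i, taxon in enumerate(m.taxa):
        if presence[i].sum() == 1:
            j = int(np.flatnonzero(presence[i])[0])
            out.append((taxon, m.loci[j].name))
    return sorted(out)
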