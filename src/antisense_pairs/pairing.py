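"""Sense/antisense pair catalog construction.

Three steps, composed by :func:`build_pair_catalog`:

1. :func:`overlap_join` — inner join of genes against ncRNAs on shared
   genomic coordinates (>= 1 overlapping base, same chromosome), strand
   ignored at this stage;
2. :func:`filter_opposite_strand` — keep pairs whose members lie on
   opposite strands (the antisense configuration);
3. :func:`select_longest_per_gene` — one pair per gene, keeping the ncRNA
   with the greatest annotated length.

"Longest" refers to the ncRNA's full annotated length, not the overlap
length.  Abutting intervals (gene end + 1 == ncRNA start) do not overlap.
A ncRNA may legitimately appear under several genes; the per-gene rule
only collapses multiple ncRNAs on one gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .annotations import FeatureSet, ValidationError

__all__ = [
    "SenseAntisensePair",
    "PairCatalog",
    "overlap_join",
    "filter_opposite_strand",
    "select_longest_per_gene",
    "build_pair_catalog",
    "write_catalog",
    "read_catalog",
]

_CATALOG_COLUMNS = (
    "gene_id",
    "ncrna_id",
    "chrom",
    "gene_strand",
    "ncrna_strand",
    "overlap_start",
    "overlap_end",
    "overlap_length",
    "ncrna_length",
)


@dataclass(frozen=True)
class SenseAntisensePair:
    """One gene matched to one overlapping ncRNA, with overlap statistics.

    Coordinates are 1-based inclusive.  ``ncrna_start`` (the ncRNA's own
    annotated start) is carried along for the deterministic tie-break in
    :func:`select_longest_per_gene`.
    """

    gene_id: str
    ncrna_id: str
    chrom: str
    gene_strand: str
    ncrna_strand: str
    overlap_start: int
    overlap_end: int
    overlap_length: int
    ncrna_length: int
    ncrna_start: int

    def __post_init__(self) -> None:
        if self.overlap_length != self.overlap_end - self.overlap_start + 1:
            raise ValidationError(
                f"pair ({self.gene_id}, {self.ncrna_id}): inconsistent overlap length"
            )
        if self.overlap_length < 1:
            raise ValidationError(
                f"pair ({self.gene_id}, {self.ncrna_id}): empty overlap"
            )

    @property
    def opposite_strand(self) -> bool:
        return self.gene_strand != self.ncrna_strand


@dataclass
class PairCatalog:
    """The resolved pair catalog plus stage-count bookkeeping.

    ``summary`` records the counts at each filtering stage (candidate pairs
    from the coordinate join, pairs after the opposite-strand filter, final
    catalog pairs) together with the distinct gene and ncRNA counts at the
    opposite-strand stage, so either reading of an aggregate "feature count"
    can be checked against external catalogs.
    """

    pairs: list[SenseAntisensePair] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if p.gene_id in seen:
                raise ValidationError(
                    f"gene {p.gene_id!r} appears more than once in resolved catalog"
                )
            seen.add(p.gene_id)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def gene_ids(self) -> list[str]:
        return [p.gene_id for p in self.pairs]

    @property
    def ncrna_ids(self) -> list[str]:
        return [p.ncrna_id for p in self.pairs]


def _make_pair(gene, ncrna) -> SenseAntisensePair:
    start = max(gene.start, ncrna.start)
    end = min(gene.end, ncrna.end)
    return SenseAntisensePair(
        gene_id=gene.feature_id,
        ncrna_id=ncrna.feature_id,
        chrom=gene.chrom,
        gene_strand=gene.strand,
        ncrna_strand=ncrna.strand,
        overlap_start=start,
        overlap_end=end,
        overlap_length=end - start + 1,
        ncrna_length=ncrna.length,
        ncrna_start=ncrna.start,
    )


def overlap_join(genes: FeatureSet, ncrnas: FeatureSet) -> list[SenseAntisensePair]:
    """All (gene, ncRNA) pairs sharing >= 1 base, regardless of strand.

    Output is ordered by (gene input order, ncRNA input order).  Implemented
    with a per-chromosome interval tree over the ncRNAs; the equivalent
    all-against-all double loop is kept in the test suite as the reference.
    """
    trees: dict[str, IntervalTree] = {}
    order: dict[str, int] = {}
    for j, nc in enumerate(ncrnas):
        order[nc.feature_id] = j
        # intervaltree is half-open; end + 1 makes the inclusive end queryable.
        trees.setdefault(nc.chrom, IntervalTree()).addi(nc.start, nc.end + 1, nc)
    pairs: list[SenseAntisensePair] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(gene.start, gene.end + 1),
                      key=lambda iv: order[iv.data.feature_id])
        pairs.extend(_make_pair(gene, iv.data) for iv in hits)
    return pairs


def filter_opposite_strand(
    pairs: Iterable[SenseAntisensePair],
) -> list[SenseAntisensePair]:
    """Keep exactly the pairs whose gene and ncRNA strands differ."""
    return [p for p in pairs if p.opposite_strand]


def select_longest_per_gene(pairs: Sequence[SenseAntisensePair]) -> PairCatalog:
    """Resolve to one pair per gene: the ncRNA with maximal annotated length.

    Ties break on smaller ncRNA start, then lexicographically smaller
    ncrna_id, so the catalog is independent of input order.
    """
    best: dict[str, SenseAntisensePair] = {}
    gene_order: list[str] = []
    for p in pairs:
        cur = best.get(p.gene_id)
        if cur is None:
            best[p.gene_id] = p
            gene_order.append(p.gene_id)
            continue
        key_new = (-p.ncrna_length, p.ncrna_start, p.ncrna_id)
        key_cur = (-cur.ncrna_length, cur.ncrna_start, cur.ncrna_id)
        if key_new < key_cur:
            best[p.gene_id] = p
    return PairCatalog(pairs=[best[g] for g in gene_order])


def build_pair_catalog(genes: FeatureSet, ncrnas: FeatureSet) -> PairCatalog:
    """Compose join -> strand filter -> per-gene resolution, with stage counts."""
    candidates = overlap_join(genes, ncrnas)
    opposite = filter_opposite_strand(candidates)
    catalog = select_longest_per_gene(opposite)
    catalog.summary = {
        "n_candidate_pairs": len(candidates),
        "n_opposite_pairs": len(opposite),
        "n_catalog_pairs": len(catalog),
        "n_distinct_genes_opposite": len({p.gene_id for p in opposite}),
        "n_distinct_ncrnas_opposite": len({p.ncrna_id for p in opposite}),
        "n_distinct_ncrnas_catalog": len(set(catalog.ncrna_ids)),
    }
    return catalog


def write_catalog(catalog: PairCatalog, path: str | Path | io.TextIOBase) -> None:
    """Write the catalog as TSV (ncrna_start column appended for round-trips)."""

    def _emit(fh) -> None:
        fh.write("\t".join(_CATALOG_COLUMNS + ("ncrna_start",)) + "\n")
        for p in catalog:
            fh.write(
                f"{p.gene_id}\t{p.ncrna_id}\t{p.chrom}\t{p.gene_strand}\t"
                f"{p.ncrna_strand}\t{p.overlap_start}\t{p.overlap_end}\t"
                f"{p.overlap_length}\t{p.ncrna_length}\t{p.ncrna_start}\n"
            )

    if isinstance(path, (str, Path)):
        with open(path, "wt", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(path)


def read_catalog(path: str | Path) -> PairCatalog:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "ncrna_id": str, "chrom": str})
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalog file missing columns {missing}")
    if "ncrna_start" not in df.columns:
        df["ncrna_start"] = df["overlap_start"]
    pairs = [
        SenseAntisensePair(
            gene_id=row.gene_id,
            ncrna_id=row.ncrna_id,
            chrom=row.chrom,
            gene_strand=row.gene_strand,
            ncrna_strand=row.ncrna_strand,
            overlap_start=int(row.overlap_start),
            overlap_end=int(row.overlap_end),
            overlap_length=int(row.overlap_length),
            ncrna_length=int(row.ncrna_length),
            ncrna_start=int(row.ncrna_start),
        )
        for row in df.itertuples()
    ]
    return PairCatalog(pairs=pairs)
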