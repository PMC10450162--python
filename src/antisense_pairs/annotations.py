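"""Genomic feature annotations: reading, validation, and normalization.

Gene and non-coding transcript coordinate sets arrive in several dialects
(GFF3, BED6, plain TSV tables such as published CUT/SUT/XUT catalogs).  This
module normalizes them all to one internal convention — 1-based, inclusive
coordinates on an explicit strand — so the pairing stage never has to think
about off-by-one conversions.

Conventions
-----------
* Internal coordinates are 1-based inclusive (GFF style).  BED input is
  0-based half-open and converted on read; the BED writer converts back.
* Strand must be ``+`` or ``-``.  Unstranded records (``.``) are rejected:
  the whole point of the downstream analysis is strand-aware overlap, so an
  unstranded feature is an input error, not a default.
* Chromosome names are compared as exact strings; no "chr" aliasing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "VALID_KINDS",
    "GenomicFeature",
    "FeatureSet",
    "AnnotationError",
    "ParseError",
    "ValidationError",
    "read_features",
    "write_bed6",
    "write_tsv",
]

VALID_KINDS = frozenset({"gene", "CUT", "SUT", "XUT", "ncRNA_other"})

_TSV_COLUMNS = ("id", "chrom", "start", "end", "strand")


class AnnotationError(Exception):
    """Base class for annotation I/O and validation failures."""


class ParseError(AnnotationError):
    """A line could not be parsed under the declared dialect."""


class ValidationError(AnnotationError):
    """A parsed record violates a GenomicFeature/FeatureSet invariant."""


@dataclass(frozen=True)
class GenomicFeature:
    """A located, stranded annotation record (gene or ncRNA).

    Coordinates are 1-based inclusive; ``length`` is ``end - start + 1``.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValidationError("feature_id must be non-empty")
        if not self.chrom:
            raise ValidationError(f"{self.feature_id}: chrom must be non-empty")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValidationError(f"{self.feature_id}: coordinates must be integers")
        if self.start < 1:
            raise ValidationError(
                f"{self.feature_id}: start must be >= 1 (got {self.start})"
            )
        if self.end < self.start:
            raise ValidationError(
                f"{self.feature_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.feature_id}: strand must be '+' or '-' (got {self.strand!r})"
            )
        if self.kind not in VALID_KINDS:
            raise ValidationError(
                f"{self.feature_id}: kind must be one of {sorted(VALID_KINDS)} "
                f"(got {self.kind!r})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureSet:
    """An ordered, duplicate-free collection of :class:`GenomicFeature`.

    Iteration order is the input order, which downstream stages rely on for
    deterministic output ordering.
    """

    features: list[GenomicFeature] = field(default_factory=list)
    label: str = "features"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValidationError(
                    f"duplicate feature_id {f.feature_id!r} in set {self.label!r}"
                )
            seen.add(f.feature_id)
        self._by_id = {f.feature_id: f for f in self.features}

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> GenomicFeature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [f.feature_id for f in self.features]


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: {what} is not an integer: {text!r}") from None


def _check_strand(strand: str, lineno: int) -> str:
    if strand not in ("+", "-"):
        raise ValidationError(
            f"line {lineno}: strand must be '+' or '-' (got {strand!r}); "
            "unstranded records are not allowed"
        )
    return strand


def _read_bed6(lines: Iterable[str], kind_default: str) -> Iterator[GenomicFeature]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(
                f"line {lineno}: BED6 requires 6 tab-separated fields, got {len(fields)}"
            )
        chrom, start0, end0, name, _score, strand = fields[:6]
        start0_i = _parse_int(start0, "start", lineno)
        end0_i = _parse_int(end0, "end", lineno)
        # BED is 0-based half-open; internal convention is 1-based inclusive.
        yield GenomicFeature(
            feature_id=name,
            chrom=chrom,
            start=start0_i + 1,
            end=end0_i,
            strand=_check_strand(strand, lineno),
            kind=kind_default,
        )


def _read_tsv(lines: Iterable[str], kind_default: str) -> Iterator[GenomicFeature]:
    it = iter(enumerate(lines, start=1))
    try:
        header_no, header_line = next(it)
    except StopIteration:
        raise ParseError("line 1: empty TSV file (header required)") from None
    header = header_line.rstrip("\n").split("\t")
    missing = [c for c in _TSV_COLUMNS if c not in header]
    if missing:
        raise ParseError(
            f"line {header_no}: TSV header missing required columns {missing} "
            f"(need {list(_TSV_COLUMNS)})"
        )
    idx = {c: header.index(c) for c in header}
    has_kind = "kind" in idx
    for lineno, raw in it:
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        yield GenomicFeature(
            feature_id=fields[idx["id"]],
            chrom=fields[idx["chrom"]],
            start=_parse_int(fields[idx["start"]], "start", lineno),
            end=_parse_int(fields[idx["end"]], "end", lineno),
            strand=_check_strand(fields[idx["strand"]], lineno),
            kind=fields[idx["kind"]] if has_kind and fields[idx["kind"]] else kind_default,
        )


def _read_gff3(
    lines: Iterable[str],
    kind_default: str,
    feature_types: Sequence[str],
) -> Iterator[GenomicFeature]:
    # Parsed line-by-line (gffutils' feature parser) so input order is kept
    # and errors carry line numbers; no feature hierarchy is needed here.
    from gffutils.feature import feature_from_line

    wanted = set(feature_types)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):  # embedded FASTA section terminates annotations
            break
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise ParseError(f"line {lineno}: malformed GFF3 record: {exc}") from exc
        if feat.featuretype not in wanted:
            continue
        ids = feat.attributes.get("ID") or feat.attributes.get("Name")
        feature_id = ids[0] if ids else f"{feat.featuretype}_{lineno}"
        yield GenomicFeature(
            feature_id=feature_id,
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=_check_strand(feat.strand, lineno),
            kind=kind_default,
        )


def read_features(
    path: str | Path,
    format: str,
    kind_default: str = "gene",
    label: str | None = None,
    gff_feature_types: Sequence[str] = ("gene",),
) -> FeatureSet:
    """Read an annotation file into a validated :class:`FeatureSet`.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``gff3``, ``bed6``, ``tsv``.  BED is 0-based half-open and is
        converted; GFF3 and TSV are already 1-based inclusive.
    kind_default
        Feature kind assigned when the file carries none (BED6, GFF3, and
        TSV rows with an empty ``kind`` column).
    label
        Label for the returned set; defaults to the file stem.
    gff_feature_types
        GFF3 ``type`` values to keep (column 3); default ``gene`` records.
    """
    path = Path(path)
    if format not in ("gff3", "bed6", "tsv"):
        raise ValueError(f"unknown format {format!r}; expected gff3, bed6 or tsv")
    if kind_default not in VALID_KINDS:
        raise ValidationError(f"kind_default must be one of {sorted(VALID_KINDS)}")
    with open(path, "rt", encoding="utf-8") as fh:
        if format == "bed6":
            feats = list(_read_bed6(fh, kind_default))
        elif format == "tsv":
            feats = list(_read_tsv(fh, kind_default))
        else:
            feats = list(_read_gff3(fh, kind_default, gff_feature_types))
    return FeatureSet(features=feats, label=label if label is not None else path.stem)


def write_bed6(features: FeatureSet, path: str | Path | io.TextIOBase) -> None:
    """Write a FeatureSet as BED6 (converting back to 0-based half-open)."""

    def _emit(fh) -> None:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start - 1}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n"
            )

    if isinstance(path, (str, Path)):
        with open(path, "wt", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(path)


def write_tsv(features: FeatureSet, path: str | Path | io.TextIOBase) -> None:
    """Write a FeatureSet as the 1-based TSV dialect (with ``kind`` column)."""

    def _emit(fh) -> None:
        fh.write("id\tchrom\tstart\tend\tstrand\tkind\n")
        for f in features:
            fh.write(
                f"{f.feature_id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\n"
            )

    if isinstance(path, (str, Path)):
        with open(path, "wt", encoding="utf-8") as fh:
            _emit(fh)
    else:
        _emit(path)
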