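"""Turn amplicon sequencing reads into an shRNA count table.

Reads of the integrated shRNA cassette carry a sample barcode (distinct
custom PCR primers per sample/replicate) and the 21-nt hairpin at fixed
offsets.  Quantification is deliberately simple: demultiplex by exact
barcode match, trim each read to the hairpin region, look the 21-mer up in
the library dictionary (exact by default, optionally allowing one mismatch
with ambiguous hits discarded), and finally drop hairpins with zero reads
across all samples.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .library_io import LibraryManifest, ManifestError
from .synthetic_data import CountTable

logger = logging.getLogger(__name__)

_AMBIGUOUS = object()


@dataclass(frozen=True)
class ReadLayout:
    """Where the barcode and hairpin sit within a read (0-based, half-open)."""

    barcode_start: int = 0
    barcode_length: int = 6
    hairpin_start: int = 30
    hairpin_length: int = 21
    allowed_mismatches: int = 0

    def __post_init__(self) -> None:
        if min(self.barcode_start, self.barcode_length,
               self.hairpin_start, self.hairpin_length) < 0:
            raise ValueError("layout offsets and lengths must be non-negative")
        if self.allowed_mismatches not in (0, 1):
            raise ValueError("allowed_mismatches must be 0 or 1")

    @property
    def barcode_end(self) -> int:
        return self.barcode_start + self.barcode_length

    @property
    def hairpin_end(self) -> int:
        return self.hairpin_start + self.hairpin_length

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReadLayout":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class SampleInfo:
    label: str
    fraction: str
    replicate: int | None = None


class BarcodeMap(dict):
    """barcode sequence -> :class:`SampleInfo`; barcodes unique, equal length."""

    def __init__(self, mapping: Mapping[str, SampleInfo]):
        super().__init__(mapping)
        if self:
            lengths = {len(bc) for bc in self}
            if len(lengths) != 1:
                raise ValueError("barcodes must all have the same length")
            labels = [info.label for info in self.values()]
            if len(set(labels)) != len(labels):
                raise ValueError("sample labels must be unique")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BarcodeMap":
        """YAML: ``barcode: {label: ..., fraction: ..., replicate: ...}``."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls({bc: SampleInfo(**info) for bc, info in data.items()})


def default_barcode_map(samples: pd.DataFrame, barcode_length: int) -> BarcodeMap:
    """Deterministic barcodes (lexicographic k-mers) for a sample sheet."""
    import itertools

    kmers = ("".join(t) for t in itertools.product("ACGT", repeat=barcode_length))
    mapping = {}
    for label, row in samples.iterrows():
        rep = row["replicate"]
        mapping[next(kmers)] = SampleInfo(
            label=label, fraction=row["fraction"],
            replicate=None if pd.isna(rep) else int(rep))
    return BarcodeMap(mapping)


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def iter_fastq(source) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ path or an iterable of either
    (id, seq) tuples or bare sequences."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        with _open_maybe_gz(source) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq)
    else:
        for item in source:
            if isinstance(item, str):
                yield "", item
            else:
                yield item[0], item[1]


@dataclass
class DemuxResult:
    reads: dict[str, list[tuple[str, str]]]  # label -> [(id, seq)]
    unassigned: int
    short: int

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.reads.values()) + self.unassigned


def demultiplex(fastq, layout: ReadLayout, barcodes: BarcodeMap) -> DemuxResult:
    """Route reads to samples by exact barcode match at the barcode region.

    Reads too short to cover the barcode region are tallied separately (they
    are also counted in ``unassigned`` so that assigned + unassigned equals
    the input read count).
    """
    if barcodes and barcodes.barcode_length != layout.barcode_length:
        raise ValueError("barcode map length does not match layout")
    out: dict[str, list[tuple[str, str]]] = {info.label: [] for info in barcodes.values()}
    unassigned = short = 0
    for read_id, seq in iter_fastq(fastq):
        if len(seq) < layout.barcode_end:
            short += 1
            unassigned += 1
            continue
        info = barcodes.get(seq[layout.barcode_start:layout.barcode_end])
        if info is None:
            unassigned += 1
        else:
            out[info.label].append((read_id, seq))
    return DemuxResult(reads=out, unassigned=unassigned, short=short)


def _hairpin_index(manifest: LibraryManifest, allowed_mismatches: int):
    """Exact-match dict plus (optionally) a Hamming-1 neighborhood dict."""
    exact: dict[str, str] = {}
    for rec in manifest.records:
        if rec.hairpin_seq in exact:
            raise ManifestError(
                f"duplicate hairpin sequence for {rec.shrna_id}; "
                "cannot build an unambiguous dictionary")
        exact[rec.hairpin_seq] = rec.shrna_id
    neighbors: dict[str, object] = {}
    if allowed_mismatches == 1:
        for seq, shrna_id in exact.items():
            for i, base in enumerate(seq):
                for alt in "ACGT":
                    if alt == base:
                        continue
                    variant = seq[:i] + alt + seq[i + 1:]
                    if variant in neighbors and neighbors[variant] != shrna_id:
                        neighbors[variant] = _AMBIGUOUS
                    else:
                        neighbors[variant] = shrna_id
    return exact, neighbors


@dataclass
class HairpinCounts:
    counts: pd.Series  # indexed by shrna_id
    unmatched: int
    short: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.unmatched


def count_hairpins(reads, manifest: LibraryManifest,
                   layout: ReadLayout) -> HairpinCounts:
    """Count reads per hairpin by (mismatch-tolerant) exact dictionary lookup.

    The substring ``[hairpin_start, hairpin_start + hairpin_length)`` of each
    read is matched against the library.  With ``allowed_mismatches=1``, a
    segment matching exactly one hairpin at Hamming distance <= 1 is assigned;
    a segment within distance 1 of two or more hairpins is ambiguous and
    counted as unmatched.  Short reads are unmatched (and tallied).
    """
    if layout.hairpin_length != manifest.hairpin_length:
        raise ValueError("layout hairpin_length does not match manifest")
    exact, neighbors = _hairpin_index(manifest, layout.allowed_mismatches)
    counts = {shrna_id: 0 for shrna_id in manifest.shrna_ids}
    unmatched = short = 0
    for _read_id, seq in iter_fastq(reads):
        if len(seq) < layout.hairpin_end:
            short += 1
            unmatched += 1
            continue
        segment = seq[layout.hairpin_start:layout.hairpin_end]
        hit = exact.get(segment)
        if hit is None and layout.allowed_mismatches == 1:
            hit = neighbors.get(segment)
            if hit is _AMBIGUOUS:
                hit = None
        if hit is None:
            unmatched += 1
        else:
            counts[hit] += 1
    series = pd.Series(counts, name="count")
    series.index.name = "shrna_id"
    return HairpinCounts(counts=series, unmatched=unmatched, short=short)


def count_samples(fastq, manifest: LibraryManifest, layout: ReadLayout,
                  barcodes: BarcodeMap) -> tuple[CountTable, dict]:
    """Demultiplex then count: the full FASTQ -> CountTable path.

    Returns the table and a run report (totals, unassigned, short,
    per-sample unmatched).
    """
    demux = demultiplex(fastq, layout, barcodes)
    columns = {}
    report = {"unassigned": demux.unassigned, "short_barcode": demux.short,
              "unmatched": {}, "short_hairpin": {}}
    order = [info.label for info in barcodes.values()]
    for label in order:
        hp = count_hairpins(demux.reads[label], manifest, layout)
        columns[label] = hp.counts
        report["unmatched"][label] = hp.unmatched
        report["short_hairpin"][label] = hp.short
    counts = pd.DataFrame(columns)
    counts.index.name = "shrna_id"
    return CountTable.from_counts(counts), report


def filter_zero(table: CountTable) -> tuple[CountTable, list[str]]:
    """Discard hairpins with zero reads across *all* samples.

    A hairpin that drops out of a single E18.5 sample is a biological
    depletion and is retained (the pseudocount downstream keeps its fold
    change finite); only hairpins never observed anywhere are removed.
    """
    zero = table.counts.sum(axis=1) == 0
    removed = list(table.counts.index[zero])
    if removed:
        logger.info("zero-read filter removed %d hairpin(s): %s",
                    len(removed), ", ".join(removed[:10]))
    kept = CountTable(counts=table.counts.loc[~zero], samples=table.samples)
    return kept, removed
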