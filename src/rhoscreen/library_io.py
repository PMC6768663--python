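"""Read, validate, synthesize and write the pooled shRNA library manifest.

The screen library targets the Rho GTPase superfamily: 20 Rho GTPases, 77
RhoGEFs, 66 RhoGAPs and 3 RhoGDIs (166 genes), with at least five distinct
hairpins per gene plus 20 scrambled (Scr) controls, for 999 hairpins total.
Hairpins are fixed-length 21-nt sequences; scrambled controls carry the
reserved gene symbol ``"SCR"``.

A manifest lives on disk as a TSV (columns ``shrna_id``, ``gene``,
``reg_class``, ``hairpin_seq``) and/or a FASTA of hairpin sequences whose
headers carry the id, gene and class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

REG_CLASSES = ("GTPASE", "GEF", "GAP", "GDI", "SCR")
SCR_GENE = "SCR"
HAIRPIN_ALPHABET = frozenset("ACGT")
DEFAULT_HAIRPIN_LENGTH = 21

MANIFEST_COLUMNS = ("shrna_id", "gene", "reg_class", "hairpin_seq")


class ManifestError(ValueError):
    """Raised when a manifest file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ShrnaRecord:
    """One hairpin of the library."""

    shrna_id: str
    gene: str
    reg_class: str
    hairpin_seq: str

    def validate(self, hairpin_length: int) -> None:
        if self.reg_class not in REG_CLASSES:
            raise ManifestError(
                f"{self.shrna_id}: unknown reg_class {self.reg_class!r}"
            )
        if (self.reg_class == "SCR") != (self.gene == SCR_GENE):
            raise ManifestError(
                f"{self.shrna_id}: reg_class SCR and gene {SCR_GENE!r} must co-occur"
            )
        if len(self.hairpin_seq) != hairpin_length:
            raise ManifestError(
                f"{self.shrna_id}: hairpin length {len(self.hairpin_seq)} != "
                f"declared {hairpin_length}"
            )
        if not HAIRPIN_ALPHABET.issuperset(self.hairpin_seq):
            raise ManifestError(
                f"{self.shrna_id}: hairpin contains non-ACGT characters"
            )


@dataclass(frozen=True)
class LibraryComposition:
    """Printed composition of the screen library (defaults = the screen's)."""

    n_gtpase: int = 20
    n_gef: int = 77
    n_gap: int = 66
    n_gdi: int = 3
    n_scr_shrnas: int = 20
    min_shrnas_per_gene: int = 5
    total_shrnas: int = 999

    @property
    def n_genes(self) -> int:
        return self.n_gtpase + self.n_gef + self.n_gap + self.n_gdi

    @property
    def min_feasible_total(self) -> int:
        return self.min_shrnas_per_gene * self.n_genes + self.n_scr_shrnas

    def validate(self) -> None:
        counts = (self.n_gtpase, self.n_gef, self.n_gap, self.n_gdi,
                  self.n_scr_shrnas, self.min_shrnas_per_gene, self.total_shrnas)
        if any(c < 0 for c in counts):
            raise ManifestError("composition counts must be non-negative")
        if self.n_genes == 0:
            raise ManifestError("composition has no targeted genes")
        if self.total_shrnas < self.min_feasible_total:
            raise ManifestError(
                f"total_shrnas={self.total_shrnas} below minimum feasible "
                f"{self.min_feasible_total} "
                f"({self.min_shrnas_per_gene}/gene x {self.n_genes} genes "
                f"+ {self.n_scr_shrnas} scrambled)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LibraryComposition":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


#: The screen's printed library composition.
DEFAULT_COMPOSITION = LibraryComposition()


@dataclass
class LibraryManifest:
    """An ordered, validated collection of hairpin records."""

    records: list[ShrnaRecord]
    hairpin_length: int = DEFAULT_HAIRPIN_LENGTH
    allow_duplicate_seqs: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_ids: set[str] = set()
        for rec in self.records:
            rec.validate(self.hairpin_length)
            if rec.shrna_id in seen_ids:
                raise ManifestError(f"duplicate shrna_id {rec.shrna_id!r}")
            seen_ids.add(rec.shrna_id)
        dup_seqs = [s for s, k in Counter(r.hairpin_seq for r in self.records).items()
                    if k > 1]
        if dup_seqs:
            if not self.allow_duplicate_seqs:
                raise ManifestError(
                    f"{len(dup_seqs)} duplicate hairpin sequence(s); "
                    "set allow_duplicate_seqs=True to keep them"
                )
            logger.warning("manifest contains %d duplicate hairpin sequence(s)",
                           len(dup_seqs))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryManifest):
            return NotImplemented
        return (self.records == other.records
                and self.hairpin_length == other.hairpin_length)

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Distinct targeted genes (scrambled controls excluded), in order."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.gene != SCR_GENE:
                seen.setdefault(r.gene)
        return list(seen)

    @property
    def scr_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records if r.gene == SCR_GENE]

    def gene_of(self) -> dict[str, str]:
        return {r.shrna_id: r.gene for r in self.records}

    @property
    def composition(self) -> LibraryComposition:
        """Recompute the composition from the records."""
        by_class = Counter(r.reg_class for r in self.records)
        per_gene = Counter(r.gene for r in self.records if r.gene != SCR_GENE)
        genes_by_class = Counter(
            {cls: len({r.gene for r in self.records if r.reg_class == cls})
             for cls in ("GTPASE", "GEF", "GAP", "GDI")}
        )
        return LibraryComposition(
            n_gtpase=genes_by_class["GTPASE"],
            n_gef=genes_by_class["GEF"],
            n_gap=genes_by_class["GAP"],
            n_gdi=genes_by_class["GDI"],
            n_scr_shrnas=by_class["SCR"],
            min_shrnas_per_gene=min(per_gene.values()) if per_gene else 0,
            total_shrnas=len(self.records),
        )


def load_manifest(path: str | Path, fasta: str | Path | None = None) -> LibraryManifest:
    """Load a manifest TSV (optionally taking sequences from a FASTA).

    The TSV must be tab-separated with a header row naming at least the
    columns ``shrna_id``, ``gene``, ``reg_class`` and — unless ``fasta`` is
    given — ``hairpin_seq``.  When ``fasta`` is given, sequences are looked up
    by ``shrna_id`` in the FASTA and any ``hairpin_seq`` column is ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ManifestError(f"{path}: empty manifest file")
    header = lines[0].rstrip("\n").split("\t")
    needed = ["shrna_id", "gene", "reg_class"] + ([] if fasta else ["hairpin_seq"])
    missing = [c for c in needed if c not in header]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in header}

    seqs: dict[str, str] = {}
    if fasta is not None:
        for rec in SeqIO.parse(str(fasta), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()

    records: list[ShrnaRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ManifestError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        shrna_id = fields[idx["shrna_id"]]
        if fasta is not None:
            if shrna_id not in seqs:
                raise ManifestError(f"{path}:{lineno}: {shrna_id} absent from FASTA")
            seq = seqs[shrna_id]
        else:
            seq = fields[idx["hairpin_seq"]].upper()
        records.append(ShrnaRecord(
            shrna_id=shrna_id,
            gene=fields[idx["gene"]],
            reg_class=fields[idx["reg_class"]],
            hairpin_seq=seq,
        ))
    if not records:
        raise ManifestError(f"{path}: manifest contains no records")
    hairpin_length = len(records[0].hairpin_seq)
    return LibraryManifest(records, hairpin_length=hairpin_length)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    """Write the manifest as a tab-separated table with a header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in manifest.records:
            fh.write(f"{r.shrna_id}\t{r.gene}\t{r.reg_class}\t{r.hairpin_seq}\n")


def write_fasta(manifest: LibraryManifest, path: str | Path) -> None:
    """Write one FASTA record per hairpin; header is ``shrna_id gene reg_class``."""
    dup = [s for s, k in Counter(r.hairpin_seq for r in manifest.records).items() if k > 1]
    if dup:
        logger.warning("writing FASTA with %d duplicate hairpin sequence(s)", len(dup))
    seq_records = [
        SeqRecord(Seq(r.hairpin_seq), id=r.shrna_id,
                  description=f"{r.gene} {r.reg_class}")
        for r in manifest.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _random_kmers(n: int, k: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` distinct random k-mers over ACGT."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = ["".join(row) for row in bases[rng.integers(0, 4, size=(n - len(out), k))]]
        for s in draw:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def synthesize_manifest(
    composition: LibraryComposition = DEFAULT_COMPOSITION,
    seed: int = 0,
    hairpin_length: int = DEFAULT_HAIRPIN_LENGTH,
) -> LibraryManifest:
    """Deterministically synthesize a manifest matching a composition.

    Gene symbols are generated per regulator class (``Gtpase001`` ...).  Every
    gene receives ``min_shrnas_per_gene`` hairpins; the surplus
    ``total - floor - n_scr`` is distributed one hairpin at a time round-robin
    over a seeded shuffle of the gene list, so the output depends only on
    ``(composition, seed, hairpin_length)``.
    """
    composition.validate()
    rng = np.random.default_rng(seed)

    genes: list[tuple[str, str]] = []
    for cls, n in (("GTPASE", composition.n_gtpase), ("GEF", composition.n_gef),
                   ("GAP", composition.n_gap), ("GDI", composition.n_gdi)):
        genes.extend((f"{cls.capitalize()}{i + 1:03d}", cls) for i in range(n))

    counts = {g: composition.min_shrnas_per_gene for g, _ in genes}
    surplus = (composition.total_shrnas - composition.n_scr_shrnas
               - composition.min_shrnas_per_gene * composition.n_genes)
    order = [genes[i][0] for i in rng.permutation(len(genes))]
    for i in range(surplus):
        counts[order[i % len(order)]] += 1

    seqs = iter(_random_kmers(composition.total_shrnas, hairpin_length, rng))
    records: list[ShrnaRecord] = []
    for gene, cls in genes:
        for j in range(counts[gene]):
            records.append(ShrnaRecord(f"sh{gene}_{j + 1}", gene, cls, next(seqs)))
    for j in range(composition.n_scr_shrnas):
        records.append(ShrnaRecord(f"shScr_{j + 1}", SCR_GENE, "SCR", next(seqs)))
    return LibraryManifest(records, hairpin_length=hairpin_length)
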