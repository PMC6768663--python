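"""Generative model of the in utero pooled shRNA screen.

The screen transduces ~15% of the ~120,000 E9.5 surface-ectoderm progenitors
per embryo at MOI <= 1, so each transduced founder carries a single hairpin
drawn from the library.  About 10% of transduced founders contribute to hair
follicles (HF); the rest stay in the interfollicular epidermis (EPI).  Each
founder expands clonally to ~40 cells by E18.5; a knockdown with a
fraction-specific fitness effect multiplies that expected clone size.
Material from 60 embryos is pooled per biological replicate and the screen is
run in triplicate; pooled genomic DNA is PCR-amplified (modelled as a
per-hairpin multiplicative gamma factor with mean 1) and sequenced to a fixed
read depth (a multinomial draw).

The simulator emits count tables (and optionally FASTQ) with known ground
truth, which is what the hit-calling statistics are validated against.
"""

from __future__ import annotations

import gzip
import io
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .library_io import SCR_GENE, LibraryManifest

FRACTIONS = ("T0", "EPI", "HF")
T0_LABEL = "T0"


@dataclass(frozen=True)
class SimParams:
    """Biological and technical parameters of the screen simulation.

    Defaults are the study conditions: 120,000 progenitors per embryo, 15%
    transduction, 10% HF founder fate, ~40-cell expansion, 60 embryos pooled
    per replicate, triplicates.  ``expansion_dispersion`` is the
    negative-binomial shape of a single founder's clone size (smaller =
    more overdispersed); ``pcr_noise_shape`` is the gamma shape of the
    mean-1 per-hairpin amplification factor.
    """

    n_progenitors_per_embryo: int = 120_000
    transduction_rate: float = 0.15
    hf_founder_fraction: float = 0.10
    expansion_mean: float = 40.0
    expansion_dispersion: float = 5.0
    embryos_per_replicate: int = 60
    n_replicates: int = 3
    reads_per_sample: int = 2_000_000
    pcr_noise_shape: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.transduction_rate <= 1.0
                and 0.0 <= self.hf_founder_fraction <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_progenitors_per_embryo, self.embryos_per_replicate,
               self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.expansion_mean <= 0 or self.expansion_dispersion <= 0:
            raise ValueError("expansion_mean and expansion_dispersion must be > 0")
        if self.pcr_noise_shape <= 0:
            raise ValueError("pcr_noise_shape must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


class EffectSpec:
    """Per-gene multiplicative fitness effects (ground truth of a simulation).

    ``effects`` maps gene symbol -> (epi_effect, hf_effect); unlisted genes
    and all scrambled controls are neutral (1.0, 1.0).  An effect of 0.25 on a
    fraction means clones of that gene expand to a quarter of the neutral
    expectation there — a 4-fold depletion.
    """

    def __init__(self, effects: Mapping[str, tuple[float, float]] | None = None):
        self._effects: dict[str, tuple[float, float]] = {}
        for gene, (epi, hf) in (effects or {}).items():
            if epi < 0 or hf < 0:
                raise ValueError(f"{gene}: effects must be >= 0")
            if gene == SCR_GENE:
                raise ValueError("scrambled controls are neutral by definition")
            self._effects[gene] = (float(epi), float(hf))

    def epi(self, gene: str) -> float:
        return self._effects.get(gene, (1.0, 1.0))[0]

    def hf(self, gene: str) -> float:
        return self._effects.get(gene, (1.0, 1.0))[1]

    def affected_genes(self) -> dict[str, tuple[float, float]]:
        return {g: e for g, e in self._effects.items() if e != (1.0, 1.0)}

    def to_json(self) -> str:
        return json.dumps({g: list(e) for g, e in sorted(self._effects.items())})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls({g: tuple(v) for g, v in data.items()})


def sample_label(fraction: str, replicate: int | None = None) -> str:
    return T0_LABEL if fraction == T0_LABEL else f"{fraction}:{replicate}"


@dataclass
class CountTable:
    """shRNA x sample read counts plus per-sample metadata.

    ``counts`` is indexed by shrna_id with one column per sample label;
    ``samples`` is indexed by label with columns ``fraction`` (T0/EPI/HF) and
    ``replicate`` (nullable integer).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shrna_ids(self) -> list[str]:
        return list(self.counts.index)

    def labels(self, fraction: str) -> list[str]:
        return list(self.samples.index[self.samples["fraction"] == fraction])

    def to_tsv(self, path: str | Path) -> None:
        """Write a single TSV; metadata is encoded in the column labels."""
        out = self.counts.copy()
        out.index.name = "shrna_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col="shrna_id")
        return cls.from_counts(counts)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountTable":
        """Build sample metadata from ``FRACTION[:replicate]`` column labels."""
        meta = []
        for label in counts.columns:
            if ":" in label:
                frac, rep = label.split(":", 1)
                meta.append((label, frac, int(rep)))
            else:
                meta.append((label, label, pd.NA))
        samples = pd.DataFrame(meta, columns=["label", "fraction", "replicate"])
        samples = samples.set_index("label")
        samples["replicate"] = samples["replicate"].astype("Int64")
        return cls(counts=counts, samples=samples)


def simulate_embryo(
    params: SimParams,
    manifest: LibraryManifest,
    effects: EffectSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one embryo; returns per-shRNA E18.5 cell tallies (EPI, HF).

    Founders ~ Binomial(n_progenitors, transduction_rate); each founder gets
    one hairpin uniformly (MOI <= 1); fate is HF with probability
    ``hf_founder_fraction`` else EPI; a founder's clone size is negative
    binomial with mean ``expansion_mean * effect(gene, fraction)`` and shape
    ``expansion_dispersion``, so the summed clone of ``f`` founders is
    negative binomial with shape ``f * dispersion``.
    """
    params.validate()
    n_sh = len(manifest)
    genes = np.array([r.gene for r in manifest.records])
    epi_eff = np.array([effects.epi(g) for g in genes])
    hf_eff = np.array([effects.hf(g) for g in genes])

    n_founders = rng.binomial(params.n_progenitors_per_embryo,
                              params.transduction_rate)
    founders = rng.multinomial(n_founders, np.full(n_sh, 1.0 / n_sh))
    hf_founders = rng.binomial(founders, params.hf_founder_fraction)
    epi_founders = founders - hf_founders

    def _expand(f: np.ndarray, eff: np.ndarray) -> np.ndarray:
        cells = np.zeros(n_sh, dtype=np.int64)
        live = (f > 0) & (eff > 0)
        if live.any():
            mean = params.expansion_mean * eff[live]
            shape = f[live] * params.expansion_dispersion
            p = params.expansion_dispersion / (params.expansion_dispersion + mean)
            cells[live] = rng.negative_binomial(shape, p)
        return cells

    return _expand(epi_founders, epi_eff), _expand(hf_founders, hf_eff)


@dataclass
class ScreenTruth:
    """Ground-truth record emitted next to a simulated count table."""

    params: SimParams
    effects: dict[str, tuple[float, float]]
    representation_fold: dict[str, float]  # achieved cells per hairpin, per fraction

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": asdict(self.params),
            "effects": {g: list(e) for g, e in sorted(self.effects.items())},
            "representation_fold": self.representation_fold,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sequence(cells: np.ndarray, params: SimParams,
              rng: np.random.Generator) -> np.ndarray:
    """PCR-amplify (gamma jackpotting, mean 1) then sequence (multinomial)."""
    if params.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be > 0")
    weights = cells * rng.gamma(params.pcr_noise_shape,
                                1.0 / params.pcr_noise_shape, size=cells.shape)
    total = weights.sum()
    if total <= 0:
        raise ValueError("sample contains no cells to sequence")
    return rng.multinomial(params.reads_per_sample, weights / total)


def simulate_screen(
    params: SimParams,
    manifest: LibraryManifest,
    effects: EffectSpec | None = None,
) -> tuple[CountTable, ScreenTruth]:
    """Simulate the full screen: one T0 plus triplicate EPI and HF samples.

    T0 ("t0 in vitro") is sequenced from the uniform library representation;
    each E18.5 replicate pools ``embryos_per_replicate`` embryos before
    amplification and sequencing.  Deterministic for a fixed ``params.seed``.
    """
    params.validate()
    effects = effects or EffectSpec()
    rng = np.random.default_rng(params.seed)
    n_sh = len(manifest)

    columns: dict[str, np.ndarray] = {}
    # T0: uniform representation of the library in cultured keratinocytes.
    t0_cells = np.full(n_sh, 1000.0)
    columns[T0_LABEL] = _sequence(t0_cells, params, rng)

    epi_cells_total = np.zeros(n_sh)
    hf_cells_total = np.zeros(n_sh)
    for rep in range(1, params.n_replicates + 1):
        epi_pool = np.zeros(n_sh, dtype=np.int64)
        hf_pool = np.zeros(n_sh, dtype=np.int64)
        for _ in range(params.embryos_per_replicate):
            epi, hf = simulate_embryo(params, manifest, effects, rng)
            epi_pool += epi
            hf_pool += hf
        epi_cells_total += epi_pool
        hf_cells_total += hf_pool
        columns[sample_label("EPI", rep)] = _sequence(epi_pool, params, rng)
        columns[sample_label("HF", rep)] = _sequence(hf_pool, params, rng)

    counts = pd.DataFrame(columns, index=pd.Index(manifest.shrna_ids, name="shrna_id"))
    table = CountTable.from_counts(counts)
    truth = ScreenTruth(
        params=params,
        effects=effects.affected_genes(),
        representation_fold={
            "EPI": float(epi_cells_total.mean() / params.n_replicates),
            "HF": float(hf_cells_total.mean() / params.n_replicates),
        },
    )
    return table, truth


def simulate_competition(
    params: SimParams,
    test_effects: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    n_embryos: int = 50,
) -> pd.DataFrame:
    """Simulate the two-color competition assay (GFP-scrambled vs RFP-test).

    The two viruses are mixed 1:1, so each transduced founder is RFP with
    probability one half.  Per embryo and fraction the readout is
    ``(final RFP/GFP cells) / (initial RFP/GFP founders)``; a neutral test
    hairpin gives ratios centred on 1.  Embryos with zero GFP cells in a
    fraction are flagged excluded (ratio undefined) with a warning.

    Returns a tidy frame: embryo, fraction, ratio, excluded.
    """
    params.validate()
    epi_eff, hf_eff = test_effects
    rng = np.random.default_rng(seed)
    rows = []
    n_excluded = 0
    for embryo in range(n_embryos):
        n_founders = rng.binomial(params.n_progenitors_per_embryo,
                                  params.transduction_rate)
        rfp_founders = rng.binomial(n_founders, 0.5)
        gfp_founders = n_founders - rfp_founders
        if gfp_founders == 0 or rfp_founders == 0:
            n_excluded += 1
            for fraction in ("EPI", "HF"):
                rows.append((embryo, fraction, np.nan, True))
            continue
        initial_ratio = rfp_founders / gfp_founders
        for fraction, eff in (("EPI", epi_eff), ("HF", hf_eff)):
            frac_p = (params.hf_founder_fraction if fraction == "HF"
                      else 1.0 - params.hf_founder_fraction)
            f_rfp = rng.binomial(rfp_founders, frac_p)
            f_gfp = rng.binomial(gfp_founders, frac_p)
            cells = []
            for f, e in ((f_rfp, eff), (f_gfp, 1.0)):
                if f == 0 or e == 0:
                    cells.append(0)
                    continue
                mean = params.expansion_mean * e
                p = params.expansion_dispersion / (params.expansion_dispersion + mean)
                cells.append(int(rng.negative_binomial(
                    f * params.expansion_dispersion, p)))
            rfp_cells, gfp_cells = cells
            if gfp_cells == 0:
                n_excluded += 1
                rows.append((embryo, fraction, np.nan, True))
                continue
            ratio = (rfp_cells / gfp_cells) / initial_ratio
            rows.append((embryo, fraction, ratio, False))
    if n_excluded:
        warnings.warn(f"{n_excluded} embryo-fraction ratio(s) undefined "
                      "(zero reference cells); excluded", stacklevel=2)
    return pd.DataFrame(rows, columns=["embryo", "fraction", "ratio", "excluded"])


# --- FASTQ emission -------------------------------------------------------

_FLANK = ("ACCGGTCGAGCTCAAGCTTCGAATTCTGCAGTCGACGGTACCGCGGGCCC" * 4)


def emit_fastq(
    counts: CountTable,
    manifest: LibraryManifest,
    layout,
    out_dir: str | Path,
    barcodes=None,
    gz: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ per sample reproducing the count table exactly.

    Each read carries its sample barcode at ``layout.barcode_start`` and the
    hairpin at ``layout.hairpin_start``, padded with a fixed flanking
    sequence; quality is a constant Phred+33 'I'.  ``barcodes`` is a
    :class:`rhoscreen.quantify.BarcodeMap`; by default one is generated with
    :func:`rhoscreen.quantify.default_barcode_map` for the table's samples.
    """
    from .quantify import default_barcode_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if barcodes is None:
        barcodes = default_barcode_map(counts.samples, layout.barcode_length)
    label_to_bc = {info.label: bc for bc, info in barcodes.items()}

    seqs = {r.shrna_id: r.hairpin_seq for r in manifest.records}
    read_len = layout.hairpin_start + layout.hairpin_length + 4
    paths: dict[str, Path] = {}
    for label in counts.counts.columns:
        bc = label_to_bc[label]
        fname = label.replace(":", "_") + (".fastq.gz" if gz else ".fastq")
        path = out_dir / fname
        opener = gzip.open if gz else open
        with opener(path, "wt") as fh:
            i = 0
            for shrna_id, n in counts.counts[label].items():
                hairpin = seqs[shrna_id]
                template = list(_FLANK[:read_len])
                template[layout.barcode_start:layout.barcode_start + len(bc)] = bc
                template[layout.hairpin_start:
                         layout.hairpin_start + len(hairpin)] = hairpin
                seq = "".join(template)
                qual = "I" * read_len
                for _ in range(int(n)):
                    i += 1
                    fh.write(f"@{label}.{i} {shrna_id}\n{seq}\n+\n{qual}\n")
        paths[label] = path
    return paths
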