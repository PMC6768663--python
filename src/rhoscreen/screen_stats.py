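"""Hit-calling statistics, screen-design arithmetic and the test dispatcher.

The screen readout for each hairpin is a scrambled-normalized log2 fold
change: counts in each sample are depth-normalized (counts per million plus a
pseudocount), ratioed against the t0 in vitro library representation, log2
transformed, and centred by subtracting the median of the 20 scrambled
controls in that sample — so the scrambled median is exactly 0 everywhere and
global amplification/depth shifts cancel.

A gene is a candidate in a fraction when at least two of its hairpins each
change at least two-fold in the same direction, each such hairpin is
statistically significant (two-tailed t-test across biological replicates,
raw p < 0.05 and Benjamini-Hochberg q < 0.10 within the fraction), and no
other hairpin of the gene changes two-fold the opposite way.  Candidates are
then classified by fraction (epidermis-only / HF-only / both), with
"HF-specific" meaning an HF call whose gene is quasi-neutral in the
epidermal fraction.

Also here: the coverage calculator used to size the screen (embryos per
replicate needed for >=100-fold founder coverage), the two-color competition
ratio, and the Shapiro-Wilk-gated parametric/non-parametric test dispatch
used for all pairwise morphometric comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library_io import SCR_GENE, LibraryManifest
from .synthetic_data import CountTable, T0_LABEL

E18_FRACTIONS = ("EPI", "HF")


# --- fold change ----------------------------------------------------------

def normalize_log2fc(
    counts: CountTable,
    manifest: LibraryManifest,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Scrambled-normalized log2 fold change of every hairpin vs t0.

    Per sample, counts are rescaled to counts-per-million before adding
    ``pseudocount`` (so the result is exactly invariant to each sample's
    sequencing depth), ratioed to the t0 sample and log2-transformed; the
    per-sample median over scrambled hairpins is then subtracted.

    Returns a tidy frame with columns shrna_id, gene, fraction, replicate,
    log2fc.  Requires a t0 sample and at least one scrambled hairpin present
    in the table.
    """
    if T0_LABEL not in counts.counts.columns:
        raise ValueError("count table has no T0 sample")
    gene_of = manifest.gene_of()
    missing = [i for i in counts.shrna_ids if i not in gene_of]
    if missing:
        raise ValueError(f"count rows absent from manifest: {missing[:5]}")
    genes = pd.Series({i: gene_of[i] for i in counts.shrna_ids})
    scr_mask = (genes == SCR_GENE).to_numpy()
    if not scr_mask.any():
        raise ValueError("no scrambled hairpins in table; cannot normalize")

    mat = counts.counts.to_numpy(dtype=float)
    depth = mat.sum(axis=0)
    if (depth <= 0).any():
        raise ValueError("sample with zero total reads")
    cpm = mat / depth * 1e6 + pseudocount
    if (cpm <= 0).any():
        raise ValueError("non-positive normalized count; use pseudocount > 0")

    t0_col = counts.counts.columns.get_loc(T0_LABEL)
    log2fc = np.log2(cpm) - np.log2(cpm[:, [t0_col]])

    rows = []
    for j, label in enumerate(counts.counts.columns):
        if label == T0_LABEL:
            continue
        fraction = counts.samples.loc[label, "fraction"]
        replicate = int(counts.samples.loc[label, "replicate"])
        col = log2fc[:, j]
        scr_median = np.median(col[scr_mask])
        centred = col - scr_median
        rows.append(pd.DataFrame({
            "shrna_id": counts.shrna_ids,
            "gene": genes.to_numpy(),
            "fraction": fraction,
            "replicate": replicate,
            "log2fc": centred,
        }))
    return pd.concat(rows, ignore_index=True)


def replicate_correlation(fc: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise squared Spearman rank correlation between replicates.

    Returns, per fraction, a symmetric replicate x replicate matrix of R^2
    values.  A replicate with a constant log2fc vector has undefined rank
    correlation; its entries are NaN and a warning is issued.
    """
    out: dict[str, pd.DataFrame] = {}
    for fraction, sub in fc.groupby("fraction"):
        wide = sub.pivot(index="shrna_id", columns="replicate", values="log2fc")
        if wide.shape[1] < 2:
            raise ValueError(f"{fraction}: need >=2 replicates")
        reps = list(wide.columns)
        r2 = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                x, y = wide.iloc[:, a], wide.iloc[:, b]
                if x.nunique() < 2 or y.nunique() < 2:
                    warnings.warn(f"{fraction}: constant replicate vector; "
                                  "correlation undefined", stacklevel=2)
                    val = np.nan
                else:
                    rho = stats.spearmanr(x, y).statistic
                    val = rho ** 2
                r2.iloc[a, b] = r2.iloc[b, a] = val
        out[fraction] = r2
    return out


# --- per-hairpin tests ----------------------------------------------------

def shrna_test(
    fc: pd.DataFrame,
    alpha: float = 0.05,
    fdr: float = 0.10,
    mode: str = "vs_scr",
) -> pd.DataFrame:
    """Two-tailed t-test per (hairpin, fraction) with BH adjustment.

    ``mode="vs_scr"`` (default) runs a row-wise two-sample t-test of each
    hairpin's replicate log2fc values against the pooled scrambled-control
    replicate values of the same fraction — the two-group comparison that
    row-wise "multiple t-test" analyses perform, and the only reading with
    enough degrees of freedom to detect screen-sized effects at triplicate
    depth.  ``mode="one_sample"`` instead tests the replicate values against
    0 (df = n_replicates - 1).  BH (step-up) q-values are computed within
    each fraction across all hairpins.  Degenerate inputs: zero replicate variance with zero mean
    gives p = 1; with nonzero mean, p is set to the smallest positive float
    with a warning.

    Returns columns shrna_id, gene, fraction, mean_log2fc, p_value, q_value.
    """
    if mode not in ("one_sample", "vs_scr"):
        raise ValueError(f"unknown mode {mode!r}")
    results = []
    for fraction, sub in fc.groupby("fraction"):
        wide = sub.pivot(index="shrna_id", columns="replicate", values="log2fc")
        if wide.shape[1] < 2:
            raise ValueError(f"{fraction}: need >=2 replicates for a t-test")
        values = wide.to_numpy()
        gene_map = sub.drop_duplicates("shrna_id").set_index("shrna_id")["gene"]
        genes = gene_map.reindex(wide.index)
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if mode == "one_sample":
                tt = stats.ttest_1samp(values, 0.0, axis=1)
            else:
                scr = values[(genes == SCR_GENE).to_numpy()].ravel()
                tt = stats.ttest_ind(values, scr[None, :].repeat(len(wide), 0),
                                     axis=1)
        pvals = np.asarray(tt.pvalue, dtype=float)
        means = values.mean(axis=1)
        degenerate = ~np.isfinite(pvals)
        if mode == "one_sample":
            degenerate |= values.std(axis=1) == 0
        if degenerate.any():
            zero_mean = degenerate & np.isclose(means, 0.0)
            pvals[zero_mean] = 1.0
            spiked = degenerate & ~zero_mean
            if spiked.any():
                warnings.warn(f"{int(spiked.sum())} hairpin(s) with zero "
                              "replicate variance and nonzero mean; p set to "
                              "the smallest positive float", stacklevel=2)
                pvals[spiked] = np.finfo(float).tiny
        qvals = multipletests(pvals, alpha=fdr, method="fdr_bh")[1]
        results.append(pd.DataFrame({
            "shrna_id": wide.index,
            "gene": genes.to_numpy(),
            "fraction": fraction,
            "mean_log2fc": means,
            "p_value": pvals,
            "q_value": qvals,
        }))
    return pd.concat(results, ignore_index=True)


# --- gene-level calls -----------------------------------------------------

class Direction(str, Enum):
    ENRICHED = "ENRICHED"
    DEPLETED = "DEPLETED"
    NONE = "NONE"


def call_gene_hits(
    tests: pd.DataFrame,
    fold_threshold: float = 2.0,
    min_shrnas: int = 2,
    alpha: float = 0.05,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Apply the gene-level candidate rule per fraction.

    A hairpin *supports* a direction when |mean log2fc| >= log2(fold_threshold)
    and it is significant (raw p < alpha AND BH q < fdr).  A gene is called
    when >= ``min_shrnas`` hairpins support the same direction and none of the
    gene's other hairpins reaches the fold threshold in the opposite
    direction.

    Returns one row per (gene, fraction): direction, n_support,
    supporting_shrna_ids (';'-joined).
    """
    log2_thr = math.log2(fold_threshold)
    rows = []
    for (fraction, gene), sub in tests.groupby(["fraction", "gene"]):
        if gene == SCR_GENE:
            continue
        sig = (sub["p_value"] < alpha) & (sub["q_value"] < fdr)
        up_fold = sub["mean_log2fc"] >= log2_thr
        down_fold = sub["mean_log2fc"] <= -log2_thr
        up_support = sub.loc[sig & up_fold, "shrna_id"]
        down_support = sub.loc[sig & down_fold, "shrna_id"]

        direction = Direction.NONE
        support: Sequence[str] = []
        if len(up_support) >= min_shrnas and not down_fold.any():
            direction, support = Direction.ENRICHED, list(up_support)
        elif len(down_support) >= min_shrnas and not up_fold.any():
            direction, support = Direction.DEPLETED, list(down_support)
        rows.append((gene, fraction, direction.value, len(support),
                     ";".join(support)))
    return pd.DataFrame(rows, columns=["gene", "fraction", "direction",
                                       "n_support", "supporting_shrna_ids"])


def classify_candidates(
    calls: pd.DataFrame,
    fc: pd.DataFrame,
    epi_neutrality_threshold: float = 1.0,
) -> pd.DataFrame:
    """Assign each called gene its fraction (Venn) class and HF specificity.

    ``calls`` holds both fractions' gene calls (output of
    :func:`call_gene_hits` on the combined test table).  ``venn_class`` is
    BOTH / EPI_ONLY / HF_ONLY / NONE; ``hf_specific`` is True when the gene is
    called in HF while its epidermal response stays quasi-neutral — the
    gene's mean |log2fc| over hairpins and replicates in EPI below
    ``epi_neutrality_threshold`` (log2 units; 1.0 = within 2-fold).
    """
    called = calls[calls["direction"] != Direction.NONE.value]
    by_gene: dict[str, dict[str, str]] = {}
    for _, row in called.iterrows():
        by_gene.setdefault(row["gene"], {})[row["fraction"]] = row["direction"]

    epi_mean_abs = (fc[fc["fraction"] == "EPI"]
                    .groupby("shrna_id")
                    .agg(gene=("gene", "first"), m=("log2fc", "mean"))
                    .assign(m=lambda d: d["m"].abs())
                    .groupby("gene")["m"].mean())

    rows = []
    for gene in sorted(set(calls["gene"])):
        dirs = by_gene.get(gene, {})
        if "EPI" in dirs and "HF" in dirs:
            venn = "BOTH"
        elif "EPI" in dirs:
            venn = "EPI_ONLY"
        elif "HF" in dirs:
            venn = "HF_ONLY"
        else:
            venn = "NONE"
        hf_specific = ("HF" in dirs
                       and float(epi_mean_abs.get(gene, 0.0)) < epi_neutrality_threshold)
        rows.append((gene, dirs.get("EPI", Direction.NONE.value),
                     dirs.get("HF", Direction.NONE.value), venn, hf_specific))
    return pd.DataFrame(rows, columns=["gene", "epi_direction", "hf_direction",
                                       "venn_class", "hf_specific"])


# --- coverage / power design ---------------------------------------------

def hf_founders_per_embryo(progenitors: int, hf_fraction: float) -> int:
    """HF-fated progenitors present per embryo at injection time."""
    if progenitors <= 0 or hf_fraction < 0:
        raise ValueError("progenitors must be > 0 and hf_fraction >= 0")
    return round(progenitors * hf_fraction)


@dataclass(frozen=True)
class CoverageDesign:
    """Inputs of the embryos-per-replicate coverage calculation."""

    library_size: int = 1000
    target_coverage: float = 100.0
    progenitors_per_embryo: int = 120_000
    hf_founder_fraction: float = 0.10
    transduction_rate: float = 0.15

    @property
    def transduced_hf_founders_per_embryo(self) -> int:
        return round(self.progenitors_per_embryo * self.hf_founder_fraction
                     * self.transduction_rate)


def min_embryos_for_coverage(design: CoverageDesign) -> int:
    """Embryos per replicate so every hairpin hits >= target_coverage founders.

    ceil(library_size * coverage / transduced HF founders per embryo); the
    screen's own numbers (1000 hairpins, 100x, 120,000 progenitors, 10% HF,
    15% transduction) give 56, consistent with the 60 embryos used.
    """
    founders = (design.progenitors_per_embryo * design.hf_founder_fraction
                * design.transduction_rate)
    if founders <= 0:
        raise ValueError("no transduced HF founders per embryo")
    if design.target_coverage <= 0:
        return 0
    return math.ceil(design.library_size * design.target_coverage / founders)


# --- competition assay ----------------------------------------------------

def competition_ratio(initial: tuple[float, float],
                      final: tuple[float, float]) -> float:
    """Normalized two-color ratio: (final RFP/GFP) / (initial RFP/GFP).

    ``initial`` and ``final`` are (GFP, RFP) cell counts.  A neutral test
    virus gives 1.  Zero GFP (either time) or zero initial RFP makes the
    ratio undefined: returns NaN with a warning.
    """
    (gfp0, rfp0), (gfp1, rfp1) = initial, final
    if gfp0 <= 0 or gfp1 <= 0 or rfp0 <= 0:
        warnings.warn("competition ratio undefined (zero reference count)",
                      stacklevel=2)
        return float("nan")
    return (rfp1 / gfp1) / (rfp0 / gfp0)


# --- normality-gated test dispatch ---------------------------------------

class ComparisonDesign(str, Enum):
    PAIRED = "PAIRED"
    UNPAIRED = "UNPAIRED"
    DISTRIBUTIONS = "DISTRIBUTIONS"


@dataclass(frozen=True)
class DispatchResult:
    test_name: str
    statistic: float
    p_value: float
    shapiro_p: tuple[float, ...]


def normality_dispatch(
    a: Sequence[float],
    b: Sequence[float],
    design: ComparisonDesign | str = ComparisonDesign.UNPAIRED,
    shapiro_alpha: float = 0.05,
) -> DispatchResult:
    """Choose and run the comparison test the way the study's statistics did.

    Both groups are first checked for normality with Shapiro-Wilk at
    ``shapiro_alpha``.  If both pass, a two-tailed t-test is run (paired or
    unpaired per ``design``); otherwise a two-tailed Mann-Whitney U (exact
    when both groups have n <= 8 and no ties, midrank normal approximation
    otherwise).  ``design=DISTRIBUTIONS`` compares frequency distributions
    with a two-sample Kolmogorov-Smirnov test, skipping the normality gate.
    Group sizes below 3 make normality untestable and raise.
    """
    design = ComparisonDesign(design)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if design is ComparisonDesign.DISTRIBUTIONS:
        res = stats.ks_2samp(a, b)
        return DispatchResult("kolmogorov-smirnov", float(res.statistic),
                              float(res.pvalue), ())
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group to test normality")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on near-identical data
        sw = tuple(float(stats.shapiro(g).pvalue) for g in (a, b))
    normal = all(p > shapiro_alpha for p in sw)
    if normal:
        if design is ComparisonDesign.PAIRED:
            if len(a) != len(b):
                raise ValueError("paired design requires equal group sizes")
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "unpaired t-test"
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # identical paired samples: no variance, no effect
            stat, p = 0.0, 1.0
    else:
        method = "exact" if (len(a) <= 8 and len(b) <= 8
                             and len(np.unique(np.r_[a, b])) == len(a) + len(b)) \
            else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        name, stat, p = "mann-whitney", float(res.statistic), float(res.pvalue)
    return DispatchResult(name, stat, p, sw)


# --- convenience: full pipeline ------------------------------------------

def analyze_screen(
    counts: CountTable,
    manifest: LibraryManifest,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    fdr: float = 0.10,
    fold_threshold: float = 2.0,
    min_shrnas: int = 2,
    epi_neutrality_threshold: float = 1.0,
    test_mode: str = "vs_scr",
) -> dict:
    """Count table -> fold changes -> tests -> gene calls -> classification."""
    fc = normalize_log2fc(counts, manifest, pseudocount=pseudocount)
    tests = shrna_test(fc, alpha=alpha, fdr=fdr, mode=test_mode)
    calls = call_gene_hits(tests, fold_threshold=fold_threshold,
                           min_shrnas=min_shrnas, alpha=alpha, fdr=fdr)
    classes = classify_candidates(calls, fc,
                                  epi_neutrality_threshold=epi_neutrality_threshold)
    return {"fold_changes": fc, "tests": tests, "calls": calls,
            "classification": classes}
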