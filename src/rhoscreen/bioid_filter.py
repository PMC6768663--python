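"""Replicate-presence filtering of a BioID proximity interactome.

The proximity-labeling experiment compares a promiscuous-ligase bait fusion
(BAIT arm) against a ligase-GFP control (CONTROL arm), each in replicate.  A
protein belongs to the interactome when it is identified in at least two of
the three bait replicates and in none of the control samples.  Upstream
peptide identification and FDR filtering are out of scope: the input is a
finished protein x replicate detection-count matrix, where detection means
count > 0.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ARMS = ("BAIT", "CONTROL")


class DetectionMatrix:
    """Protein x replicate detection counts with an arm per column.

    ``counts`` is indexed by protein id; ``arms`` maps each column to
    "BAIT" or "CONTROL".  On disk this is a TSV whose column headers are
    ``ARM:replicate`` (e.g. ``BAIT:1``).
    """

    def __init__(self, counts: pd.DataFrame, arms: pd.Series):
        if counts.shape[1] == 0:
            raise ValueError("detection matrix has no replicate columns")
        if list(counts.columns) != list(arms.index):
            raise ValueError("arm metadata does not match columns")
        unknown = set(arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arm label(s): {sorted(unknown)}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("detection counts must be non-negative")
        self.counts = counts
        self.arms = arms

    def columns(self, arm: str) -> list[str]:
        return list(self.arms.index[self.arms == arm])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DetectionMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        arms = pd.Series({c: c.split(":", 1)[0] for c in counts.columns})
        return cls(counts, arms)


def filter_interactome(
    det: DetectionMatrix,
    min_bait: int = 2,
    max_control: int = 0,
) -> pd.DataFrame:
    """Keep proteins detected in >= ``min_bait`` bait replicates and
    <= ``max_control`` control replicates (default: absent from all).

    Returns columns protein, n_bait_detected, n_control_detected,
    total_count (summed bait detection counts, the "frequency" used for the
    interactome cloud), sorted by descending total_count then protein id.
    """
    bait_cols = det.columns("BAIT")
    control_cols = det.columns("CONTROL")
    if len(bait_cols) < min_bait:
        raise ValueError(f"need >= {min_bait} bait replicates, "
                         f"have {len(bait_cols)}")
    detected = det.counts > 0
    n_bait = detected[bait_cols].sum(axis=1)
    n_control = detected[control_cols].sum(axis=1) if control_cols else 0
    keep = (n_bait >= min_bait) & (n_control <= max_control)
    out = pd.DataFrame({
        "protein": det.counts.index[keep],
        "n_bait_detected": n_bait[keep].to_numpy(),
        "n_control_detected": (n_control[keep].to_numpy()
                               if control_cols else 0),
        "total_count": det.counts.loc[keep, bait_cols].sum(axis=1).to_numpy(),
    })
    return (out.sort_values(["total_count", "protein"],
                            ascending=[False, True])
            .reset_index(drop=True))


def frequency_table(entries: pd.DataFrame) -> pd.DataFrame:
    """Relative detection frequencies for the interactome word cloud.

    Reports both readings of "frequency": ``freq_spectral`` normalizes the
    summed detection counts, ``freq_replicates`` the number of bait
    replicates each protein was seen in.  Each column sums to 1.
    """
    if len(entries) == 0:
        raise ValueError("empty interactome")
    total_counts = entries["total_count"].sum()
    if total_counts <= 0:
        raise ValueError("all detection counts are zero")
    return pd.DataFrame({
        "protein": entries["protein"],
        "freq_spectral": entries["total_count"] / total_counts,
        "freq_replicates": (entries["n_bait_detected"]
                            / entries["n_bait_detected"].sum()),
    })
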