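"""Isobaric reporter-ion (iTRAQ-style) differential interactomics.

Per-protein relative abundance between genotypes is the median (or mean)
of peptide-level reporter intensity ratios. Each prey's KO:KI ratio is
then normalized to the bait's own KO:KI ratio, so calls reflect changes
in association with the bait rather than pulldown yield. Partners with a
bait-normalized ratio at or above the gain threshold are called gained,
at or below the loss threshold lost, otherwise unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ItraqConfig

CHANNELS = ["intensity_ki", "intensity_wt_mock", "intensity_ko", "intensity_ko_mock"]


class BaitNotQuantifiedError(RuntimeError):
    """The bait has no usable peptides; normalization is impossible."""


def protein_ratio(
    numerator: pd.Series | np.ndarray,
    denominator: pd.Series | np.ndarray,
    aggregate: str = "median",
) -> float:
    """Aggregate peptide-level intensity ratios into one protein ratio.

    Peptides with a missing or non-positive intensity in either channel
    are dropped; NaN is returned when nothing is quantifiable.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    ok = np.isfinite(num) & np.isfinite(den) & (num > 0) & (den > 0)
    if not ok.any():
        return float("nan")
    ratios = num[ok] / den[ok]
    if aggregate == "median":
        return float(np.median(ratios))
    if aggregate == "mean":
        return float(np.mean(ratios))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def quantify(itraq: pd.DataFrame, config: ItraqConfig | None = None) -> pd.DataFrame:
    """Per-protein KI:WT and KO:KI ratios from the peptide-level table.

    ``itraq`` columns: protein, peptide_id, intensity_ki,
    intensity_wt_mock, intensity_ko, intensity_ko_mock. With
    ``subtract_mock`` the mock-channel intensity is subtracted from the
    matching pulldown channel first (clipped at zero, which drops the
    peptide from that ratio).
    """
    config = config or ItraqConfig()
    missing = {"protein", "peptide_id", *CHANNELS} - set(itraq.columns)
    if missing:
        raise ValueError(f"itraq table missing columns: {sorted(missing)}")
    rows = []
    for protein, g in itraq.groupby("protein", sort=True):
        ki = g["intensity_ki"].astype(float)
        ko = g["intensity_ko"].astype(float)
        wt_mock = g["intensity_wt_mock"].astype(float)
        ko_mock = g["intensity_ko_mock"].astype(float)
        if config.subtract_mock:
            ki = (ki - wt_mock).clip(lower=0.0)
            ko = (ko - ko_mock).clip(lower=0.0)
        rows.append(
            {
                "protein": protein,
                "n_peptides": len(g),
                "ratio_ki_wt": protein_ratio(ki, wt_mock, config.aggregate),
                "ratio_ko_ki": protein_ratio(ko, ki, config.aggregate),
            }
        )
    return pd.DataFrame(rows)


def bait_normalize(ratios: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every KO:KI ratio by the bait's; the bait maps to exactly 1."""
    bait_rows = ratios.loc[ratios["protein"] == bait_id, "ratio_ko_ki"]
    if bait_rows.empty or not np.isfinite(bait_rows.iloc[0]) or bait_rows.iloc[0] <= 0:
        raise BaitNotQuantifiedError(
            f"bait {bait_id!r} is not quantified; cannot normalize"
        )
    bait_ratio = float(bait_rows.iloc[0])
    out = ratios.copy()
    out["norm_ratio_ko_ki"] = out["ratio_ko_ki"] / bait_ratio
    out.loc[out["protein"] == bait_id, "norm_ratio_ko_ki"] = 1.0
    return out


def rewiring_report(
    normalized: pd.DataFrame,
    gain_threshold: float = 2.0,
    loss_threshold: float = 0.5,
    bait_id: str | None = None,
) -> pd.DataFrame:
    """Call gained / lost / unchanged partners from bait-normalized ratios."""
    out = normalized.copy()
    r = out["norm_ratio_ko_ki"]
    call = pd.Series("unchanged", index=out.index)
    call[r >= gain_threshold] = "gained"
    call[r <= loss_threshold] = "lost"
    call[~np.isfinite(r)] = "not_quantified"
    if bait_id is not None:
        call[out["protein"] == bait_id] = "bait"
    out["call"] = call
    return out


def analyze_itraq(
    itraq: pd.DataFrame, bait_id: str, config: ItraqConfig | None = None
) -> pd.DataFrame:
    """Full chain: quantify -> bait-normalize -> call re-wiring."""
    config = config or ItraqConfig()
    ratios = quantify(itraq, config)
    normalized = bait_normalize(ratios, bait_id)
    return rewiring_report(
        normalized, config.gain_threshold, config.loss_threshold, bait_id
    )
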