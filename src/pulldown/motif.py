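"""Proline-directed (Cdk-type) phosphorylation motif scoring.

A functional stand-in for a web-service motif scanner: every S/T with
the mandatory proline at +1 is a candidate site, scored as a normalized
weighted mismatch against a window model (0 = perfect consensus,
1 = worst). A protein's score is its best (minimum) site score, 1.0 if
it has no candidate sites. Stringency classes are calibrated as
percentile cutoffs of the protein-score distribution over a background
proteome: the high-confidence class is the lowest-scoring 0.2% by
default and the medium class the lowest 1.0%, so high is nested in
medium by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class CalibrationError(ValueError):
    """Raised when the background score distribution cannot calibrate cutoffs."""


@dataclass(frozen=True)
class MotifFeature:
    offset: int  # relative to the phosphoacceptor (0)
    residues: frozenset[str]
    weight: float


@dataclass(frozen=True)
class MotifModel:
    """Window model for S/T-P-x-K/R sites.

    ``features`` are penalty terms: a site's raw score is the weight sum
    of mismatched features divided by the total weight. The +1 proline is
    both a gating requirement (no site without it) and a feature, so it
    always matches on scored sites. Offsets outside the sequence count as
    mismatches.
    """

    phosphoacceptors: frozenset[str] = frozenset("ST")
    features: tuple[MotifFeature, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.features:
            raise ValueError("motif model needs at least one feature")
        if any(f.weight < 0 for f in self.features):
            raise ValueError("feature weights must be >= 0")
        if not any(f.offset == 1 and "P" in f.residues for f in self.features):
            raise ValueError("model must include the mandatory +1 proline feature")

    @property
    def total_weight(self) -> float:
        return sum(f.weight for f in self.features)


def default_model() -> MotifModel:
    """Default full-Cdk-site model: mandatory +1 P, basic residue at +3,
    and small/flexible context preferences at -2..+5."""
    f = MotifFeature
    return MotifModel(
        features=(
            f(+1, frozenset("P"), 2.0),
            f(+3, frozenset("KR"), 2.0),
            f(-2, frozenset("SPA"), 0.5),
            f(+2, frozenset("SPA"), 0.5),
            f(+4, frozenset("SPA"), 0.5),
            f(+5, frozenset("KRA"), 0.5),
        )
    )


def two_feature_model() -> MotifModel:
    """Minimal equal-weight model (+1 P, +3 K/R); handy for worked examples."""
    return MotifModel(
        features=(
            MotifFeature(+1, frozenset("P"), 1.0),
            MotifFeature(+3, frozenset("KR"), 1.0),
        )
    )


def score_sites(sequence: str, model: MotifModel | None = None) -> list[tuple[int, str, float]]:
    """Score every candidate phosphosite in a sequence.

    Returns ``(position, residue, score)`` triples with 1-based positions,
    one per S/T followed by the mandatory +1 proline.
    """
    model = model or default_model()
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    total = model.total_weight
    sites = []
    for i, res in enumerate(sequence):
        if res not in model.phosphoacceptors:
            continue
        if i + 1 >= len(sequence) or sequence[i + 1] != "P":
            continue
        mismatch = 0.0
        for feat in model.features:
            j = i + feat.offset
            if not (0 <= j < len(sequence)) or sequence[j] not in feat.residues:
                mismatch += feat.weight
        sites.append((i + 1, res, mismatch / total))
    return sites


def protein_score(sequence: str, model: MotifModel | None = None) -> float:
    """Best (minimum) site score of the protein; 1.0 if it has no sites."""
    sites = score_sites(sequence, model)
    return min((s for _, _, s in sites), default=1.0)


def score_proteome(
    sequences: dict[str, str], model: MotifModel | None = None
) -> pd.Series:
    model = model or default_model()
    return pd.Series(
        {p: protein_score(seq, model) for p, seq in sequences.items()},
        name="motif_score",
    ).sort_index()


@dataclass
class StringencyCalibration:
    high_percentile: float
    medium_percentile: float
    high_threshold: float
    medium_threshold: float
    median_high: float
    median_medium: float
    median_background: float


def calibrate_and_classify(
    background_scores: pd.Series,
    high_percentile: float = 0.2,
    medium_percentile: float = 1.0,
) -> tuple[pd.Series, StringencyCalibration]:
    """Percentile-calibrated stringency classes over a background proteome.

    Thresholds are the empirical quantiles of the background protein-score
    distribution at ``high_percentile`` / ``medium_percentile`` (percent).
    A protein scoring at or below a threshold joins that class; the high
    class is nested within medium. Returns the per-protein class Series
    ('high' / 'medium' / 'none') and the calibration (thresholds + class
    and background medians).
    """
    scores = pd.Series(background_scores).astype(float)
    if len(scores) < 1000:
        raise CalibrationError("background must contain at least 1000 proteins")
    if float(scores.max()) == float(scores.min()):
        raise CalibrationError("degenerate background: all scores identical")
    if not 0 < high_percentile <= medium_percentile <= 100:
        raise CalibrationError("need 0 < high_percentile <= medium_percentile <= 100")
    hi_thr = float(np.quantile(scores, high_percentile / 100.0))
    med_thr = float(np.quantile(scores, medium_percentile / 100.0))
    classes = pd.Series("none", index=scores.index, name="stringency")
    classes[scores <= med_thr] = "medium"
    classes[scores <= hi_thr] = "high"
    in_high = scores <= hi_thr
    in_medium = scores <= med_thr  # high is nested in medium
    calib = StringencyCalibration(
        high_percentile=high_percentile,
        medium_percentile=medium_percentile,
        high_threshold=hi_thr,
        medium_threshold=med_thr,
        median_high=float(scores[in_high].median()) if in_high.any() else float("nan"),
        median_medium=float(scores[in_medium].median()) if in_medium.any() else float("nan"),
        median_background=float(scores.median()),
    )
    return classes, calib


def class_members(classes: pd.Series, stringency: str) -> set[str]:
    """Members of a stringency tier; 'medium' includes the nested high tier."""
    if stringency == "high":
        return set(classes.index[classes == "high"])
    if stringency == "medium":
        return set(classes.index[classes.isin(["high", "medium"])])
    raise ValueError(f"unknown stringency {stringency!r}")


def substrate_prediction_enrichment(
    interactomes: dict[str, set[str]],
    classes: pd.Series,
    combined: set[str] | None = None,
) -> pd.DataFrame:
    """Predicted-substrate enrichment tables, overall and per organ.

    For each scope (the combined interactome plus every organ) and each
    stringency tier, counts predicted substrates inside the scope vs the
    whole scored background and runs the one-tailed Fisher test with the
    scope subtracted from the background row.
    """
    from .enrichment import substrate_overlay_counts

    if combined is None:
        combined = set().union(*interactomes.values()) if interactomes else set()
    if not combined:
        raise ValueError("empty interactome")
    background = set(classes.index)
    scopes = {"combined": combined, **interactomes}
    rows = []
    for scope_name, members in scopes.items():
        members = members & background
        for tier in ("high", "medium"):
            tier_set = class_members(classes, tier)
            res = substrate_overlay_counts(
                len(members & tier_set), len(members), len(tier_set), len(background)
            )
            rows.append(
                {
                    "scope": scope_name,
                    "stringency": tier,
                    "predicted": res["hits"],
                    "interactome_size": res["list_size"],
                    "background_predicted": res["background_hits"],
                    "background_size": res["background_size"],
                    "percent": res["list_percent"],
                    "background_percent": res["background_percent"],
                    "fold": res["fold"],
                    "p": res["p"],
                }
            )
    return pd.DataFrame(rows)
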