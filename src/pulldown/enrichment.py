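"""Functional annotation of interactomes.

Three analyses: a single primary-function label per interactor (first
match in a priority-ordered vocabulary of mapped gene-set terms), a
per-organ fold-enrichment heatmap of biological-process terms filtered
by EASE score, and the known-substrate overlay test (one-tailed Fisher
of the interactome's substrate rate against the whole-proteome rate).

Background convention: the background term/substrate counts describe the
*whole* annotation universe including the gene list; the list is
subtracted from the background row before the exact test so the two rows
of the 2x2 table are disjoint (this reproduces the study's printed
p-values, e.g. 15/117 vs 390/19,999 -> p = 8.9e-9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .stats import ease_score, enrichment_fisher, fisher_one_tailed

#: default priority order of the primary-function vocabulary
DEFAULT_PRIORITY = [
    "cell cycle",
    "transcription",
    "neuronal function",
    "microtubules/cytoskeleton",
    "ubiquitination",
    "metabolism",
]

#: default mapping of vocabulary labels to annotation term names
DEFAULT_VOCAB_MAP = {
    "cell cycle": ["CELL_CYCLE"],
    "transcription": ["TRANSCRIPTION"],
    "neuronal function": ["NEURONAL_FUNCTION"],
    "microtubules/cytoskeleton": ["MICROTUBULE_CYTOSKELETON"],
    "ubiquitination": ["UBIQUITINATION"],
    "metabolism": ["METABOLISM"],
}


def assign_primary_function(
    protein: str,
    annotations: dict[str, set[str]],
    vocab_map: dict[str, list[str]] | None = None,
    priority: list[str] | None = None,
) -> str:
    """First vocabulary label (in priority order) annotating the protein;
    ``"other"`` if none do."""
    vocab_map = vocab_map if vocab_map is not None else DEFAULT_VOCAB_MAP
    priority = priority if priority is not None else DEFAULT_PRIORITY
    for label in priority:
        for term in vocab_map.get(label, []):
            if protein in annotations.get(term, set()):
                return label
    return "other"


def primary_function_table(
    interactomes: dict[str, set[str]],
    annotations: dict[str, set[str]],
    vocab_map: dict[str, list[str]] | None = None,
    priority: list[str] | None = None,
    frequent_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-organ primary-function label frequencies.

    Returns one row per (organ, label) with count, frequency and a flag
    for labels covering at least ``frequent_fraction`` of the organ's
    interactors. Frequencies sum to 1 within each organ.
    """
    priority = priority if priority is not None else DEFAULT_PRIORITY
    labels = list(priority) + ["other"]
    rows = []
    for organ, members in interactomes.items():
        counts = {lab: 0 for lab in labels}
        for p in sorted(members):
            counts[assign_primary_function(p, annotations, vocab_map, priority)] += 1
        n = len(members)
        for lab in labels:
            freq = counts[lab] / n if n else 0.0
            rows.append(
                {
                    "organ": organ,
                    "label": lab,
                    "count": counts[lab],
                    "frequency": freq,
                    "frequent": freq >= frequent_fraction,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentCell:
    organ: str
    term: str
    k: int  # interactors annotated to the term
    n: int  # organ interactome size (within the background)
    K: int  # background genes in the term
    N: int  # background size
    fold: float
    fisher_p: float
    ease_p: float


def enrichment_cell(
    interactors: set[str], term_genes: set[str], background: set[str], organ: str, term: str
) -> EnrichmentCell:
    members = interactors & background
    genes = term_genes & background
    k = len(members & genes)
    n, K, N = len(members), len(genes), len(background)
    fold = (k / n) / (K / N) if n and K else 0.0
    return EnrichmentCell(
        organ=organ,
        term=term,
        k=k,
        n=n,
        K=K,
        N=N,
        fold=fold,
        fisher_p=enrichment_fisher(k, n, K, N),
        ease_p=ease_score(k, n, K, N),
    )


def enrichment_heatmap(
    interactomes: dict[str, set[str]],
    annotations: dict[str, set[str]],
    background: set[str],
    ease_threshold: float = 0.2,
    fold_clamp: tuple[float, float] = (1.0, 5.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-enrichment heatmap over (organ, term) with EASE row filtering.

    Returns ``(cells, display)``: ``cells`` has one row per organ x term
    with k/n/K/N, fold, Fisher and EASE p-values plus the row-retention
    flag (a term is kept if its minimum EASE score over organs is at or
    below ``ease_threshold``); ``display`` is the retained organ x term
    matrix of folds clamped to ``fold_clamp`` for plotting.
    """
    rows = []
    for term in sorted(annotations):
        genes = annotations[term] & background
        if not genes:
            warnings.warn(f"term {term!r} absent from background; skipped", stacklevel=2)
            continue
        for organ in interactomes:
            c = enrichment_cell(interactomes[organ], genes, background, organ, term)
            rows.append(vars(c))
    cells = pd.DataFrame(rows)
    if cells.empty:
        return cells, pd.DataFrame()
    min_ease = cells.groupby("term")["ease_p"].transform("min")
    cells["retained"] = min_ease <= ease_threshold
    lo, hi = fold_clamp
    kept = cells[cells["retained"]]
    display = (
        kept.assign(display_fold=kept["fold"].clip(lo, hi))
        .pivot(index="term", columns="organ", values="display_fold")
        .sort_index()
    )
    return cells, display


def substrate_overlay_counts(
    hits: int, list_size: int, background_hits: int, background_size: int
) -> dict:
    """Known-substrate overlay from printed-style counts.

    ``background_hits / background_size`` is the whole-proteome substrate
    rate including the list; the Fisher table subtracts the list from the
    background row. Fold is the ratio of the printed rates.
    """
    if list_size > background_size:
        raise ValueError("gene list larger than the background proteome")
    if hits > list_size or background_hits > background_size:
        raise ValueError("hits exceed set sizes")
    if hits > background_hits:
        raise ValueError("list hits exceed background hits")
    rate_list = hits / list_size if list_size else 0.0
    rate_bg = background_hits / background_size if background_size else 0.0
    fold = rate_list / rate_bg if rate_bg else 0.0
    if background_hits == 0:
        p = 1.0
    else:
        p = fisher_one_tailed(
            hits,
            list_size - hits,
            background_hits - hits,
            (background_size - background_hits) - (list_size - hits),
        )
    return {
        "hits": hits,
        "list_size": list_size,
        "background_hits": background_hits,
        "background_size": background_size,
        "list_percent": 100.0 * rate_list,
        "background_percent": 100.0 * rate_bg,
        "fold": fold,
        "p": p,
    }


def substrate_overlay(
    interactome: set[str],
    substrates: set[str],
    background_size: int,
    background_hits: int | None = None,
) -> dict:
    """Overlay an interactor set with a known-substrate list.

    ``background_hits`` defaults to the size of the substrate list (i.e.
    the list is assumed to lie within the ``background_size`` proteome).
    """
    hits = len(interactome & substrates)
    if background_hits is None:
        background_hits = len(substrates)
    return substrate_overlay_counts(hits, len(interactome), background_hits, background_size)
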