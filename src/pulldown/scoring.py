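"""Interactor calling from replicated KI vs mock spectral-count runs.

For every (tissue, protein) pair the scorer fills an evidence row with
the four statistics of the study's supplementary interactor tables:

* ``p_tissue`` — one-tailed Fisher exact p on the detection table
  [[runs_detected_KI, n_runs_KI - detected], [detected_WT, n_WT - detected]],
* ``ratio_tissue`` — pseudocounted per-run peptide-rate ratio KI/WT,
* ``p_all`` / ``ratio_all`` — the same computed on runs pooled over all
  tissues.

Categories (three-tier classification with network rescue):

* BAIT — the tagged protein itself.
* CORE (Category 1) — passes the per-tissue statistical thresholds, or is
  promoted because it passed them in another organ and was detected here
  with a KI-biased ratio.
* CAT2 — sub-threshold in this tissue but significant on pooled evidence
  and database-linked to a same-tissue CORE interactor.
* CAT3 — detection-only rescue: repeatedly detected, KI-biased, and
  database-linked to a same-tissue CORE interactor.
* REJECTED — everything else; mock-dominated proteins (ratio <= 1 or no KI
  detections) are rejected regardless of other rules (background
  subtraction).
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import ScoringThresholds
from .stats import fisher_one_tailed

CALLED_CATEGORIES = ("CORE", "CAT2", "CAT3")

EVIDENCE_COLUMNS = [
    "protein",
    "tissue",
    "peptides_ki",
    "peptides_wt",
    "runs_detected_ki",
    "runs_detected_wt",
    "n_runs_ki",
    "n_runs_wt",
    "p_tissue",
    "ratio_tissue",
    "p_all",
    "ratio_all",
    "category",
    "promoted",
]


def detection_pvalue(
    runs_detected_ki: int, n_runs_ki: int, runs_detected_wt: int, n_runs_wt: int
) -> float:
    """One-tailed Fisher p for KI-biased detection across replicate runs."""
    if n_runs_ki < 1 or n_runs_wt < 1:
        raise ValueError("need at least one run in each genotype")
    return fisher_one_tailed(
        runs_detected_ki,
        n_runs_ki - runs_detected_ki,
        runs_detected_wt,
        n_runs_wt - runs_detected_wt,
    )


def rate_ratio(
    peptides_ki: float,
    n_runs_ki: int,
    peptides_wt: float,
    n_runs_wt: int,
    pseudocount: float = 0.5,
) -> float:
    """Pseudocounted per-run peptide rate ratio (KI rate / WT rate)."""
    if n_runs_ki < 1 or n_runs_wt < 1:
        raise ValueError("need at least one run in each genotype")
    return (peptides_ki / n_runs_ki + pseudocount) / (
        peptides_wt / n_runs_wt + pseudocount
    )


def score_runs(
    runs: pd.DataFrame,
    thresholds: ScoringThresholds | None = None,
) -> pd.DataFrame:
    """Compute evidence rows (statistics only) for every tissue x protein.

    ``runs`` is the long per-run count table (run_id, tissue, genotype,
    protein, peptide_count). A protein gets a row in every tissue where it
    was detected in at least one run of either genotype; pooled statistics
    use all runs of all tissues.
    """
    thresholds = thresholds or ScoringThresholds()
    required = {"run_id", "tissue", "genotype", "protein", "peptide_count"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"runs table missing columns: {sorted(missing)}")
    if not set(runs["genotype"]).issubset({"KI", "WT"}):
        raise ValueError("genotype must be 'KI' or 'WT'")

    run_meta = runs[["run_id", "tissue", "genotype"]].drop_duplicates()
    n_runs = run_meta.groupby(["tissue", "genotype"])["run_id"].nunique().unstack(fill_value=0)
    for g in ("KI", "WT"):
        if g not in n_runs.columns:
            n_runs[g] = 0
    total_ki = int(n_runs["KI"].sum())
    total_wt = int(n_runs["WT"].sum())

    per = (
        runs.groupby(["tissue", "genotype", "protein"])
        .agg(peptides=("peptide_count", "sum"), detections=("run_id", "nunique"))
        .reset_index()
    )
    wide = per.pivot_table(
        index=["tissue", "protein"],
        columns="genotype",
        values=["peptides", "detections"],
        fill_value=0,
        aggfunc="sum",
    )
    wide.columns = [f"{a}_{b.lower()}" for a, b in wide.columns]
    for col in ("peptides_ki", "peptides_wt", "detections_ki", "detections_wt"):
        if col not in wide.columns:
            wide[col] = 0
    wide = wide.reset_index()

    pooled = (
        wide.groupby("protein")[
            ["peptides_ki", "peptides_wt", "detections_ki", "detections_wt"]
        ]
        .sum()
        .rename(columns=lambda c: f"all_{c}")
    )

    pc = thresholds.pseudocount
    rows = []
    pool_p_cache: dict[str, float] = {}
    for rec in wide.itertuples(index=False):
        tissue, protein = rec.tissue, rec.protein
        nki = int(n_runs.loc[tissue, "KI"])
        nwt = int(n_runs.loc[tissue, "WT"])
        if nki < 1 or nwt < 1:
            raise ValueError(f"tissue {tissue!r} lacks runs in one genotype")
        det_ki, det_wt = int(rec.detections_ki), int(rec.detections_wt)
        pep_ki, pep_wt = int(rec.peptides_ki), int(rec.peptides_wt)
        pool = pooled.loc[protein]
        if protein not in pool_p_cache:
            pool_p_cache[protein] = detection_pvalue(
                int(pool["all_detections_ki"]), total_ki,
                int(pool["all_detections_wt"]), total_wt,
            )
        rows.append(
            {
                "protein": protein,
                "tissue": tissue,
                "peptides_ki": pep_ki,
                "peptides_wt": pep_wt,
                "runs_detected_ki": det_ki,
                "runs_detected_wt": det_wt,
                "n_runs_ki": nki,
                "n_runs_wt": nwt,
                "p_tissue": detection_pvalue(det_ki, nki, det_wt, nwt),
                "ratio_tissue": rate_ratio(pep_ki, nki, pep_wt, nwt, pc),
                "p_all": pool_p_cache[protein],
                "ratio_all": rate_ratio(
                    int(pool["all_peptides_ki"]), total_ki,
                    int(pool["all_peptides_wt"]), total_wt, pc,
                ),
                "category": "UNSCORED",
                "promoted": False,
            }
        )
    out = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    return out.sort_values(["tissue", "protein"], ignore_index=True)


def assign_categories(
    evidence: pd.DataFrame,
    edges: pd.DataFrame | None,
    thresholds: ScoringThresholds | None = None,
    bait_id: str = "BAIT",
) -> pd.DataFrame:
    """Assign BAIT/CORE/CAT2/CAT3/REJECTED to every evidence row.

    Promotion (cross-organ rescue) requires all tissues to be scored
    together: a protein that is CORE by statistics in one organ becomes
    CORE (``promoted=True``) in any other organ where it was detected with
    a KI-biased ratio. Category 2/3 rescue requires a database edge to a
    same-tissue CORE interactor.
    """
    thresholds = thresholds or ScoringThresholds()
    ev = evidence.copy()

    p_core = ev["p_tissue"]
    if thresholds.fdr:
        p_core = pd.Series(
            multipletests(ev["p_tissue"], method="fdr_bh")[1], index=ev.index
        )
    stat_core = (
        (p_core <= thresholds.alpha_core)
        & (ev["ratio_tissue"] >= thresholds.min_ratio)
        & (ev["runs_detected_ki"] >= thresholds.min_ki_detections)
        & (ev["protein"] != bait_id)
    )
    core_proteins = set(ev.loc[stat_core, "protein"])

    is_bait = ev["protein"] == bait_id
    background = (ev["ratio_tissue"] <= 1.0) | (ev["runs_detected_ki"] == 0)
    promoted = (
        ~stat_core
        & ~is_bait
        & ~background
        & ev["protein"].isin(core_proteins)
    )
    core = stat_core | promoted

    adjacency = _database_adjacency(edges, set(ev["protein"]) | {bait_id})
    core_by_tissue = {
        t: set(ev.loc[core & (ev["tissue"] == t), "protein"])
        for t in ev["tissue"].unique()
    }
    linked = pd.Series(
        [
            bool(adjacency.get(p, set()) & (core_by_tissue[t] - {p}))
            for p, t in zip(ev["protein"], ev["tissue"])
        ],
        index=ev.index,
    )
    cat2 = (
        ~core & ~is_bait & ~background & (ev["p_all"] <= thresholds.alpha_pooled) & linked
    )
    cat3 = (
        ~core
        & ~cat2
        & ~is_bait
        & ~background
        & (ev["runs_detected_ki"] >= thresholds.min_ki_detections)
        & (ev["ratio_tissue"] > 1.0)
        & linked
    )

    ev["category"] = "REJECTED"
    ev.loc[core, "category"] = "CORE"
    ev.loc[cat2, "category"] = "CAT2"
    ev.loc[cat3, "category"] = "CAT3"
    ev.loc[is_bait, "category"] = "BAIT"
    ev["promoted"] = promoted
    return ev


def _database_adjacency(
    edges: pd.DataFrame | None, known: set[str]
) -> dict[str, set[str]]:
    if edges is None or len(edges) == 0:
        return {}
    unknown = (set(edges["protein_a"]) | set(edges["protein_b"])) - known
    if unknown:
        warnings.warn(
            f"{len(unknown)} edge endpoint(s) not in the scored protein set; "
            "those edges are kept for rescue lookups only among scored proteins",
            stacklevel=2,
        )
    g = nx.from_pandas_edgelist(edges, "protein_a", "protein_b")
    return {p: set(g.neighbors(p)) for p in g.nodes}


def interactomes_by_tissue(evidence: pd.DataFrame, core_only: bool = False) -> dict[str, set[str]]:
    """Called interactor sets per tissue (CORE, or CORE+CAT2+CAT3)."""
    cats = ("CORE",) if core_only else CALLED_CATEGORIES
    keep = evidence[evidence["category"].isin(cats)]
    out = {t: set(g["protein"]) for t, g in keep.groupby("tissue")}
    for t in evidence["tissue"].unique():
        out.setdefault(t, set())
    return out


def combined_interactome(evidence: pd.DataFrame, core_only: bool = False) -> pd.DataFrame:
    """One row per called protein with the organs it was called in."""
    cats = ("CORE",) if core_only else CALLED_CATEGORIES
    keep = evidence[evidence["category"].isin(cats)]
    rows = []
    for protein, g in keep.groupby("protein"):
        cats_seen = set(g["category"])
        best = next(c for c in ("CORE", "CAT2", "CAT3") if c in cats_seen)
        rows.append(
            {
                "protein": protein,
                "organs": ",".join(sorted(g["tissue"])),
                "n_organs": g["tissue"].nunique(),
                "best_category": best,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "organs", "n_organs", "best_category"]
    ).sort_values("protein", ignore_index=True)
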