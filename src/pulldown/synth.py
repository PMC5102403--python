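"""Synthetic AP-MS study generator with known ground truth.

Emulates a replicated tagged-bait purification study across several
organs: per-run spectral counts for knock-in (KI) and mock (WT)
purifications, a database-style protein interaction edge list in which
most true interactors connect to other true interactors, gene-set
annotations, known-substrate labels enriched among true interactors,
protein sequences carrying planted phosphorylation motifs, and 4-channel
isobaric (iTRAQ-style) reporter intensities for a two-genotype
comparison with planted re-wired partners.

All randomness flows from ``SynthConfig.seed`` through named substreams
(universe / runs / itraq), so each stage can be regenerated
independently and identical configs yield byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SynthConfig
from . import io as pio

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: embedded consensus phosphosite: S at +0, P at +1, K at +3, favourable context
MOTIF_INSERT = "SASPAKAA"
#: indices of the context positions in MOTIF_INSERT (offsets -2, +2, +4, +5)
_MOTIF_CONTEXT_IDX = (0, 4, 6, 7)

VOCAB_TERMS = [
    "CELL_CYCLE",
    "TRANSCRIPTION",
    "NEURONAL_FUNCTION",
    "MICROTUBULE_CYTOSKELETON",
    "UBIQUITINATION",
    "METABOLISM",
]

_STREAM_UNIVERSE, _STREAM_RUNS, _STREAM_ITRAQ = 1, 2, 3


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted: dict[str, set[str]]  # organ -> planted interactor ids
    substrates: set[str]
    itraq_folds: dict[str, float]  # protein -> true KO:KI fold change
    gained: set[str]
    lost: set[str]
    contaminant_ranks: dict[str, int]  # protein -> 1-based stickiness rank

    def to_dict(self) -> dict:
        return {
            "planted": {o: sorted(s) for o, s in self.planted.items()},
            "substrates": sorted(self.substrates),
            "itraq_folds": dict(sorted(self.itraq_folds.items())),
            "gained": sorted(self.gained),
            "lost": sorted(self.lost),
            "contaminant_ranks": dict(sorted(self.contaminant_ranks.items())),
        }


@dataclass
class Universe:
    """Static catalog shared by every run of the study."""

    proteins: list[str]
    edges: pd.DataFrame  # columns: protein_a, protein_b, source
    annotations: dict[str, set[str]]
    substrates: set[str]
    sequences: dict[str, str]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _draw_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int, model: str
) -> np.ndarray:
    """Spectral counts: NB with var = mean + dispersion*mean^2, or Poisson."""
    if model == "poisson" or dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


# ---------------------------------------------------------------------------
# universe
# ---------------------------------------------------------------------------

def generate_universe(config: SynthConfig) -> tuple[Universe, GroundTruth]:
    """Create the protein catalog, edge list, annotations, substrate labels
    and sequences, together with the planted ground truth."""
    rng = _rng(config, _STREAM_UNIVERSE)
    n = config.n_proteins
    proteins = [config.bait_id] + [f"P{i:05d}" for i in range(1, n)]
    prey = np.array(proteins[1:])

    planted = _plant_interactors(config, rng, prey)
    planted_any = set().union(*planted.values()) if planted else set()

    substrates = _draw_substrates(config, rng, prey, planted_any)
    edges = _draw_edges(config, rng, proteins, planted)
    annotations = _draw_annotations(config, rng, proteins, planted)
    sequences = _draw_sequences(config, rng, proteins, substrates)

    itraq_folds, gained, lost = _plant_itraq_effects(config, planted)
    ranks = _draw_contaminants(config, rng, prey)

    truth = GroundTruth(
        planted=planted,
        substrates=substrates,
        itraq_folds=itraq_folds,
        gained=gained,
        lost=lost,
        contaminant_ranks=ranks,
    )
    universe = Universe(
        proteins=proteins,
        edges=edges,
        annotations=annotations,
        substrates=substrates,
        sequences=sequences,
    )
    return universe, truth


def _plant_interactors(
    config: SynthConfig, rng: np.random.Generator, prey: np.ndarray
) -> dict[str, set[str]]:
    """Shared pool common to all organs + disjoint organ-unique sets.

    With a shared pool of round(shared_fraction * planted_per_organ), every
    organ pair shares exactly that many proteins, realising the configured
    shared fraction exactly.
    """
    k = config.planted_per_organ
    n_shared = int(round(config.shared_fraction * k))
    n_needed = n_shared + (k - n_shared) * len(config.organs)
    if n_needed > len(prey):
        raise ConfigError("not enough proteins to plant the requested interactors")
    chosen = [str(p) for p in rng.choice(prey, size=n_needed, replace=False)]
    shared = set(chosen[:n_shared])
    planted: dict[str, set[str]] = {}
    off = n_shared
    for organ in config.organs:
        planted[organ] = shared | set(chosen[off : off + (k - n_shared)])
        off += k - n_shared
    return planted


def _draw_substrates(
    config: SynthConfig,
    rng: np.random.Generator,
    prey: np.ndarray,
    planted_any: set[str],
) -> set[str]:
    base = config.substrate_base_rate
    enriched = min(1.0, base * config.substrate_enrichment)
    probs = np.where(np.isin(prey, sorted(planted_any)), enriched, base)
    hits = rng.random(len(prey)) < probs
    return {str(p) for p in prey[hits]}


def _draw_edges(
    config: SynthConfig,
    rng: np.random.Generator,
    proteins: list[str],
    planted: dict[str, set[str]],
) -> pd.DataFrame:
    """Database-verified edges: a 'core' wiring among same-organ planted
    interactors plus a sparse Erdos-Renyi background over the catalog."""
    pairs: set[tuple[str, str]] = set()
    # core edges: each planted interactor links to another of the same organ,
    # and occasionally directly to the bait (as curated databases do)
    for organ in config.organs:
        members = sorted(planted[organ])
        if len(members) < 2:
            continue
        for i, p in enumerate(members):
            if rng.random() < config.core_edge_prob:
                j = int(rng.integers(0, len(members) - 1))
                q = members[j if j < i else j + 1]
                pairs.add((min(p, q), max(p, q)))
            if rng.random() < config.bait_edge_prob:
                pairs.add((min(p, config.bait_id), max(p, config.bait_id)))
    # background edges
    n = len(proteins)
    n_pairs = n * (n - 1) // 2
    m = rng.binomial(n_pairs, config.edge_density)
    if m > 0:
        idx = rng.choice(n_pairs, size=m, replace=False)
        # decode linear index -> (i, j) upper triangle
        i = (n - 2 - np.floor(np.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
        j = (idx + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2).astype(int)
        for a, b in zip(i, j):
            pa, pb = proteins[a], proteins[b]
            pairs.add((min(pa, pb), max(pa, pb)))
    rows = sorted(pairs)
    return pd.DataFrame(rows, columns=["protein_a", "protein_b"]).assign(
        source="database"
    )


def _draw_annotations(
    config: SynthConfig,
    rng: np.random.Generator,
    proteins: list[str],
    planted: dict[str, set[str]],
) -> dict[str, set[str]]:
    """GMT-style gene sets covering >=90% of the catalog.

    Planted interactors lean toward cell-cycle/transcription terms (and an
    organ-flavoured term per organ) so functional enrichment has signal;
    everything else is annotated uniformly.
    """
    n_generic = max(0, config.n_annotation_terms - len(VOCAB_TERMS))
    terms = VOCAB_TERMS + [f"PROCESS_{i:03d}" for i in range(1, n_generic + 1)]
    annotations: dict[str, set[str]] = {t: set() for t in terms}
    organ_term = {
        organ: VOCAB_TERMS[i % len(VOCAB_TERMS)]
        for i, organ in enumerate(config.organs)
    }
    planted_any: dict[str, list[str]] = {}
    for organ, members in planted.items():
        for p in members:
            planted_any.setdefault(p, []).append(organ)
    for p in proteins:
        if rng.random() < 0.05 and p not in planted_any:
            continue  # ~5% of the catalog stays unannotated
        if p in planted_any:
            if rng.random() < 0.45:
                annotations["CELL_CYCLE"].add(p)
            if rng.random() < 0.25:
                annotations["TRANSCRIPTION"].add(p)
            for organ in planted_any[p]:
                if rng.random() < 0.4:
                    annotations[organ_term[organ]].add(p)
        n_terms = 1 + int(rng.poisson(1.0))
        for t in rng.choice(len(terms), size=min(n_terms, len(terms)), replace=False):
            annotations[terms[int(t)]].add(p)
    return {t: members for t, members in annotations.items() if members}


def _draw_sequences(
    config: SynthConfig,
    rng: np.random.Generator,
    proteins: list[str],
    substrates: set[str],
) -> dict[str, str]:
    lo, hi = config.seq_length_range
    sequences = {}
    for p in proteins:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(AMINO_ACIDS, size=length)
        if p in substrates:
            # embed one S-P-x-K consensus phosphosite; context positions are
            # favourable only ~60% of the time so substrate scores spread
            # instead of piling up at 0
            insert = list(MOTIF_INSERT)
            for idx in _MOTIF_CONTEXT_IDX:
                if rng.random() >= 0.6:
                    insert[idx] = str(rng.choice(AMINO_ACIDS))
            pos = int(rng.integers(1, length - len(insert)))
            seq[pos : pos + len(insert)] = insert
        sequences[p] = "".join(seq)
    return sequences


def _draw_contaminants(
    config: SynthConfig, rng: np.random.Generator, prey: np.ndarray
) -> dict[str, int]:
    """One fixed 'sticky protein' ranking per universe, so the same
    contaminants recur across runs and genotypes."""
    n = min(config.n_contaminants, len(prey))
    chosen = rng.choice(prey, size=n, replace=False)
    return {str(p): r for r, p in enumerate(chosen, start=1)}


def _plant_itraq_effects(
    config: SynthConfig, planted: dict[str, set[str]]
) -> tuple[dict[str, float], set[str], set[str]]:
    if config.itraq_effects is not None:
        folds = dict(config.itraq_effects)
    else:
        organ = _itraq_organ(config)
        members = sorted(planted.get(organ, set()))
        folds = {}
        for p in members[:3]:
            folds[p] = 4.0
        for p in members[3:4]:
            folds[p] = 0.1
    bait_fold = folds.get(config.bait_id, 1.0)
    gained = {p for p, f in folds.items() if f / bait_fold >= 2.0 and p != config.bait_id}
    lost = {p for p, f in folds.items() if f / bait_fold <= 0.5 and p != config.bait_id}
    return folds, gained, lost


def _itraq_organ(config: SynthConfig) -> str:
    return "spleen" if "spleen" in config.organs else config.organs[0]


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------

def simulate_runs(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-run spectral counts for every organ and genotype.

    Returns a long table (run_id, tissue, genotype, protein,
    peptide_count). The bait appears in every KI run with count >= 1 and in
    no WT run; planted interactors get negative-binomial counts in KI runs
    (dropped with probability ``detection_floor``); sticky contaminants are
    detected in both genotypes with probability following the configured
    power law of their rank.
    """
    if set(truth.planted) != set(config.organs):
        raise ConfigError(
            f"ground-truth organs {sorted(truth.planted)} do not match "
            f"configured organs {sorted(config.organs)}"
        )
    rng = _rng(config, _STREAM_RUNS)
    contaminants = sorted(truth.contaminant_ranks)
    det_prob = {
        p: min(
            config.contaminant_max_prob,
            config.contaminant_max_prob
            * truth.contaminant_ranks[p] ** -config.contaminant_law_exponent,
        )
        for p in contaminants
    }
    rows: list[tuple[str, str, str, str, int]] = []
    for organ in config.organs:
        n_ki = config.n_ki_runs or int(rng.integers(6, 11))
        n_wt = config.n_wt_runs or int(rng.integers(6, 12))
        planted = sorted(truth.planted[organ])
        for k in range(1, n_ki + 1):
            run_id = f"{organ}_KI_{k:02d}"
            counts: dict[str, int] = {}
            bait = _draw_counts(
                rng,
                config.bait_count_mean,
                config.interactor_count_dispersion,
                1,
                config.count_model,
            )[0]
            counts[config.bait_id] = max(1, int(bait))
            c = _draw_counts(
                rng,
                config.interactor_count_mean,
                config.interactor_count_dispersion,
                len(planted),
                config.count_model,
            )
            dropped = rng.random(len(planted)) < config.detection_floor
            for p, ci, drop in zip(planted, c, dropped):
                if not drop and ci > 0:
                    counts[p] = counts.get(p, 0) + int(ci)
            _add_contaminants(rng, config, contaminants, det_prob, counts)
            rows.extend((run_id, organ, "KI", p, n) for p, n in sorted(counts.items()))
        for k in range(1, n_wt + 1):
            run_id = f"{organ}_WT_{k:02d}"
            counts = {}
            _add_contaminants(rng, config, contaminants, det_prob, counts)
            counts.pop(config.bait_id, None)  # never in mock runs
            rows.extend((run_id, organ, "WT", p, n) for p, n in sorted(counts.items()))
    return pd.DataFrame(
        rows, columns=["run_id", "tissue", "genotype", "protein", "peptide_count"]
    )


def _add_contaminants(rng, config, contaminants, det_prob, counts) -> None:
    detected = rng.random(len(contaminants)) < np.array(
        [det_prob[p] for p in contaminants]
    )
    extra = 1 + rng.poisson(max(config.contaminant_count_mean - 1.0, 0.0), len(contaminants))
    for p, hit, n in zip(contaminants, detected, extra):
        if hit:
            counts[p] = counts.get(p, 0) + int(n)


# ---------------------------------------------------------------------------
# iTRAQ
# ---------------------------------------------------------------------------

def simulate_itraq(
    config: SynthConfig,
    truth: GroundTruth,
    n_peptides_mean: float = 4.0,
) -> pd.DataFrame:
    """Peptide-level 4-channel reporter intensities for the two-genotype
    comparison (KI pulldown, WT mock, KO pulldown, KO mock).

    Per-peptide log2 ratios are centered on the configured true fold
    changes with normal (i.e. lognormal on the linear scale) noise of sd
    ``itraq_noise_sd``.
    """
    rng = _rng(config, _STREAM_ITRAQ)
    organ = _itraq_organ(config)
    quantified = sorted(
        {config.bait_id}
        | truth.planted[organ]
        | {p for p, r in truth.contaminant_ranks.items() if r <= 30}
    )
    interactors = truth.planted[organ] | {config.bait_id}
    sd = config.itraq_noise_sd
    rows = []
    for p in quantified:
        n_pep = 1 + int(rng.poisson(n_peptides_mean))
        if n_pep <= 0:
            raise ConfigError(f"protein {p} requested with zero peptides")
        fold = truth.itraq_folds.get(p, 1.0)
        ki_wt = config.itraq_ki_wt_fold if p in interactors else 1.0
        for j in range(1, n_pep + 1):
            base = float(rng.lognormal(mean=np.log(1e5), sigma=1.0))
            ki = base * 2.0 ** (rng.normal(0.0, sd) if sd > 0 else 0.0)
            ko = ki * fold * 2.0 ** (rng.normal(0.0, sd) if sd > 0 else 0.0)
            wt_mock = base / ki_wt * 2.0 ** (rng.normal(0.0, sd) if sd > 0 else 0.0)
            ko_mock = base / ki_wt * 2.0 ** (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append((p, f"{p}_pep{j:02d}", ki, wt_mock, ko, ko_mock))
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "peptide_id",
            "intensity_ki",
            "intensity_wt_mock",
            "intensity_ko",
            "intensity_ko_mock",
        ],
    )


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

def write_inputs(
    outdir: str | Path,
    config: SynthConfig,
    universe: Universe,
    truth: GroundTruth,
    runs: pd.DataFrame,
    itraq: pd.DataFrame,
) -> dict[str, Path]:
    """Write the full input bundle (runs.tsv, edges.tsv, annotations.gmt,
    substrates.txt, sequences.fasta, itraq.tsv, truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fn for name, fn in [
        ("runs", "runs.tsv"), ("edges", "edges.tsv"),
        ("annotations", "annotations.gmt"), ("substrates", "substrates.txt"),
        ("sequences", "sequences.fasta"), ("itraq", "itraq.tsv"),
        ("truth", "truth.json"),
    ]}
    pio.write_tsv(runs, paths["runs"])
    pio.write_tsv(universe.edges, paths["edges"])
    pio.write_gmt(universe.annotations, paths["annotations"])
    with open(paths["substrates"], "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(f"{p}\n" for p in sorted(universe.substrates))
    pio.write_fasta(universe.sequences, paths["sequences"])
    itraq_out = itraq.copy()
    for col in itraq_out.columns[2:]:
        itraq_out[col] = itraq_out[col].map(lambda v: f"{v:.6g}")
    pio.write_tsv(itraq_out, paths["itraq"])
    pio.write_json(truth.to_dict(), paths["truth"])
    return paths


def simulate_all(config: SynthConfig, outdir: str | Path | None = None):
    """Generate universe + runs + iTRAQ; optionally write the file bundle.

    Returns (universe, truth, runs, itraq).
    """
    universe, truth = generate_universe(config)
    runs = simulate_runs(config, truth)
    itraq = simulate_itraq(config, truth)
    if outdir is not None:
        write_inputs(outdir, config, universe, truth, runs, itraq)
    return universe, truth, runs, itraq
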