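"""End-to-end orchestration: simulate -> score -> network/overlap ->
enrichment -> motif -> iTRAQ -> report.

Every stage is a plain function over DataFrames/dicts that also writes
its tabular outputs, so the CLI and library users can run stages
individually. ``run_pipeline`` chains them and emits a ``report.json``
summary plus a ``manifest.json`` recording the seed and input checksums;
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import io as pio
from . import itraq as itq
from . import motif as mot
from . import network as net
from . import scoring, synth
from .config import PipelineConfig

log = logging.getLogger("pulldown.pipeline")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema-check the input bundle (runs, edges, annotations, substrates,
    sequences, itraq). Distinguishes fatal errors from warnings."""
    rep = ValidationReport()
    for name, p in paths.items():
        if not Path(p).exists():
            rep.fatal.append(f"{name}: file not found: {p}")
    if rep.fatal:
        return rep

    if "runs" in paths:
        try:
            runs = pio.read_tsv(paths["runs"])
            need = {"run_id", "tissue", "genotype", "protein", "peptide_count"}
            if missing := need - set(runs.columns):
                rep.fatal.append(f"runs: missing columns {sorted(missing)}")
            else:
                if (runs["peptide_count"] < 0).any():
                    rep.fatal.append("runs: negative peptide counts")
                bad = set(runs["genotype"]) - {"KI", "WT"}
                if bad:
                    rep.fatal.append(f"runs: unknown genotype labels {sorted(bad)}")
                dup = runs.duplicated(["run_id", "protein"]).sum()
                if dup:
                    rep.warnings.append(
                        f"runs: {dup} duplicate protein rows within a run; counts are summed"
                    )
        except Exception as e:  # noqa: BLE001 - report, don't crash
            rep.fatal.append(f"runs: {e}")
    if "edges" in paths:
        try:
            edges = pio.read_tsv(paths["edges"])
            if missing := {"protein_a", "protein_b"} - set(edges.columns):
                rep.fatal.append(f"edges: missing columns {sorted(missing)}")
            elif (edges["protein_a"] == edges["protein_b"]).any():
                rep.warnings.append("edges: self-loops present; they are ignored")
        except Exception as e:  # noqa: BLE001
            rep.fatal.append(f"edges: {e}")
    if "annotations" in paths:
        try:
            pio.read_gmt(paths["annotations"])
        except Exception as e:  # noqa: BLE001
            rep.fatal.append(f"annotations: {e}")
    if "sequences" in paths:
        try:
            seqs = pio.read_fasta(paths["sequences"])
            bad_seqs = [p for p, s in seqs.items() if set(s) - mot.AA_ALPHABET]
            if bad_seqs:
                rep.fatal.append(
                    f"sequences: non-amino-acid characters in {bad_seqs[:5]}"
                )
        except Exception as e:  # noqa: BLE001
            rep.fatal.append(f"sequences: {e}")
    if "itraq" in paths:
        try:
            it = pio.read_tsv(paths["itraq"])
            if missing := set(["protein", "peptide_id", *itq.CHANNELS]) - set(it.columns):
                rep.fatal.append(f"itraq: missing columns {sorted(missing)}")
        except Exception as e:  # noqa: BLE001
            rep.fatal.append(f"itraq: {e}")
    return rep


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_score(runs, edges, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    log.info("scoring %d count rows", len(runs))
    runs = runs.groupby(
        ["run_id", "tissue", "genotype", "protein"], as_index=False
    )["peptide_count"].sum()  # duplicate rows within a run are summed
    evidence = scoring.score_runs(runs, config.thresholds)
    evidence = scoring.assign_categories(
        evidence, edges, config.thresholds, config.synth.bait_id
    )
    pio.write_tsv(evidence, outdir / "evidence.tsv")
    for tissue, g in evidence.groupby("tissue"):
        keep = g[g["category"] != "REJECTED"]
        pio.write_tsv(keep, outdir / f"interactome_{tissue}.tsv")
    pio.write_tsv(
        scoring.combined_interactome(evidence), outdir / "combined_interactome.tsv"
    )
    return evidence


def stage_network(evidence, edges, config: PipelineConfig, outdir: Path):
    interactomes = scoring.interactomes_by_tissue(evidence)
    bait = config.synth.bait_id
    combined = net.build_graph(interactomes, edges, bait)
    net.write_graphml(combined, outdir / "network_combined.graphml")
    net.write_sif(combined, outdir / "network_combined.sif")
    for organ in sorted(interactomes):
        g = net.build_graph(interactomes, edges, bait, scope=organ)
        net.write_sif(g, outdir / f"network_{organ}.sif")
    summary = net.overlap_stats(interactomes)
    pio.write_tsv(summary.to_frame(), outdir / "overlap_summary.tsv")
    log.info(
        "combined interactome: %d proteins (%d multi-organ)",
        summary.combined_size,
        summary.multi_organ_count,
    )
    return combined, summary


def stage_enrich(evidence, universe: synth.Universe, config: PipelineConfig, outdir: Path):
    interactomes = scoring.interactomes_by_tissue(
        evidence, core_only=not config.enrichment.include_rescued
    )
    background = set(universe.proteins)
    funcs = enr.primary_function_table(
        interactomes,
        universe.annotations,
        frequent_fraction=config.enrichment.frequent_label_fraction,
    )
    pio.write_tsv(funcs, outdir / "primary_functions.tsv")
    cells, display = enr.enrichment_heatmap(
        interactomes,
        universe.annotations,
        background,
        ease_threshold=config.enrichment.ease_threshold,
        fold_clamp=config.enrichment.fold_clamp,
    )
    pio.write_tsv(cells, outdir / "enrichment_heatmap.tsv")
    combined = set().union(*interactomes.values()) if interactomes else set()
    overlay = enr.substrate_overlay(
        combined, universe.substrates, background_size=len(background)
    )
    pio.write_tsv(pd.DataFrame([overlay]), outdir / "substrate_overlay.tsv")
    log.info(
        "substrate overlay: %d/%d hits, p = %.3g", overlay["hits"],
        overlay["list_size"], overlay["p"],
    )
    return funcs, cells, display, overlay


def stage_motif(evidence, universe: synth.Universe, config: PipelineConfig, outdir: Path):
    model = mot.default_model()
    scores = mot.score_proteome(universe.sequences, model)
    classes, calib = mot.calibrate_and_classify(
        scores, config.motif.high_percentile, config.motif.medium_percentile
    )
    pio.write_tsv(
        pd.DataFrame(
            {"protein": scores.index, "score": scores.values, "stringency": classes.values}
        ),
        outdir / "protein_classes.tsv",
    )
    interactomes = scoring.interactomes_by_tissue(evidence)
    table = mot.substrate_prediction_enrichment(interactomes, classes)
    pio.write_tsv(table, outdir / "substrate_enrichment.tsv")
    # per-site scores for the called interactome only (the full proteome
    # table is large and reproducible from sequences.fasta)
    combined = set().union(*interactomes.values()) if interactomes else set()
    site_rows = [
        {"protein": p, "position": pos, "residue": res, "score": s}
        for p in sorted(combined)
        for pos, res, s in mot.score_sites(universe.sequences[p], model)
    ]
    pio.write_tsv(
        pd.DataFrame(site_rows, columns=["protein", "position", "residue", "score"]),
        outdir / "site_scores.tsv",
    )
    return scores, classes, calib, table


def stage_itraq(itraq_df, config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    report = itq.analyze_itraq(itraq_df, config.synth.bait_id, config.itraq)
    pio.write_tsv(report, outdir / "itraq_report.tsv")
    gained = sorted(report.loc[report["call"] == "gained", "protein"])
    lost = sorted(report.loc[report["call"] == "lost", "protein"])
    log.info("iTRAQ re-wiring: %d gained, %d lost", len(gained), len(lost))
    return report


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on a freshly simulated input bundle.

    Returns the summary report (also written to ``report.json``).
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs_dir = outdir / "inputs"

    log.info("simulating inputs (seed=%d)", config.synth.seed)
    universe, truth, runs, itraq_df = synth.simulate_all(config.synth, inputs_dir)
    input_paths = {
        name: inputs_dir / f"{name}.{ext}"
        for name, ext in [
            ("runs", "tsv"), ("edges", "tsv"), ("substrates", "txt"),
            ("sequences", "fasta"), ("itraq", "tsv"), ("truth", "json"),
        ]
    }
    input_paths["annotations"] = inputs_dir / "annotations.gmt"
    report_v = validate_inputs(input_paths)
    if not report_v.ok:
        raise RuntimeError(f"input validation failed: {report_v.fatal}")

    evidence = stage_score(runs, universe.edges, config, outdir)
    _, overlap = stage_network(evidence, universe.edges, config, outdir)
    _, cells, _, overlay = stage_enrich(evidence, universe, config, outdir)
    _, classes, calib, motif_table = stage_motif(evidence, universe, config, outdir)
    itraq_report = stage_itraq(itraq_df, config, outdir)

    interactomes = scoring.interactomes_by_tissue(evidence)
    category_counts = (
        evidence.groupby(["tissue", "category"]).size().unstack(fill_value=0)
    )
    report = {
        "seed": config.synth.seed,
        "organs": list(config.synth.organs),
        "interactome_sizes": {t: len(s) for t, s in sorted(interactomes.items())},
        "category_counts": {
            t: {c: int(n) for c, n in row.items()} for t, row in category_counts.iterrows()
        },
        "combined_size": overlap.combined_size,
        "multi_organ_count": overlap.multi_organ_count,
        "unique_counts": overlap.unique_counts,
        "enrichment_rows_retained": int(
            cells[cells["retained"]]["term"].nunique() if len(cells) else 0
        ),
        "substrate_overlay": {
            k: overlay[k] for k in ("hits", "list_size", "list_percent", "fold", "p")
        },
        "motif_calibration": dataclasses.asdict(calib),
        "motif_enrichment": motif_table.to_dict(orient="records"),
        "itraq_calls": {
            call: sorted(g["protein"])
            for call, g in itraq_report.groupby("call")
            if call in ("gained", "lost")
        },
        "validation_warnings": report_v.warnings,
    }
    pio.write_json(report, outdir / "report.json")

    manifest = {
        "seed": config.synth.seed,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(path) for name, path in sorted(input_paths.items())
        },
    }
    pio.write_json(manifest, outdir / "manifest.json")
    log.info("pipeline complete: %s", outdir)
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
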