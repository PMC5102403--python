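import warnings

import pandas as pd
import pytest

from pulldown.config import PipelineConfig, ScoringThresholds, SynthConfig
from pulldown.scoring import assign_categories, score_runs
from pulldown.synth import simulate_all

warnings.filterwarnings("ignore", message=".*edge endpoint.*")


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """Default synthetic study: (universe, truth, runs, itraq)."""
    return simulate_all(default_config)


@pytest.fixture(scope="session")
def scored_evidence(study, default_config):
    universe, truth, runs, _ = study
    evidence = score_runs(runs, ScoringThresholds())
    return assign_categories(
        evidence, universe.edges, ScoringThresholds(), default_config.bait_id
    )


def make_runs(spec: dict[tuple[str, str], dict[str, list[int]]]) -> pd.DataFrame:
    """Build a long run table from {(tissue, genotype): {protein: per-run counts}}.

    All proteins under one (tissue, genotype) must list the same number of
    runs; zeros are omitted from the table (not detected).
    """
    rows = []
    for (tissue, genotype), proteins in spec.items():
        n_runs = {len(v) for v in proteins.values()}
        assert len(n_runs) == 1, "all proteins must cover the same runs"
        for protein, counts in proteins.items():
            for i, c in enumerate(counts, 1):
                run_id = f"{tissue}_{genotype}_{i:02d}"
                if c > 0:
                    rows.append((run_id, tissue, genotype, protein, c))
                else:
                    # keep the run itself on record via a filler protein
                    rows.append((run_id, tissue, genotype, "_filler", 1))
    df = pd.DataFrame(
        rows, columns=["run_id", "tissue", "genotype", "protein", "peptide_count"]
    )
    return df.groupby(
        ["run_id", "tissue", "genotype", "protein"], as_index=False
    )["peptide_count"].sum()
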