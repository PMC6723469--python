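"""Shared configuration for the analysis drivers.

The shipped analysis runs the full workflow on the default study conditions:
seven FBP gene families simulated along the 21-taxon eudicot tree with the
default dual-source corruption channel (10% missed genes, 30% UTR extensions
half of which shift the coding start, 10% truncations, redundant transcript
variants, 5% identical duplicates).
"""

from __future__ import annotations

import argparse
from pathlib import Path

from annoconcord.pipeline import PipelineConfig
from annoconcord.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def pipeline_config(seed: int) -> PipelineConfig:
    return PipelineConfig(
        outdir=RESULTS,
        seed=seed,
        simulation=SimulationConfig(seed=seed),
        tree_bootstraps=0,  # supports are recomputed on demand; rescue ignores them
    )


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed
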