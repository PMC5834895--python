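"""Shared fixtures: toy transcripts with designed ORFs and a session-scoped
full-scale synthetic pipeline run used by the acceptance tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lofprev.orf import OrfAnnotation, TranscriptSeq
from lofprev.pipeline import RunConfig, run_pipeline
from lofprev.simulate import SimulationConfig, build_species_panel, designed_transcript

SESSION_SEED = 1


def make_coding_transcript(
    rng: np.random.Generator,
    n_codons: int = 60,
    strand: str = "+",
    transcript_id: str = "t1",
) -> tuple[TranscriptSeq, OrfAnnotation]:
    """A transcript with one designed ORF of ``n_codons`` codons (incl. stop)."""
    return designed_transcript(rng, n_codons, strand, transcript_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default-scale synthetic run (35 species x 5000 genes x 2 individuals).

    Returns (output directory, the generating panel rebuilt at the same
    seed).  Session-scoped: the heavy pipeline executes once.
    """
    out = tmp_path_factory.mktemp("fullrun")
    sim = SimulationConfig()
    cfg = RunConfig(out_dir=out, sim=sim, seed=SESSION_SEED)
    run_pipeline(cfg)
    panel = build_species_panel(dataclasses.replace(sim, seed=SESSION_SEED))
    return out, panel
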