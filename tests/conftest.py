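"""Shared fixtures: one trained bundle and one full pipeline run per session.

The heavy artifacts (a per-motif classifier bundle trained at the default
simulator conditions, and an end-to-end transcriptome analysis) are built
once and reused by the acceptance-style tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from nanostoich import model, polya_apa, quantify, simulate

SEED = 7


@pytest.fixture(scope="session")
def sim_params() -> simulate.SimParams:
    """Default study conditions (moderate effect size, realistic noise)."""
    return simulate.SimParams(seed=SEED)


@pytest.fixture(scope="session")
def trained_bundle(sim_params):
    """Bundle trained on labeled events at the default conditions."""
    labeled = simulate.simulate_labeled_events(sim_params, 300)
    bundle, report = model.train_bundle(labeled.vectors(), model.TrainConfig(seed=SEED))
    return bundle, report


@dataclass
class PipelineRun:
    sim: simulate.TranscriptomeSim
    calls: list
    sites: pd.DataFrame
    clusters: list
    screen: pd.DataFrame
    fold_changes: pd.DataFrame


@pytest.fixture(scope="session")
def apa_run(sim_params, trained_bundle) -> PipelineRun:
    """Full pipeline on the synthetic transcriptome (100 genes, depth 100)."""
    bundle, _ = trained_bundle
    sim = simulate.simulate_transcriptome(sim_params)
    vectors = sim.site_vectors()
    calls = quantify.calls_from_vectors(bundle, vectors)
    sites = quantify.aggregate_sites(calls, min_mod_reads=20)

    clusters = polya_apa.cluster_polya_sites(sim.polya)
    stops = dict(zip(sim.genes.gene_id, zip(sim.genes.strand, sim.genes.stop_codon_genomic)))
    by_gene: dict[str, list] = {}
    for c in clusters:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gid, cl in by_gene.items():
        strand, stop = stops[gid]
        polya_apa.assign_proximal_distal(cl, strand, int(stop))
    screen = polya_apa.apa_polya_length_screen(clusters)

    passing = {
        (r.transcript_id, int(r.tpos))
        for r in sites[sites.pass_filter].itertuples(index=False)
    }
    polya_apa.attach_cluster_m6a(clusters, calls, passing)
    fold_changes = polya_apa.apa_fold_change_table(clusters)
    return PipelineRun(sim, calls, sites, clusters, screen, fold_changes)
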