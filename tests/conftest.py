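"""Shared fixtures: a mid-sized synthetic community run once per session.

The `community8` fixture is the canonical validation scenario: 8 genomes of
100 kb, two multi-gene islands planted across distant genomes (one verbatim,
one at 0.5% per-site divergence), one vertically related genome pair at 5%
divergence, and one transposon element copied next to both islands and
scattered elsewhere — the confounder that chains the two island groups into
one.  The full pipeline (ANI, search, detection) runs on it once; tests
share the results read-only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hgtscan.ani import ANIMatrix, build_ani_matrix
from hgtscan.detection import (
    DetectionParams,
    assemble_islands,
    cluster_groups,
    filter_hgt_hits,
    promiscuous_genes,
    rank_and_stats,
)
from hgtscan.homology import HomologyParams, search_all_vs_all
from hgtscan.synthetic import IslandSpec, SyntheticConfig, generate_community

COMMUNITY_SEED = 20257


def community_config(seed: int = COMMUNITY_SEED) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        n_genomes=8,
        relative_pairs=(("G1", "G2", 0.05),),
        planted_islands=(
            IslandSpec("islA", "G3", ("G4", "G5"), n_genes=5, per_site_divergence=0.0),
            IslandSpec("islB", "G6", ("G7",), n_genes=4, per_site_divergence=0.005),
        ),
        confounder_transposons=1,
    )


@dataclass
class CommunityRun:
    config: SyntheticConfig
    genomes: list
    truth: object
    meta: dict
    ani: ANIMatrix
    hits: list
    params: DetectionParams
    edges: list
    candidates: dict
    islands: list
    groups: list
    flagged: set


@pytest.fixture(scope="session")
def community8() -> CommunityRun:
    config = community_config()
    genomes, truth, meta = generate_community(config)
    ani = build_ani_matrix(genomes)
    hits = search_all_vs_all(genomes, HomologyParams())
    # promiscuity threshold scaled to community size (8 genomes: a gene seen
    # in more than 3 partner genomes is suspect); spec default of 10 targets
    # collections of >100 genomes
    params = DetectionParams(promiscuous_min_genomes=3)
    edges, candidates = filter_hgt_hits(hits, ani, meta, params)
    islands = assemble_islands(candidates, genomes, params)
    groups = rank_and_stats(cluster_groups(islands, edges), meta, genomes, params)
    flagged = promiscuous_genes(edges, params)
    return CommunityRun(
        config, genomes, truth, meta, ani, hits, params,
        edges, candidates, islands, groups, flagged,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1729)
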