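import itertools

import pytest

from coreflex import simulate as sim
from coreflex.pangenome import (
    ScorerConfig,
    build_panortholog_set,
    classify_core_flexible,
    reciprocal_best_hits,
    score_all_pairs,
)


@pytest.fixture(scope="session")
def sim_pangenome():
    """Default desk-scale synthetic pangenome (5 genomes, 20 core / 10 flexible)."""
    return sim.simulate_pangenome(sim.PangenomeSimConfig(seed=7))


@pytest.fixture(scope="session")
def pangenome_call(sim_pangenome):
    """Full orthology call on the synthetic pangenome: (hits, rbh, groups, partition)."""
    ann = sim_pangenome.annotations
    gids = sorted(ann)
    scorer = ScorerConfig()
    hits = {
        (a, b): score_all_pairs(ann[a].proteins(), ann[b].proteins(), scorer)
        for a, b in itertools.permutations(gids, 2)
    }
    rbh = {
        (a, b): reciprocal_best_hits(hits[(a, b)], hits[(b, a)])
        for a, b in itertools.combinations(gids, 2)
    }
    groups = build_panortholog_set(gids, rbh, hits)
    partition = classify_core_flexible(ann[sim_pangenome.reference_genome_id], groups)
    return hits, rbh, groups, partition
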