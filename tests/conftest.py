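import pytest

from cyanomine import synthetic_data as sd
from cyanomine.report import PipelineConfig, mine_genomes


@pytest.fixture(scope="session")
def seven_group_run():
    """One planted cluster per group at mutation 0, fully mined."""
    plan = sd.seven_group_plan(seed=11)
    genomes, truth = sd.generate(plan)
    hits, architectures, clusters = mine_genomes(genomes, PipelineConfig())
    return {
        "plan": plan, "genomes": genomes, "truth": truth,
        "hits": hits, "architectures": architectures, "clusters": clusters,
    }


@pytest.fixture(scope="session")
def dense_precursor_run():
    """A single group-II cluster surrounded by sixteen planted precursors
    (mixed families/strands/annotation) and eight motif-free decoys."""
    fams = ["NHLP", "N11P", "HETP", "DUF37"]
    plan = sd.SyntheticPlan(
        seed=7,
        clusters=[sd.PlannedCluster(group="II")],
        precursors=[
            sd.PlannedPrecursor(
                family=fams[i % 4], cluster=0,
                strand=+1 if i % 2 == 0 else -1, annotated=i % 3 == 0,
            )
            for i in range(16)
        ],
        decoys=8,
    )
    genomes, truth = sd.generate(plan)
    hits, architectures, clusters = mine_genomes(genomes, PipelineConfig())
    from cyanomine.precursor_miner import mine_precursors

    precursors = mine_precursors(genomes[0], clusters)
    return {
        "plan": plan, "genomes": genomes, "truth": truth,
        "clusters": clusters, "precursors": precursors,
    }
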