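import pandas as pd
import pytest

from pseudosponge import preprocessing, simulate
from pseudosponge.matrices import tumor_samples


@pytest.fixture(scope="session")
def config():
    return simulate.SimulationConfig()


@pytest.fixture(scope="session")
def dataset(config):
    """One fully generated default cohort, shared across the suite."""
    genes = simulate.generate_annotations(config)
    interactions, disease, truth = simulate.generate_interactions(genes, config)
    counts, labels = simulate.generate_expression(genes, truth, config)
    meth = simulate.generate_methylation(genes, truth, config)
    clinical = simulate.generate_survival(counts, truth, config)
    return {
        "config": config,
        "genes": genes,
        "interactions": interactions,
        "disease": disease,
        "truth": truth,
        "counts": counts,
        "labels": labels,
        "methylation": meth,
        "clinical": clinical,
    }


@pytest.fixture(scope="session")
def processed(dataset):
    kept, rpkm, logged = preprocessing.preprocess(dataset["counts"], dataset["genes"])
    return {"kept": kept, "rpkm": rpkm, "log": logged}


@pytest.fixture(scope="session")
def tumor_ids(dataset, processed):
    return [s for s in tumor_samples(dataset["labels"]) if s in processed["log"].values.columns]


def run_discovery(seed: int, n_seeds_config=None):
    """Full generate -> preprocess -> discover chain for one seed."""
    from pseudosponge import cerna

    cfg = simulate.SimulationConfig(seed=seed)
    genes = simulate.generate_annotations(cfg)
    interactions, disease, truth = simulate.generate_interactions(genes, cfg)
    counts, labels = simulate.generate_expression(genes, truth, cfg)
    _, _, logged = preprocessing.preprocess(counts, genes)
    samples = [s for s in tumor_samples(labels) if s in logged.values.columns]
    candidates, _ = cerna.identify_candidates(interactions, disease, logged, samples=samples)
    reported = set(
        zip(
            candidates.loc[candidates["passed"], "pseudogene_id"],
            candidates.loc[candidates["passed"], "mrna_id"],
        )
    )
    planted = set(truth.true_pairs)
    recall = len(planted & reported) / len(planted)
    false_fraction = len(reported - planted) / max(len(reported), 1)
    return recall, false_fraction, candidates
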