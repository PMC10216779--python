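import pytest
from hypothesis import HealthCheck, settings

import motif2mol as m2m
from motif2mol.curation import MotifCompoundPair
from motif2mol.model import TINY_PRESET, build_vocabs
from motif2mol.sampling import sample_fixed_runs, sample_until_unique
from motif2mol.synthetic import generate_heldout_target, known_actives

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ps00107():
    return m2m.parse_prosite(m2m.PS00107, accession_label="PS00107")


@pytest.fixture(scope="session")
def kinome():
    """The reference synthetic kinome: 20 targets, nominal 25 actives each."""
    return m2m.generate_kinome(m2m.SynthSpec(seed=11))


@pytest.fixture(scope="session")
def kinome_motifs(kinome, ps00107):
    return {
        t.target_id: m2m.scan_and_extend(
            t.sequence, ps00107, target_id=t.target_id
        ).motif_text
        for t in kinome.targets
    }


@pytest.fixture(scope="session")
def one_pair(kinome, kinome_motifs):
    t = kinome.targets[0]
    return MotifCompoundPair(t.target_id, kinome_motifs[t.target_id], t.actives[0])


@pytest.fixture(scope="session")
def overfit_model(one_pair):
    """Tiny-preset model memorizing a single motif/SMILES pair.

    Dropout is off: the memorization oracle wants a deterministic fit, and
    dropout exists precisely to impede memorization."""
    import dataclasses

    cfg = dataclasses.replace(TINY_PRESET, dropout=0.0)
    sv, tv = build_vocabs([one_pair])
    model = m2m.init_model(cfg, sv, tv, seed=0)
    tc = m2m.TrainConfig(epochs=400, batch_size=1, learning_rate=2e-3, seed=0)
    return m2m.train(model, [one_pair], [one_pair], tc)


@pytest.fixture(scope="session")
def trained_pipeline(kinome, kinome_motifs):
    """End-to-end desk-scale experiment shared by the evaluation tests:
    curate the synthetic kinome, train the tiny preset for 30 epochs,
    sample 20 unique candidates per target, and evaluate per target."""
    split = m2m.curate(kinome.records, kinome_motifs, seed=11)
    sv, tv = build_vocabs(list(split.train) + list(split.validation))
    model = m2m.init_model(TINY_PRESET, sv, tv, seed=11)
    tc = m2m.TrainConfig(epochs=30, batch_size=8, learning_rate=2e-3, seed=11)
    m2m.train(model, list(split.train), list(split.validation), tc)
    results = [
        sample_until_unique(
            model,
            kinome_motifs[t.target_id],
            n_unique=20,
            seed=100 + i,
            target_id=t.target_id,
        )
        for i, t in enumerate(kinome.targets)
    ]
    report = m2m.per_target_report(results, known_actives(kinome))
    return {
        "kinome": kinome,
        "split": split,
        "model": model,
        "results": results,
        "report": report,
    }


@pytest.fixture(scope="session")
def heldout_runs(trained_pipeline, ps00107):
    """High-identity held-out target sampled for 1000 runs under 5 seeds."""
    kinome = trained_pipeline["kinome"]
    model = trained_pipeline["model"]
    target = generate_heldout_target(kinome, "high", seed=7)
    motif = m2m.scan_and_extend(target.sequence, ps00107, target_id=target.target_id)
    runs = [
        sample_fixed_runs(model, motif.motif_text, runs=1000, seed=1000 + s,
                          target_id=target.target_id)
        for s in range(5)
    ]
    return {"target": target, "runs": runs}
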