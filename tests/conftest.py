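from types import SimpleNamespace

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dataclasses import replace

from fusionsurvey.simgen import (
    FusionSpec,
    SimConfig,
    apply_fusion,
    fusion_study_weights,
    make_reference,
    models_on_tumor,
    simulate_exome,
    simulate_rnaseq,
    write_scenario,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11, n_pairs=2500)


@pytest.fixture(scope="session")
def fusion_scenario(sim_config):
    """One fully simulated somatic fusion study shared across tests."""
    genome, models = make_reference(sim_config)
    spec = FusionSpec("G001", "G007", 1, 1, homology=2, somatic=True)
    tumor, fused, truth = apply_fusion(genome, models, spec)
    tumor_models = models_on_tumor(models, truth, fused)
    rna_config = replace(
        sim_config,
        expression_weights=fusion_study_weights(models, fused.gene_id, spec),
    )
    rna, rna_truth = simulate_rnaseq(
        tumor, tumor_models, rna_config, {fused.gene_id: truth.junction_offset}
    )
    exome_tumor, exome_tumor_truth = simulate_exome(tumor, tumor_models, sim_config, "tumor")
    exome_normal, _ = simulate_exome(genome, models, sim_config, "normal")
    by_id = {m.gene_id: m for m in models}
    return SimpleNamespace(
        config=sim_config,
        genome=genome,
        models=models,
        by_id=by_id,
        spec=spec,
        tumor=tumor,
        fused=fused,
        truth=truth,
        tumor_models=tumor_models,
        rna=rna,
        rna_truth=rna_truth,
        exome_tumor=exome_tumor,
        exome_tumor_truth=exome_tumor_truth,
        exome_normal=exome_normal,
    )


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory):
    """The same study written to disk for pipeline-level tests."""
    outdir = tmp_path_factory.mktemp("scenario") / "sim"
    cfg = SimConfig(seed=11, n_pairs=2500)
    spec = FusionSpec("G001", "G007", 1, 1, homology=2, somatic=True)
    write_scenario(cfg, outdir, spec)
    return outdir


@pytest.fixture(scope="session")
def wildtype_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("wildtype") / "sim"
    cfg = SimConfig(seed=11, n_pairs=2500)
    write_scenario(cfg, outdir, fusion=None)
    return outdir
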