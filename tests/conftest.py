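import numpy as np
import pandas as pd
import pytest

import methpanel as mp


@pytest.fixture()
def tiny_matrix() -> mp.MethylationMatrix:
    values = pd.DataFrame(
        [[0.10, 0.90], [0.20, 0.80], [0.55, 0.45]],
        index=["cg01", "cg02", "cg03"],
        columns=["s1", "s2"],
    )
    return mp.MethylationMatrix(values, "beta")


@pytest.fixture()
def small_cohort():
    """A quick 60-sample cohort with two planted blocks."""
    cfg = mp.SimulationConfig(
        n_tumor=40,
        n_normal=20,
        n_probes=80,
        n_signal_blocks=2,
        block_size=3,
        effect_m=3.0,
        shared_noise_m=1.2,
        within_block_noise_m=0.2,
        precision=300.0,
        n_batches=2,
        batch_sd_m=0.3,
        seed=5,
    )
    return mp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_run():
    """Full discovery pipeline on the documented panel-recovery scenario."""
    cfg = mp.default_recovery_scenario()
    matrix, sheet, truth = mp.simulate_cohort(cfg)
    adjusted, _ = mp.batch_adjust(mp.beta_to_m(matrix), sheet)
    results = mp.DifferentialMethylation(adjusted, sheet).fit()
    dmps = results.call_dmps()
    binary = mp.binarize_matrix(adjusted, list(dmps["probe_id"]))
    labels = sheet.groups_for(binary.sample_ids)
    selection = mp.PanelSelector(binary, labels, mp.SelectionConfig(seed=17)).fit()
    return {
        "config": cfg,
        "sheet": sheet,
        "truth": truth,
        "adjusted": adjusted,
        "dmp_results": results,
        "dmps": dmps,
        "binary": binary,
        "labels": labels,
        "selection": selection,
        "panel": selection.panel,
    }


@pytest.fixture(scope="session")
def external_report(recovery_run):
    """External validation of the recovered panel on a fresh 458/34 cohort."""
    vmat, vsheet, _ = mp.simulate_cohort(mp.external_validation_scenario(seed=450))
    vadj, _ = mp.batch_adjust(mp.beta_to_m(vmat), vsheet)
    report = mp.validate_external(
        vadj, vsheet, recovery_run["panel"], mp.SelectionConfig(seed=17), seed=3
    )
    return report
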