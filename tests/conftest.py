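import numpy as np
import pandas as pd
import pytest

import germdelay as gd


def make_expression_set(values, times, replicates, layer="protein",
                        detected=None, gene_ids=None):
    """Small ExpressionSet builder: values shape (genes, times*reps),
    samples ordered time-major."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    assert m == len(times) * replicates
    meta = pd.DataFrame({
        "time_hai": np.repeat(times, replicates),
        "replicate": np.tile(np.arange(1, replicates + 1), len(times)),
    })
    if detected is None:
        detected = np.isfinite(values)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    return gd.ExpressionSet(gene_ids, layer, values, np.asarray(detected, bool), meta)


@pytest.fixture(scope="session")
def scenario_cfg():
    """The reference synthetic scenario: 2,000 genes, 300 delayed_up /
    100 delayed_down / 200 concordant / 1,400 null, effect 2.0, noise 0.3,
    lags uniform on {1,2,3}, 3 replicates."""
    return gd.SimConfig(seed=0)


def run_scenario_seed(seed):
    """One full classify-and-score pass of the reference scenario."""
    cfg = gd.SimConfig(seed=seed)
    total, poly, prot, truth = gd.generate_multiomics(cfg)
    detected = gd.protein_detection_filter(prot)
    poly_calls = gd.call_de(gd.ebayes_shrink(gd.fit_contrasts(poly)))
    prot_calls = gd.call_de(gd.ebayes_shrink(gd.fit_contrasts(prot)))
    records = gd.classify_delay(poly_calls, prot_calls, detected)
    scores = gd.score_against_truth(records, truth)
    return dict(cfg=cfg, total=total, poly=poly, prot=prot, truth=truth,
                detected=detected, records=records, scores=scores)


@pytest.fixture(scope="session")
def scenario_runs():
    """Ten seeded runs of the reference scenario (shared across tests)."""
    return [run_scenario_seed(s) for s in range(10)]


@pytest.fixture(scope="session")
def scenario_run(scenario_runs):
    return scenario_runs[0]
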