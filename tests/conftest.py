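import numpy as np
import pytest

import polyrisk as pr
from polyrisk.cohort import CohortConfig, default_risk_factors, simulate_cohort
from polyrisk.datasets import SURROGATE_PAIRS
from polyrisk.factors import build_factor_scores, full_model
from polyrisk.genetic import ld_exclude
from polyrisk.pipeline import build_genetic_scores


@pytest.fixture(scope="session")
def panels():
    """Bundled synthetic panels with the surrogate already excluded from the
    24-SNP panel: (retained 23-SNP panel, 68-SNP panel, LD table)."""
    p24, p68, ld = pr.load_default_panels()
    p24r, _ = ld_exclude(p24, ld, 0.3, SURROGATE_PAIRS)
    return p24r, p68, ld


@pytest.fixture(scope="session")
def study_cohort(panels):
    """One study-scale cohort (1,732 cases / 1,910 controls) with all scores."""
    p24r, p68, _ = panels
    cfg = CohortConfig(seed=20180214 % 2**31)
    cohort, info = simulate_cohort(cfg, p24r, p68)
    scores = build_genetic_scores(cohort, p24r, p68, cfg.seed)
    mrfs, nmrfs, weights = build_factor_scores(cohort, default_risk_factors())
    scores["MRFS"], scores["NMRFS"] = mrfs, nmrfs
    scores["FM"] = full_model(scores["GRS92"], mrfs, nmrfs)
    return {"cohort": cohort, "info": info, "scores": scores, "weights": weights, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
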