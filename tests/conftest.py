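"""Shared fixtures: the default synthetic study and its discovery products.

The expensive pieces (masked-CV rank selection, calibration) run once per
session and are reused by unit and acceptance tests alike.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from oneirolex import (dimensions as dims_mod, domain_discovery as dd,
                       domain_scoring as ds, synthetic_data as sd)
from oneirolex.corpus import time_rank


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic study, seed 7."""
    return sd.default_scenario(seed=7)


@pytest.fixture(scope="session")
def discovery(scenario):
    """Similarity matrix -> CV rank selection -> NNMF -> domain model."""
    emb = scenario["embeddings"]
    sim = dd.build_similarity_matrix(emb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        k_star, curve = dd.cv_select_rank(sim, ranks=range(2, 25), reps=8,
                                          seed=1, max_iter=300)
        fit = dd.fit_nnmf(sim, k_star, seed=3)
        model = dd.build_domain_embeddings(fit, emb)
    model.selected_rank = k_star
    model.rmse_curve = curve
    return dict(sim=sim, fit=fit, model=model, k_star=k_star)


@pytest.fixture(scope="session")
def scored(scenario, discovery):
    """Lemma-domain matrix, continuous scores, calibrated binarization."""
    emb = scenario["embeddings"]
    reports = scenario["reports"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        M = ds.build_lemma_domain_matrix(emb, discovery["model"])
        rdm = ds.score_reports(reports, M)
        null_spec, null_shared = ds.build_null_sets(reports, M, seed=7)
        rdm = ds.calibrate_and_binarize(rdm, null_spec, null_shared, M)
    return dict(M=M, rdm=rdm)


@pytest.fixture(scope="session")
def analysis_table(scenario, scored):
    """Merged one-row-per-report table for the model suite."""
    reports, traits = scenario["reports"], scenario["traits"]
    rdm = scored["rdm"]
    dim_table = dims_mod.aggregate_rater_scores(scenario["rater_scores"])
    B = pd.DataFrame(rdm.B.astype(int), columns=rdm.retained_domains)
    B["report_id"] = rdm.report_ids
    table = (reports.merge(traits, on="participant_id")
             .merge(B, on="report_id")
             .merge(dim_table.reset_index(), on="report_id"))
    table["state"] = (table["vigilance_state"] == "dream").astype(int)
    table["time_rank"] = time_rank(table["date"])
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
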