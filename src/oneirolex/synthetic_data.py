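"""Synthetic study generator.

Produces every input the pipeline consumes — a lemma embedding space with
planted lexical domains, bag-of-lemma dream/wake reports with participant,
state and time effects, noisy multi-rater Likert scores, participant traits
and actigraphic indices — with known ground truth, so each analysis stage
can be tested for parameter recovery without any external download.

The generator makes no attempt at linguistically realistic text: reports are
bags of lemma tokens drawn from a planted domain mixture.  The geometric
construction places unit lemma vectors around domain centroids whose
pairwise cosines hit the requested within/between-similarity targets
exactly in expectation.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import (DIMENSION_NAMES, EmbeddingTable, REPORT_COLUMNS,
                     TRAIT_COLUMNS)

__all__ = [
    "GroundTruth",
    "gen_embedding_space",
    "gen_corpus",
    "gen_rater_scores",
    "gen_traits_and_actigraphy",
    "default_scenario",
    "DEFAULT_LATENT_EFFECTS",
]


@dataclass
class GroundTruth:
    """Planted structure and every parameter needed to regenerate a dataset."""

    generator: str
    seed: int
    params: dict
    domain_lemmas: dict | None = None        # domain index -> member lemmas
    shared_lemmas: list | None = None
    macro_assignment: list | None = None
    enriched_domains: list | None = None
    participant_effects: dict | None = None  # participant -> per-domain logits
    latent_effects: dict | None = None
    factor_loadings: list | None = None

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(self.__dict__, default=default,
                                         indent=1), encoding="utf-8")


def _orthonormal_complement(dim: int, k: int, rng: np.random.Generator,
                            avoid: np.ndarray | None = None) -> np.ndarray:
    """k random orthonormal directions, orthogonal to the rows of ``avoid``."""
    basis = [] if avoid is None else [v / np.linalg.norm(v) for v in avoid]
    out = []
    while len(out) < k:
        v = rng.standard_normal(dim)
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            v /= norm
            basis.append(v)
            out.append(v)
    return np.vstack(out)


def gen_embedding_space(
    n_domains: int = 10,
    lemmas_per_domain: int = 30,
    n_shared_lemmas: int = 20,
    dim: int = 50,
    within_sim: float = 0.7,
    between_sim: float = 0.1,
    n_macro: int = 1,
    macro_sim: float = 0.5,
    seed: int = 0,
) -> tuple[EmbeddingTable, GroundTruth]:
    """Unit lemma vectors clustered around planted domain centroids.

    Domain centroids share a common component so that centroids in different
    macro-clusters have cosine ``between_sim`` and centroids within the same
    macro-cluster ``macro_sim`` (with ``n_macro = 1`` every pair gets
    ``between_sim``).  Lemmas mix their centroid with isotropic noise so two
    same-domain lemmas have expected cosine ``within_sim``.  Shared lemmas
    sit midway between two random centroids.
    """
    if not 0.0 <= between_sim < within_sim <= 1.0:
        raise ValueError("need 0 <= between_sim < within_sim <= 1")
    a = macro_sim if n_macro > 1 else between_sim
    if n_macro > 1 and not between_sim <= a < within_sim:
        raise ValueError("need between_sim <= macro_sim < within_sim")
    if dim < 1 + n_macro + n_domains:
        raise ValueError(f"dim={dim} too small for {n_domains} domains in "
                         f"{n_macro} macro-clusters; need >= {1 + n_macro + n_domains}")
    rng = np.random.default_rng(seed)
    u0 = _orthonormal_complement(dim, 1, rng)[0]
    e = _orthonormal_complement(dim, n_macro, rng, avoid=u0[None, :])
    f = _orthonormal_complement(dim, n_domains, rng,
                                avoid=np.vstack([u0[None, :], e]))
    macro_of = np.array([k % n_macro for k in range(n_domains)])
    centroids = (np.sqrt(between_sim) * u0[None, :]
                 + np.sqrt(a - between_sim) * e[macro_of]
                 + np.sqrt(1.0 - a) * f)

    lemmas, vectors = [], []
    domain_lemmas: dict[int, list[str]] = {k: [] for k in range(n_domains)}
    w = within_sim
    for k in range(n_domains):
        for i in range(lemmas_per_domain):
            g = rng.standard_normal(dim)
            g /= np.linalg.norm(g)
            v = np.sqrt(w) * centroids[k] + np.sqrt(1.0 - w) * g
            v /= np.linalg.norm(v)
            name = f"d{k:02d}_w{i:03d}"
            lemmas.append(name)
            vectors.append(v)
            domain_lemmas[k].append(name)
    shared = []
    for i in range(n_shared_lemmas):
        k1, k2 = rng.choice(n_domains, size=2, replace=False)
        mid = centroids[k1] + centroids[k2]
        mid /= np.linalg.norm(mid)
        g = rng.standard_normal(dim)
        g /= np.linalg.norm(g)
        v = np.sqrt(w) * mid + np.sqrt(1.0 - w) * g
        v /= np.linalg.norm(v)
        name = f"sh_{i:03d}"
        lemmas.append(name)
        vectors.append(v)
        shared.append(name)
    table = EmbeddingTable(lemmas, np.vstack(vectors))
    truth = GroundTruth(
        generator="gen_embedding_space", seed=seed,
        params=dict(n_domains=n_domains, lemmas_per_domain=lemmas_per_domain,
                    n_shared_lemmas=n_shared_lemmas, dim=dim,
                    within_sim=within_sim, between_sim=between_sim,
                    n_macro=n_macro, macro_sim=macro_sim),
        domain_lemmas={str(k): v for k, v in domain_lemmas.items()},
        shared_lemmas=shared,
        macro_assignment=macro_of.tolist(),
    )
    return table, truth


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def gen_corpus(
    space_truth: GroundTruth,
    n_participants: int = 40,
    reports_per_state: int = 8,
    tokens_per_report: int = 25,
    state_domain_shift: float = 1.0,
    participant_sd: float = 0.5,
    time_effect: float = 0.0,
    n_enriched: int = 3,
    p_shared: float = 0.15,
    seed: int = 0,
    start_date: dt.date = dt.date(2020, 3, 1),
    span_days: int = 1460,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bag-of-lemma dream/wake reports from a planted domain mixture.

    Each report draws ``tokens_per_report`` tokens: with probability
    ``p_shared`` a shared lemma, otherwise a lemma from a domain sampled
    from a softmax mixture whose logits combine a per-participant random
    effect (sd ``participant_sd``), a dream-state boost of
    ``state_domain_shift`` log-odds on the ``n_enriched`` designated
    dream-enriched domains, and an optional monotone time drift
    (``time_effect`` log-odds across the acquisition window) on the first
    enriched domain.
    """
    if abs(state_domain_shift) > 20:
        raise ValueError("state_domain_shift degenerates the mixture")
    rng = np.random.default_rng(seed)
    n_domains = space_truth.params["n_domains"]
    domain_lemmas = {int(k): v for k, v in space_truth.domain_lemmas.items()}
    shared = space_truth.shared_lemmas or []
    enriched = list(range(min(n_enriched, n_domains)))
    part_fx = {f"p{p:03d}": rng.normal(0.0, participant_sd, size=n_domains)
               for p in range(n_participants)}
    rows = []
    rid = 0
    for pid, fx in part_fx.items():
        day0 = int(rng.integers(0, max(span_days - 15, 1)))
        days = rng.choice(15, size=reports_per_state, replace=False) + 1
        for state in ("dream", "wake"):
            for day in np.sort(days):
                date = start_date + dt.timedelta(days=day0 + int(day))
                t = (day0 + int(day)) / span_days
                logits = fx.copy()
                if state == "dream":
                    logits[enriched] += state_domain_shift
                if time_effect != 0.0 and enriched:
                    logits[enriched[0]] += time_effect * t
                mix = _softmax(logits)
                toks = []
                for _ in range(tokens_per_report):
                    if shared and rng.random() < p_shared:
                        toks.append(shared[rng.integers(len(shared))])
                    else:
                        k = rng.choice(n_domains, p=mix)
                        members = domain_lemmas[k]
                        toks.append(members[rng.integers(len(members))])
                rows.append((f"r{rid:05d}", pid, state, date, toks,
                             tokens_per_report, "main"))
                rid += 1
    reports = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    truth = GroundTruth(
        generator="gen_corpus", seed=seed,
        params=dict(n_participants=n_participants,
                    reports_per_state=reports_per_state,
                    tokens_per_report=tokens_per_report,
                    state_domain_shift=state_domain_shift,
                    participant_sd=participant_sd, time_effect=time_effect,
                    n_enriched=n_enriched, p_shared=p_shared,
                    start_date=str(start_date), span_days=span_days),
        enriched_domains=enriched,
        participant_effects={k: v.tolist() for k, v in part_fx.items()},
    )
    return reports, truth


#: default latent structure for the rater-score generator: a strong dream
#: boost on bizarreness, moderate perceptual boosts, a wake-leaning thought
#: dimension, neutral elsewhere
DEFAULT_LATENT_EFFECTS = {
    dim: {"base": 5.0, "state": 0.0, "time": 0.0, "participant_sd": 0.7}
    for dim in DIMENSION_NAMES
}
DEFAULT_LATENT_EFFECTS["bizarreness"]["state"] = 2.0
DEFAULT_LATENT_EFFECTS["visual"]["state"] = 1.2
DEFAULT_LATENT_EFFECTS["space"]["state"] = 1.0
DEFAULT_LATENT_EFFECTS["thought"]["state"] = -1.5
DEFAULT_LATENT_EFFECTS["agentivity"]["state"] = -1.2


def gen_rater_scores(
    reports: pd.DataFrame,
    latent_effects: dict | None = None,
    rater_sd: float = 1.0,
    n_raters: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noisy multi-rater 1–9 Likert scores around a planted latent value.

    Per report and dimension the latent score is ``base`` plus a dream-state
    effect, a time trend over normalized date rank, and a per-participant
    intercept; each rater observes the latent value plus independent
    ``N(0, rater_sd)`` noise, rounded and clipped to 1..9.
    """
    if rater_sd < 0:
        raise ValueError("rater_sd must be non-negative")
    if latent_effects is None:
        latent_effects = DEFAULT_LATENT_EFFECTS
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(reports["date"])
    span = (dates.max() - dates.min()).days or 1
    t = (dates - dates.min()).dt.days / span
    is_dream = (reports["vigilance_state"] == "dream").to_numpy().astype(float)
    participants = sorted(reports["participant_id"].unique())
    rows = []
    latents = {}
    for dim_name, eff in latent_effects.items():
        p_int = dict(zip(participants,
                         rng.normal(0.0, eff.get("participant_sd", 0.0),
                                    size=len(participants))))
        latent = (eff["base"]
                  + eff.get("state", 0.0) * is_dream
                  + eff.get("time", 0.0) * t.to_numpy()
                  + reports["participant_id"].map(p_int).to_numpy())
        latent = np.clip(latent, 1.0, 9.0)
        latents[dim_name] = latent
        for rater in range(n_raters):
            noisy = latent + rng.normal(0.0, rater_sd, size=len(latent))
            score = np.clip(np.rint(noisy), 1, 9).astype(int)
            for rid_, s in zip(reports["report_id"], score):
                rows.append((rid_, dim_name, f"rater{rater}", s))
    scores = pd.DataFrame(rows, columns=["report_id", "dimension",
                                         "rater_id", "score"])
    truth = GroundTruth(
        generator="gen_rater_scores", seed=seed,
        params=dict(rater_sd=rater_sd, n_raters=n_raters),
        latent_effects={k: {kk: vv for kk, vv in v.items()}
                        for k, v in latent_effects.items()},
    )
    return scores, truth


def gen_traits_and_actigraphy(
    n_participants: int = 40,
    n_indices: int = 24,
    n_factors: int = 4,
    nights_per_participant: int = 14,
    trait_corr: np.ndarray | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Participant trait table plus per-night actigraphic indices.

    Continuous traits are drawn from a multivariate normal with the
    requested correlation (identity by default); demographics mimic the
    study population (ages 18–69, 8–23 education years).  Actigraphic
    indices follow an ``n_factors`` latent model: each index loads on one
    dominant factor (block structure) plus ``N(0, noise_sd)`` noise, so a
    correlation PCA recovers the factors at low noise.
    """
    rng = np.random.default_rng(seed)
    cont = ["STAI", "PSQI", "ATD", "MW", "BSRT", "ROCFr", "MEQ", "VVIQ", "SCWT"]
    if trait_corr is None:
        trait_corr = np.eye(len(cont))
    trait_corr = np.asarray(trait_corr, dtype=float)
    try:
        L = np.linalg.cholesky(trait_corr)
    except np.linalg.LinAlgError:
        raise ValueError("trait correlation matrix is not positive definite")
    Z = rng.standard_normal((n_participants, len(cont))) @ L.T
    traits = pd.DataFrame(Z, columns=cont)
    traits.insert(0, "participant_id", [f"p{p:03d}" for p in range(n_participants)])
    traits.insert(1, "sex", rng.choice(["female", "male"], size=n_participants))
    traits.insert(2, "age", np.clip(rng.normal(35, 12, n_participants), 18, 69).round(1))
    traits.insert(3, "education", np.clip(rng.normal(17, 3, n_participants), 8, 23).round(1))
    traits.insert(4, "BADA", rng.normal(4.6, 0.4, n_participants).round(3))

    block = n_indices // n_factors
    loadings = np.zeros((n_indices, n_factors))
    for j in range(n_indices):
        loadings[j, min(j // block, n_factors - 1)] = rng.uniform(0.7, 1.0)
        loadings[j] += rng.uniform(-0.1, 0.1, n_factors)
    nights = []
    for p in range(n_participants):
        factors = rng.standard_normal((nights_per_participant, n_factors))
        X = factors @ loadings.T + rng.normal(0, noise_sd,
                                              (nights_per_participant, n_indices))
        df = pd.DataFrame(X, columns=[f"act{j + 1:02d}" for j in range(n_indices)])
        df.insert(0, "participant_id", f"p{p:03d}")
        df.insert(1, "night", range(1, nights_per_participant + 1))
        nights.append(df)
    actigraphy = pd.concat(nights, ignore_index=True)
    truth = GroundTruth(
        generator="gen_traits_and_actigraphy", seed=seed,
        params=dict(n_participants=n_participants, n_indices=n_indices,
                    n_factors=n_factors,
                    nights_per_participant=nights_per_participant,
                    noise_sd=noise_sd),
        factor_loadings=loadings.tolist(),
    )
    return traits, actigraphy, truth


def default_scenario(seed: int = 7, **overrides) -> dict:
    """The desk-scale study: 40 participants with 8 dream + 8 wake reports
    of 8 tokens each, 16 planted domains in 3 macro-clusters in a
    64-dimensional space.  Returns all generated tables plus their ground
    truths in one dictionary.

    The domain count deliberately exceeds the tokens-per-report count: a
    report holding a single domain-specific lemma scores ``1/L`` on its
    domain, while a report full of shared lemmas scores about ``1/K`` per
    domain (each shared lemma splits its unit row mass over its domains),
    so threshold calibration can only separate the two null distributions
    when ``K > L`` — the same regime as a real corpus, where the domain
    count is of the order of the report length.
    """
    params = dict(n_domains=16, lemmas_per_domain=24, n_shared_lemmas=24,
                  dim=64, within_sim=0.75, between_sim=0.08, n_macro=3,
                  macro_sim=0.25, n_participants=40, reports_per_state=8,
                  tokens_per_report=8, state_domain_shift=1.0,
                  participant_sd=0.5, time_effect=0.0, rater_sd=1.0)
    params.update(overrides)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    space, space_truth = gen_embedding_space(
        n_domains=params["n_domains"],
        lemmas_per_domain=params["lemmas_per_domain"],
        n_shared_lemmas=params["n_shared_lemmas"], dim=params["dim"],
        within_sim=params["within_sim"], between_sim=params["between_sim"],
        n_macro=params["n_macro"], macro_sim=params["macro_sim"],
        seed=int(seeds[0]))
    reports, corpus_truth = gen_corpus(
        space_truth, n_participants=params["n_participants"],
        reports_per_state=params["reports_per_state"],
        tokens_per_report=params["tokens_per_report"],
        state_domain_shift=params["state_domain_shift"],
        participant_sd=params["participant_sd"],
        time_effect=params["time_effect"], seed=int(seeds[1]))
    scores, rater_truth = gen_rater_scores(reports, rater_sd=params["rater_sd"],
                                           seed=int(seeds[2]))
    traits, actigraphy, trait_truth = gen_traits_and_actigraphy(
        n_participants=params["n_participants"], seed=int(seeds[3]))
    return dict(embeddings=space, reports=reports, rater_scores=scores,
                traits=traits, actigraphy=actigraphy,
                truths=dict(space=space_truth, corpus=corpus_truth,
                            raters=rater_truth, traits=trait_truth),
                seed=seed, params=params)
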