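"""From a domain model to per-report domain scores.

The chain implemented here: cosine similarities between every lemma and every
domain embedding are sparsified per domain at a knee-point cutoff, then
normalized twice (within domain, then within lemma) to yield the
lemma-by-domain weight matrix; report scores are length-normalized sums of
their tokens' weights; per-domain binarization thresholds are calibrated on
two synthetic null corpora (domain-specific-only lemmas for sensitivity,
shared lemmas for specificity) at the sensitivity = specificity crossing,
and a domain is retained only if its balanced accuracy exceeds the floor
(80% by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .corpus import EmbeddingTable
from .domain_discovery import DomainModel, cosine_rows

__all__ = [
    "LemmaDomainMatrix",
    "ReportDomainMatrix",
    "NullReportSet",
    "knee_point",
    "build_lemma_domain_matrix",
    "score_reports",
    "build_null_sets",
    "calibrate_and_binarize",
    "domain_frequencies",
    "jaccard_matrix",
    "FILLER_TOKEN",
]

logger = logging.getLogger(__name__)

#: out-of-vocabulary filler used in null reports when no zero-weight lemma exists
FILLER_TOKEN = "__filler__"


@dataclass
class LemmaDomainMatrix:
    """Sparsified, doubly normalized lemma x domain weights.

    Every lemma row with at least one nonzero entry sums to 1, so a lemma
    loading on a single domain carries weight exactly 1 there.
    """

    lemmas: list[str]
    domains: list[str]
    M: np.ndarray
    knee_thresholds: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {lem: i for i, lem in enumerate(self.lemmas)}

    @property
    def sparsity(self) -> float:
        return 1.0 - np.count_nonzero(self.M) / self.M.size

    def row(self, lemma: str) -> np.ndarray | None:
        i = self._index.get(lemma)
        return None if i is None else self.M[i]

    def domain_specific_lemmas(self) -> dict[str, list[str]]:
        """Lemmas whose row is nonzero in exactly one domain, per domain."""
        nnz = np.count_nonzero(self.M, axis=1)
        out: dict[str, list[str]] = {d: [] for d in self.domains}
        for i in np.flatnonzero(nnz == 1):
            k = int(np.flatnonzero(self.M[i])[0])
            out[self.domains[k]].append(self.lemmas[i])
        return out

    def shared_lemmas(self) -> list[str]:
        """Lemmas loading on two or more domains."""
        nnz = np.count_nonzero(self.M, axis=1)
        return [self.lemmas[i] for i in np.flatnonzero(nnz >= 2)]

    def unloaded_lemmas(self) -> list[str]:
        nnz = np.count_nonzero(self.M, axis=1)
        return [self.lemmas[i] for i in np.flatnonzero(nnz == 0)]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "lemma_domain.mtx"), sparse.csr_matrix(self.M))
        pd.Series(self.lemmas, name="lemma").to_csv(
            directory / "lemma_domain_rows.csv", index=False)
        pd.DataFrame({"domain": self.domains,
                      "knee_threshold": self.knee_thresholds}).to_csv(
            directory / "lemma_domain_cols.csv", index=False)


@dataclass
class ReportDomainMatrix:
    """Continuous (and, after calibration, binary) report x domain scores."""

    report_ids: list[str]
    domains: list[str]
    C: np.ndarray
    B: np.ndarray | None = None
    retained_domains: list[str] | None = None
    thresholds: pd.Series | None = None
    calibration: pd.DataFrame | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.C, index=self.report_ids, columns=self.domains).to_csv(
            directory / "report_domain_continuous.csv")
        if self.B is not None:
            mmwrite(str(directory / "report_domain_binary.mtx"),
                    sparse.csr_matrix(self.B.astype(np.int8)))
            pd.Series(self.report_ids, name="report_id").to_csv(
                directory / "report_domain_rows.csv", index=False)
            pd.Series(self.retained_domains, name="domain").to_csv(
                directory / "report_domain_cols.csv", index=False)
        if self.calibration is not None:
            self.calibration.to_csv(directory / "calibration.csv", index=False)


@dataclass
class NullReportSet:
    """Synthetic calibration corpus matched to the real one in size."""

    kind: str                       # 'domain_specific' or 'shared'
    reports: list[list[str]]
    target_domain: list[str] | None = None


# ---------------------------------------------------------------------------
# knee point
# ---------------------------------------------------------------------------

def knee_point(values: np.ndarray) -> float:
    """Knee of a descending sorted positive curve.

    Returns the value at the point of maximum perpendicular distance from
    the chord joining the first and last points (the classic knee/elbow
    heuristic).  Ties pick the first (largest-value) index.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("knee_point needs at least 3 values")
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("values must be sorted in descending order")
    if np.ptp(v) == 0:
        raise ValueError("constant input has no knee")
    x = np.arange(v.size, dtype=float)
    # chord from (x0, v0) to (xn, vn); perpendicular distance of each point
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    dist = np.abs(dy * x - dx * v + dx * v[0] - dy * x[0]) / np.hypot(dx, dy)
    return float(v[int(np.argmax(dist))])


# ---------------------------------------------------------------------------
# lemma-by-domain matrix
# ---------------------------------------------------------------------------

def build_lemma_domain_matrix(
    table: EmbeddingTable,
    model: DomainModel,
    domain_names: list[str] | None = None,
) -> LemmaDomainMatrix:
    """Sparsify and doubly normalize lemma-to-domain cosine similarities.

    Steps, per the pipeline: (1) cosine similarity between every lemma
    embedding and every domain embedding, negatives clipped to 0;
    (2) within each domain, zero every similarity below that domain's
    knee-point cutoff; (3) within each domain, divide surviving entries by
    their sum; (4) within each lemma, divide surviving entries by their sum.
    """
    if table.d != model.embeddings.shape[1]:
        raise ValueError("embedding dimensionality mismatch")
    if domain_names is None:
        domain_names = [f"domain{k:02d}" for k in range(model.n_domains)]
    C = cosine_rows(table.vectors, model.embeddings)
    np.clip(C, 0.0, None, out=C)
    K = model.n_domains
    thresholds = np.empty(K)
    for k in range(K):
        col = C[:, k]
        pos = np.sort(col[col > 0])[::-1]
        if pos.size < 3 or np.ptp(pos) == 0:
            warnings.warn(f"domain {domain_names[k]}: too few distinct positive "
                          "similarities for a knee; kept un-sparsified",
                          RuntimeWarning)
            thresholds[k] = 0.0
            continue
        thresholds[k] = knee_point(pos)
        col[col < thresholds[k]] = 0.0
    # within-domain normalization
    col_sums = C.sum(axis=0)
    empty = col_sums == 0
    if np.any(empty):
        warnings.warn("domain(s) with no surviving lemmas after sparsification: "
                      f"{[domain_names[k] for k in np.flatnonzero(empty)]}",
                      RuntimeWarning)
    C = C / np.where(empty, 1.0, col_sums)
    # within-lemma normalization
    row_sums = C.sum(axis=1, keepdims=True)
    C = np.divide(C, np.where(row_sums == 0, 1.0, row_sums))
    return LemmaDomainMatrix(list(table.lemmas), list(domain_names), C, thresholds)


# ---------------------------------------------------------------------------
# report scoring
# ---------------------------------------------------------------------------

def _score_lemma_lists(lemma_lists, M: LemmaDomainMatrix) -> np.ndarray:
    K = len(M.domains)
    C = np.zeros((len(lemma_lists), K))
    for r, toks in enumerate(lemma_lists):
        acc = np.zeros(K)
        for tok in toks:
            row = M.row(tok)
            if row is not None:
                acc += row
        C[r] = acc / len(toks)
    return C


def score_reports(reports: pd.DataFrame, M: LemmaDomainMatrix) -> ReportDomainMatrix:
    """Continuous report x domain scores.

    Each report's score for a domain is the sum of its tokens' weights for
    that domain, divided by the report's total token count.  Out-of-
    vocabulary tokens contribute nothing to the numerator but count in the
    denominator; repeated lemmas contribute once per occurrence.
    Contentless reports are skipped (logged).
    """
    n_empty = int((reports["lemmas"].apply(len) == 0).sum())
    if n_empty:
        logger.info("skipping %d contentless report(s)", n_empty)
    kept = reports[reports["lemmas"].apply(len) > 0]
    C = _score_lemma_lists(list(kept["lemmas"]), M)
    return ReportDomainMatrix(report_ids=list(kept["report_id"]),
                              domains=list(M.domains), C=C)


# ---------------------------------------------------------------------------
# null sets and calibration
# ---------------------------------------------------------------------------

def build_null_sets(
    reports: pd.DataFrame,
    M: LemmaDomainMatrix,
    seed: int,
    min_reports: int | None = None,
) -> tuple[NullReportSet, NullReportSet]:
    """Construct the two calibration corpora, sized like ``reports``.

    The *domain-specific* set mirrors the corpus (same number of reports,
    same words per report) but plants exactly one domain-specific lemma in
    each null report — a lemma loading on that report's target domain only —
    padding the rest with non-loading fillers; it estimates sensitivity.
    The *shared* set fills each report with lemmas loading on two or more
    domains, sampled to match their occurrence frequencies in the real
    corpus; it estimates specificity.  ``min_reports`` optionally inflates
    both sets (cycling over the corpus' report lengths) for more stable
    calibration on small corpora.
    """
    rng = np.random.default_rng(seed)
    kept = reports[reports["lemmas"].apply(len) > 0]
    lengths = [len(toks) for toks in kept["lemmas"]]
    if min_reports is not None and len(lengths) < min_reports:
        reps = int(np.ceil(min_reports / len(lengths)))
        lengths = (lengths * reps)[:min_reports]

    specific = M.domain_specific_lemmas()
    eligible = [d for d in M.domains if specific[d]]
    skipped = [d for d in M.domains if not specific[d]]
    if skipped:
        warnings.warn("domain(s) without any domain-specific lemma excluded "
                      f"from sensitivity calibration: {skipped}", RuntimeWarning)
    if not eligible:
        raise ValueError("no domain has a domain-specific lemma")
    fillers = M.unloaded_lemmas() or [FILLER_TOKEN]

    spec_reports, targets = [], []
    for r, L in enumerate(lengths):
        target = eligible[r % len(eligible)]
        lem = specific[target][rng.integers(len(specific[target]))]
        toks = list(rng.choice(fillers, size=L - 1)) if L > 1 else []
        toks.insert(int(rng.integers(L)) if L > 1 else 0, lem)
        spec_reports.append(toks)
        targets.append(target)

    shared = M.shared_lemmas()
    if not shared:
        raise ValueError("no shared lemmas available for the specificity null")
    counts = pd.Series(
        [tok for toks in kept["lemmas"] for tok in toks]).value_counts()
    w = np.array([counts.get(lem, 0) for lem in shared], dtype=float)
    w = np.ones(len(shared)) / len(shared) if w.sum() == 0 else w / w.sum()
    shared_reports = [list(rng.choice(shared, size=L, p=w)) for L in lengths]

    return (NullReportSet("domain_specific", spec_reports, targets),
            NullReportSet("shared", shared_reports))


def _sweep_grid(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct pooled scores, plus flanks."""
    u = np.unique(scores)
    if u.size == 1:
        return np.array([u[0]])
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1e-12], mids, [u[-1] + 1e-12]))


def calibrate_and_binarize(
    rdm: ReportDomainMatrix,
    null_specific: NullReportSet,
    null_shared: NullReportSet,
    M: LemmaDomainMatrix,
    accuracy_floor: float = 0.80,
) -> ReportDomainMatrix:
    """Calibrate per-domain binarization thresholds on the two null sets.

    For each domain the threshold grid covers midpoints of all distinct
    pooled null scores; sensitivity is the fraction of that domain's
    domain-specific null reports scoring at or above the threshold,
    specificity the fraction of shared null reports scoring below it.  The
    chosen threshold minimizes |sensitivity - specificity| (ties resolved
    toward higher balanced accuracy, then lower threshold).  A domain is
    retained iff its balanced accuracy exceeds ``accuracy_floor``; the
    continuous matrix is binarized at the retained thresholds.
    """
    C_spec = _score_lemma_lists(null_specific.reports, M)
    C_shared = _score_lemma_lists(null_shared.reports, M)
    targets = np.asarray(null_specific.target_domain)
    rows = []
    for k, dom in enumerate(rdm.domains):
        own = C_spec[targets == dom, k]
        other = C_shared[:, k]
        if own.size == 0:
            warnings.warn(f"domain {dom}: no targeted null reports; dropped",
                          RuntimeWarning)
            rows.append((dom, np.nan, np.nan, np.nan, np.nan, False))
            continue
        grid = _sweep_grid(np.concatenate([own, other]))
        sens = (own[:, None] >= grid[None, :]).mean(axis=0)
        spec = (other[:, None] < grid[None, :]).mean(axis=0)
        bacc = (sens + spec) / 2.0
        gap = np.abs(sens - spec)
        # minimal gap; ties -> higher balanced accuracy, then lower threshold
        order = np.lexsort((grid, -bacc, gap))
        j = order[0]
        rows.append((dom, float(grid[j]), float(sens[j]), float(spec[j]),
                     float(bacc[j]), bool(bacc[j] > accuracy_floor)))
    calib = pd.DataFrame(rows, columns=["domain", "threshold", "sensitivity",
                                        "specificity", "balanced_accuracy",
                                        "retained"])
    retained = calib[calib["retained"]]["domain"].tolist()
    idx = [rdm.domains.index(d) for d in retained]
    thresholds = calib.set_index("domain")["threshold"]
    B = rdm.C[:, idx] >= thresholds[retained].to_numpy()[None, :]
    return ReportDomainMatrix(
        report_ids=rdm.report_ids, domains=rdm.domains, C=rdm.C,
        B=B, retained_domains=retained, thresholds=thresholds,
        calibration=calib)


def evaluate_on_nulls(
    rdm: ReportDomainMatrix,
    null_specific: NullReportSet,
    null_shared: NullReportSet,
    M: LemmaDomainMatrix,
) -> pd.DataFrame:
    """Balanced accuracy of already-calibrated thresholds on fresh null sets.

    Used to verify that calibration generalizes: the thresholds come from
    ``rdm`` (previously calibrated), the null sets are newly generated.
    """
    if rdm.thresholds is None:
        raise ValueError("matrix has not been calibrated")
    C_spec = _score_lemma_lists(null_specific.reports, M)
    C_shared = _score_lemma_lists(null_shared.reports, M)
    targets = np.asarray(null_specific.target_domain)
    rows = []
    for dom in rdm.retained_domains:
        k = rdm.domains.index(dom)
        t = rdm.thresholds[dom]
        own = C_spec[targets == dom, k]
        sens = float((own >= t).mean()) if own.size else np.nan
        spec = float((C_shared[:, k] < t).mean())
        rows.append((dom, t, sens, spec, (sens + spec) / 2.0))
    return pd.DataFrame(rows, columns=["domain", "threshold", "sensitivity",
                                       "specificity", "balanced_accuracy"])


# ---------------------------------------------------------------------------
# frequencies and overlap
# ---------------------------------------------------------------------------

def domain_frequencies(rdm: ReportDomainMatrix, reports: pd.DataFrame) -> pd.DataFrame:
    """Absolute domain frequencies by vigilance state, with the standard
    deviation of per-participant frequencies (missing when a state has a
    single participant)."""
    if rdm.B is None:
        raise ValueError("matrix has not been binarized")
    meta = reports.set_index("report_id").loc[rdm.report_ids]
    B = pd.DataFrame(rdm.B.astype(int), columns=rdm.retained_domains)
    B["state"] = meta["vigilance_state"].to_numpy()
    B["participant"] = meta["participant_id"].to_numpy()
    rows = []
    for state, grp in B.groupby("state"):
        per_part = grp.groupby("participant")[rdm.retained_domains].sum()
        for dom in rdm.retained_domains:
            sd = float(per_part[dom].std(ddof=1)) if len(per_part) > 1 else np.nan
            rows.append((dom, state, int(grp[dom].sum()), sd))
    return pd.DataFrame(rows, columns=["domain", "state", "count",
                                       "sd_across_participants"])


def jaccard_matrix(B: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard overlap between binary domain columns.

    ``J(a, b) = |a AND b| / |a OR b|``; a pair of all-zero columns gets 0
    with a warning (0/0 is undefined).
    """
    B = np.asarray(B, dtype=bool)
    inter = (B.T.astype(int) @ B.astype(int)).astype(float)
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union == 0, 1, union), 0.0)
    if np.any(union == 0):
        warnings.warn("all-zero domain column pair(s); Jaccard set to 0",
                      RuntimeWarning)
    return J
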