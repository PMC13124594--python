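"""Data model and I/O for verbal reports, traits, rater scores and embeddings.

The analysis operates on four tabular inputs plus a lemma embedding space:

* an :class:`EmbeddingTable` mapping each lemma to a dense vector (word2vec
  text format on disk);
* a report table, one row per verbal report, with participant ID, vigilance
  state (``dream``/``wake``), date and the pre-lemmatized content lemmas;
* per-participant trait scores (demographics, questionnaires, cognitive tests);
* long-format per-rater Likert scores for the 16 semantic dimensions.

This module also hosts the small preprocessing computations that sit between
raw tables and modelling: composite embeddings for out-of-vocabulary lemmas,
the verbosity score from the picture-description task, per-participant
downsampling of wakefulness reports to match dream reports, and normalized
time ranks for longitudinal models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EmbeddingTable",
    "REPORT_COLUMNS",
    "TRAIT_COLUMNS",
    "DIMENSION_NAMES",
    "read_embeddings",
    "write_embeddings",
    "read_reports_jsonl",
    "write_reports_jsonl",
    "read_reports_csv",
    "write_reports_csv",
    "read_traits",
    "write_traits",
    "read_rater_scores",
    "write_rater_scores",
    "composite_embedding",
    "verbosity_score",
    "downsample_wakefulness",
    "time_rank",
    "contentful",
]

#: canonical column order for report tables
REPORT_COLUMNS = [
    "report_id",
    "participant_id",
    "vigilance_state",
    "date",
    "lemmas",
    "n_words",
    "dataset",
]

#: trait columns beyond participant_id, following the study's naming conventions
TRAIT_COLUMNS = [
    "sex", "age", "education", "BADA",
    "STAI", "PSQI", "ATD", "MW", "BSRT", "ROCFr", "MEQ", "VVIQ", "SCWT",
]

#: the 16 hypothesis-driven semantic dimensions
DIMENSION_NAMES = [
    "incorporation", "thought", "visual", "auditory", "tactile",
    "valence", "arousal", "bizarreness", "social", "movements",
    "settings", "space", "time", "body", "limitations", "agentivity",
]


@dataclass
class EmbeddingTable:
    """Lemma -> dense vector lookup backing the whole lexical analysis.

    Parameters
    ----------
    lemmas
        Unique lemma strings, one per row of ``vectors``.
    vectors
        Array of shape ``(n_lemmas, d)``; all rows finite and nonzero.
    """

    lemmas: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array")
        if len(self.lemmas) != self.vectors.shape[0]:
            raise ValueError("lemma count does not match vector rows")
        if self.vectors.shape[1] < 2:
            raise ValueError("embedding dimensionality must be >= 2")
        if len(set(self.lemmas)) != len(self.lemmas):
            dupes = pd.Series(self.lemmas).value_counts()
            dupes = dupes[dupes > 1].index.tolist()
            raise ValueError(f"duplicate lemmas: {dupes[:5]}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding values")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = [self.lemmas[i] for i in np.flatnonzero(norms == 0)[:5]]
            raise ValueError(f"zero embedding vector(s) for: {bad}")
        self._index = {lem: i for i, lem in enumerate(self.lemmas)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.lemmas)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self._index

    def vector(self, lemma: str) -> np.ndarray:
        try:
            return self.vectors[self._index[lemma]]
        except KeyError:
            raise KeyError(f"lemma not in embedding table: {lemma!r}") from None

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the vectors."""
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        return self.vectors / norms


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a word2vec text file (header ``n d``, then ``lemma v1 ... vd``)."""
    lemmas: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected word2vec text header 'n d'")
        n, d = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(f"malformed embedding line for {parts[0]!r}")
            lemmas.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if len(lemmas) != n:
        raise ValueError(f"header promised {n} rows, found {len(lemmas)}")
    return EmbeddingTable(lemmas, np.vstack(rows))


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.d}\n")
        for lemma, vec in zip(table.lemmas, table.vectors):
            fh.write(lemma + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def _normalize_reports(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["lemmas"] = df["lemmas"].apply(list)
    df["n_words"] = df["n_words"].astype(int)
    bad = set(df["vigilance_state"]) - {"dream", "wake"}
    if bad:
        raise ValueError(f"unknown vigilance_state values: {sorted(bad)}")
    return df[REPORT_COLUMNS]


def read_reports_jsonl(path: str | Path) -> pd.DataFrame:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                records.append(json.loads(line))
    return _normalize_reports(pd.DataFrame.from_records(records))


def write_reports_jsonl(reports: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in reports[REPORT_COLUMNS].to_dict("records"):
            rec["date"] = str(rec["date"])
            rec["lemmas"] = list(rec["lemmas"])
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_reports_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", keep_default_na=False)
    df["lemmas"] = [s.split("|") if s else [] for s in df["lemmas"].astype(str)]
    return _normalize_reports(df)


def write_reports_csv(reports: pd.DataFrame, path: str | Path) -> None:
    out = reports[REPORT_COLUMNS].copy()
    out["lemmas"] = out["lemmas"].apply("|".join)
    out.to_csv(path, index=False, encoding="utf-8")


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant_id in trait table")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=False, encoding="utf-8")


def read_rater_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if not df["score"].between(1, 9).all():
        raise ValueError("rater scores must lie in 1..9")
    if df.duplicated(["report_id", "dimension", "rater_id"]).any():
        raise ValueError("duplicate (report, dimension, rater) score")
    return df


def write_rater_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False, encoding="utf-8")


def contentful(reports: pd.DataFrame) -> pd.DataFrame:
    """Reports with at least one content lemma (contentless ones are kept in
    the table but excluded from domain scoring and models)."""
    return reports[reports["lemmas"].apply(len) > 0]


# ---------------------------------------------------------------------------
# preprocessing computations
# ---------------------------------------------------------------------------

def composite_embedding(member_lemmas: list[str], table: EmbeddingTable) -> np.ndarray:
    """Element-wise mean of the member lemmas' vectors.

    Used to synthesize embeddings for out-of-vocabulary items (e.g. building
    a 'covid' vector from coronavirus/virus/pandemic/... members) and for
    anonymization placeholder codes.
    """
    if not member_lemmas:
        raise ValueError("member lemma list must be non-empty")
    vecs = np.vstack([table.vector(lem) for lem in member_lemmas])
    return vecs.mean(axis=0)


def verbosity_score(word_counts: tuple[int, int] | list[int]) -> float:
    """Natural log of the mean word count over the two picture descriptions."""
    if len(word_counts) != 2:
        raise ValueError("expected exactly two word counts")
    a, b = word_counts
    if a < 1 or b < 1:
        raise ValueError("word counts must be positive")
    return float(np.log((a + b) / 2.0))


def time_rank(dates) -> np.ndarray:
    """Normalized chronological ranks in [0, 1]; ties get the average rank."""
    dates = pd.to_datetime(pd.Series(list(dates)))
    if dates.nunique() < 2:
        raise ValueError("time_rank needs at least 2 distinct dates")
    r = rankdata(dates.values, method="average") - 1.0
    return np.asarray(r / r.max())


def downsample_wakefulness(reports: pd.DataFrame, seed: int) -> list[str]:
    """Select wakefulness reports to match each participant's dream count.

    Per participant, ``min(n_wake, n_dream)`` wake reports are chosen.  Each
    dream (processed chronologically) is matched to the nearest earlier
    experimental day holding an unassigned wake report; dreams without such a
    day draw uniformly from the remaining unassigned wake reports.

    Returns the selected wake ``report_id`` values (order not meaningful).
    """
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for _, grp in reports.groupby("participant_id", sort=True):
        dreams = grp[grp["vigilance_state"] == "dream"].sort_values(["date", "report_id"])
        wakes = grp[grp["vigilance_state"] == "wake"].sort_values(["date", "report_id"])
        if wakes.empty or dreams.empty:
            continue
        n_pick = min(len(wakes), len(dreams))
        unassigned = dict(zip(wakes["report_id"], wakes["date"]))
        picked: list[str] = []
        for d_date in dreams["date"]:
            earlier = [rid for rid, w_date in unassigned.items() if w_date < d_date]
            if earlier:
                # nearest earlier day; report_id breaks date ties deterministically
                rid = max(earlier, key=lambda r: (unassigned[r], r))
                picked.append(rid)
                del unassigned[rid]
        # substitutes for unmatched dreams, drawn uniformly from the leftovers
        n_substitute = min(n_pick - len(picked), len(unassigned))
        if n_substitute > 0:
            pool = sorted(unassigned)
            picked.extend(rng.choice(pool, size=n_substitute, replace=False).tolist())
        selected.extend(picked[:n_pick])
    return selected
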