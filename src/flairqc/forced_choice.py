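"""Blinded forced-choice comparison: scheduling, simulated votes, ratings.

Observed image quality is quantified by repeated two-alternative forced
choice: a rater sees a random pair of volumes and must pick the better
one.  Each study's quality estimate is the proportion of comparisons won,

    P = N_s / N_t,            SD = sqrt(P (1 - P) / N_t),

with N_s the comparisons won and N_t the comparisons involving the study;
P follows a binomial proportion.  A logistic (Bradley-Terry-style)
observer with decision scale tau stands in for the human rater when votes
are simulated rather than ingested.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

WINNERS = ("left", "right")


@dataclass(frozen=True)
class Vote:
    study_left: str
    study_right: str
    winner: str  # "left" | "right"
    observer_id: str = "sim-01"
    vote_index: int = 0

    def __post_init__(self) -> None:
        if self.study_left == self.study_right:
            raise ValueError(f"self-pair forbidden: {self.study_left}")
        if self.winner not in WINNERS:
            raise ValueError(f"winner must be one of {WINNERS}, got {self.winner!r}")


@dataclass
class RatingResult:
    study_id: str
    n_superior: int
    n_total: int

    @property
    def p(self) -> float:
        return self.n_superior / self.n_total

    @property
    def sd(self) -> float:
        p = self.p
        return float(np.sqrt(p * (1.0 - p) / self.n_total))


@dataclass(frozen=True)
class ObserverModel:
    """Logistic paired-comparison observer.

    Picks the left volume with probability sigmoid((q_left - q_right)/tau):
    tau -> 0 gives a deterministic quality oracle, tau -> inf a coin flip.
    """

    quality: dict[str, float] = field(default_factory=dict)
    tau: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def schedule_pairs(
    study_ids: list[str], n_votes: int, seed: int
) -> list[tuple[str, str]]:
    """Uniform random unordered pairs with replacement, sides randomized.

    The only constraint is no self-comparison.  Deterministic per seed.
    """
    ids = list(study_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 studies to schedule comparisons")
    if n_votes < 1:
        raise ValueError("n_votes must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ids)
    i = rng.integers(0, n, size=n_votes)
    j = rng.integers(0, n - 1, size=n_votes)
    j = np.where(j >= i, j + 1, j)  # uniform over the other n-1 studies
    swap = rng.integers(0, 2, size=n_votes).astype(bool)
    left = np.where(swap, j, i)
    right = np.where(swap, i, j)
    return [(ids[a], ids[b]) for a, b in zip(left, right)]


def simulate_votes(pairs: list[tuple[str, str]], model: ObserverModel) -> list[Vote]:
    """Simulate one observer voting on the scheduled pairs."""
    for pair in pairs:
        for sid in pair:
            if sid not in model.quality:
                raise KeyError(f"no latent quality for study {sid!r}")
    rng = np.random.default_rng(model.seed)
    u = rng.random(len(pairs))
    votes = []
    for k, (left, right) in enumerate(pairs):
        d = (model.quality[left] - model.quality[right]) / model.tau
        p_left = 1.0 / (1.0 + np.exp(-d))
        votes.append(
            Vote(left, right, "left" if u[k] < p_left else "right", vote_index=k)
        )
    return votes


def compute_ratings(
    votes: list[Vote], study_ids: list[str] | None = None
) -> tuple[list[RatingResult], list[str]]:
    """Per-study estimate P and binomial SD; unrated studies are returned
    separately (flagged, excluded from downstream statistics)."""
    if not votes:
        raise ValueError("empty vote list")
    wins: dict[str, int] = {}
    totals: dict[str, int] = {}
    for v in votes:
        for sid in (v.study_left, v.study_right):
            totals[sid] = totals.get(sid, 0) + 1
            wins.setdefault(sid, 0)
        winner = v.study_left if v.winner == "left" else v.study_right
        wins[winner] += 1
    all_ids = list(study_ids) if study_ids is not None else sorted(totals)
    rated = [
        RatingResult(sid, wins.get(sid, 0), totals[sid])
        for sid in all_ids
        if totals.get(sid, 0) >= 1
    ]
    unrated = [sid for sid in all_ids if totals.get(sid, 0) == 0]
    return rated, unrated


VOTE_COLUMNS = ["study_left", "study_right", "winner", "observer_id", "vote_index"]


def write_votes(votes: list[Vote], path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(VOTE_COLUMNS)
        for v in votes:
            w.writerow([v.study_left, v.study_right, v.winner, v.observer_id, v.vote_index])


def read_votes(path: str | Path) -> list[Vote]:
    """Read a vote log; malformed rows, self-pairs and unknown winner
    tokens are rejected with the offending line number."""
    votes = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        n_skipped = 0
        while header and header[0].startswith("#"):  # provenance comment lines
            header = next(reader, None)
            n_skipped += 1
        if header != VOTE_COLUMNS:
            raise ValueError(f"{path}: line {1 + n_skipped}: expected header {VOTE_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2 + n_skipped):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != len(VOTE_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected {len(VOTE_COLUMNS)} fields, got {len(row)}")
            left, right, winner, observer_id, idx = row
            try:
                vote = Vote(left, right, winner, observer_id, int(idx))
            except (ValueError, KeyError) as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from e
            votes.append(vote)
    if not votes:
        raise ValueError(f"{path}: no votes found")
    return votes
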