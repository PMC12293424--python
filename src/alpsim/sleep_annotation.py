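"""EEG-based sleep-state consensus labels and subject inclusion.

Between consecutive DTI scans a 90 s EEG segment is scored by several
independent raters as awake (0), asleep (1) or unreadable (U).  An epoch's
consensus label is the state a strict majority of raters agrees on; epochs
without such a majority become N (no consensus / unusable).  A subject enters
the ALPS analysis only when the analysis window — the awake scan plus the
first six sleep scans by default — shows an awake first epoch followed
exclusively by sleep.

Inter-rater agreement is summarised with Fleiss' kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

__all__ = [
    "N_EPOCHS",
    "AnnotationGrid",
    "consensus_epoch",
    "consensus_grid",
    "include_subjects",
    "fleiss_kappa",
    "table1_grid",
    "simulate_ratings",
]

#: scans per session: one awake scan + 16 sleep-period scans
N_EPOCHS = 17

AWAKE, SLEEP, UNREADABLE, NO_CONSENSUS = "0", "1", "U", "N"


@dataclass
class AnnotationGrid:
    """Consensus sleep labels, subjects x 17 epochs, values {0, 1, N}."""

    subjects: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.shape != (len(self.subjects), N_EPOCHS):
            raise ValueError(
                f"grid must be {len(self.subjects)} x {N_EPOCHS}, "
                f"got {self.labels.shape}"
            )
        bad = set(self.labels.ravel()) - {AWAKE, SLEEP, NO_CONSENSUS}
        if bad:
            raise ValueError(f"invalid grid labels: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.labels,
            index=pd.Index(self.subjects, name="subject"),
            columns=[f"epoch_{i + 1}" for i in range(N_EPOCHS)],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationGrid":
        cols = [f"epoch_{i + 1}" for i in range(N_EPOCHS)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"annotation grid missing columns: {missing}")
        return cls(list(df.index.astype(str)), df[cols].to_numpy(dtype="U1"))


def consensus_epoch(labels) -> str:
    """Majority consensus of one epoch's rater labels.

    Returns the label shared by a strict majority (> n/2) of the raters among
    {0, 1}; N otherwise (including unreadable-dominated epochs).
    """
    labels = [str(l) for l in labels]
    if len(labels) == 0:
        raise ValueError("epoch has no rater labels")
    if len(labels) < 2:
        raise ValueError("consensus needs at least 2 raters")
    bad = set(labels) - {AWAKE, SLEEP, UNREADABLE}
    if bad:
        raise ValueError(f"invalid rater labels: {sorted(bad)}")
    need = len(labels) // 2 + 1
    for state in (AWAKE, SLEEP):
        if labels.count(state) >= need:
            return state
    return NO_CONSENSUS


def consensus_grid(ratings: pd.DataFrame) -> AnnotationGrid:
    """Collapse a long-format ratings table (subject, epoch, rater, label)
    into a consensus AnnotationGrid."""
    required = {"subject", "epoch", "rater", "label"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    subjects = list(pd.unique(ratings["subject"].astype(str)))
    labels = np.full((len(subjects), N_EPOCHS), NO_CONSENSUS, dtype="U1")
    for si, sub in enumerate(subjects):
        block = ratings[ratings["subject"].astype(str) == sub]
        for epoch, grp in block.groupby("epoch"):
            labels[si, int(epoch) - 1] = consensus_epoch(grp["label"].tolist())
    return AnnotationGrid(subjects, labels)


def include_subjects(grid: AnnotationGrid, window=range(1, 8)) -> list:
    """Subjects whose analysis window is awake-then-stable-sleep.

    ``window`` holds 1-based epoch indices; the first must be awake (0) and
    every later one asleep (1).  Any N (or awake relapse) inside the window
    drops the subject.  The default window — epochs 1-7 — is the awake scan
    plus the six sleep scans the time-series analysis uses.
    """
    window = list(window)
    if not window or min(window) < 1 or max(window) > N_EPOCHS:
        raise ValueError(f"window must be within 1..{N_EPOCHS}")
    first, rest = window[0], window[1:]
    out = []
    for sub, row in zip(grid.subjects, grid.labels):
        if row[first - 1] == AWAKE and all(row[e - 1] == SLEEP for e in rest):
            out.append(sub)
    return out


def fleiss_kappa(ratings, categories=(AWAKE, SLEEP), unreadable: str = "drop"):
    """Fleiss' kappa for an epochs x raters label matrix.

    ``unreadable``: ``"drop"`` removes epochs containing a U label (default);
    ``"category"`` keeps U as a rating category of its own.  Returns 1.0 for
    the degenerate all-one-category case (chance agreement is 1 there and the
    usual formula is 0/0).
    """
    ratings = np.asarray(ratings, dtype="U1")
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be epochs x raters with >= 2 raters")
    cats = list(categories)
    if unreadable == "drop":
        keep = ~np.any(ratings == UNREADABLE, axis=1)
        ratings = ratings[keep]
    elif unreadable == "category":
        if UNREADABLE not in cats:
            cats = cats + [UNREADABLE]
    else:
        raise ValueError(f"unknown unreadable policy {unreadable!r}")
    if ratings.shape[0] == 0:
        raise ValueError("no rateable epochs left")
    bad = set(ratings.ravel()) - set(cats)
    if bad:
        raise ValueError(f"labels outside the category set: {sorted(bad)}")
    counts = np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1)
    marginals = counts.sum(axis=0) / counts.sum()
    if np.max(marginals) >= 1.0:  # every rating in one category
        import warnings

        warnings.warn(
            "degenerate ratings: one category everywhere; kappa = 1 by convention",
            stacklevel=2,
        )
        return 1.0
    return float(_sm_fleiss_kappa(counts, method="fleiss"))


_TABLE1_RESOURCE = "table1_annotations.tsv"


def table1_grid() -> AnnotationGrid:
    """The packaged 12-subject demonstration grid.

    An awake first epoch, then sleep with unreadable (N) and relapse epochs
    distributed so that exactly the first nine subjects satisfy the default
    7-epoch inclusion window.
    """
    with resources.files("alpsim").joinpath("data", _TABLE1_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).set_index("subject")
    return AnnotationGrid.from_frame(df)


def simulate_ratings(
    consensus_row, n_raters: int = 3, disagreement_rate: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Synthesize per-rater labels consistent with a consensus label row.

    Each epoch starts from its consensus state replicated across raters; with
    probability ``disagreement_rate`` a single rater flips to the opposite
    state, preserving the majority.  Epochs labelled N get one of each of
    {0, 1, U} (no majority).  Used to build rater-level fixtures for
    agreement statistics.
    """
    rng = np.random.default_rng(seed)
    row = np.asarray(consensus_row, dtype="U1")
    out = np.empty((row.size, n_raters), dtype="U1")
    for i, lab in enumerate(row):
        if lab == NO_CONSENSUS:
            trio = np.array([AWAKE, SLEEP, UNREADABLE])
            rng.shuffle(trio)
            out[i] = np.resize(trio, n_raters)
        else:
            out[i] = lab
            if n_raters >= 3 and rng.random() < disagreement_rate:
                flip = rng.integers(n_raters)
                out[i, flip] = SLEEP if lab == AWAKE else AWAKE
    return out
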