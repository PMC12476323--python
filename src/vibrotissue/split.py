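"""Recording-grouped K-fold splitting.

Segments cut from one physical recording are strongly correlated; letting
them straddle the train/test boundary inflates test metrics (data leakage).
The splitter therefore assigns whole *recordings* to folds: per-fold class
quotas are computed from the corpus class totals, then recordings are drawn
in seeded random order and assigned — atomically — to the fold with the most
remaining quota for their class. Fold sizes can only be balanced up to the
size of the largest single recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CorpusManifest


class SplitInfeasibleError(ValueError):
    """A class has fewer recordings than folds — every fold needs each class."""


@dataclass
class FoldAssignment:
    """A partition of recording ids into ``n_folds`` folds."""

    n_folds: int
    fold_of_recording: dict[str, int]
    per_fold_class_counts: pd.DataFrame  # index fold, columns class_id, values segment counts
    seed: int

    def recordings_in_fold(self, fold: int) -> list[str]:
        return [r for r, f in self.fold_of_recording.items() if f == fold]

    def segment_folds(self, manifest: CorpusManifest) -> np.ndarray:
        """Fold index of every manifest row."""
        return manifest.df["recording_id"].map(self.fold_of_recording).to_numpy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_of_recording": self.fold_of_recording,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, manifest: CorpusManifest | None = None) -> "FoldAssignment":
        payload = json.loads(Path(path).read_text())
        counts = pd.DataFrame()
        if manifest is not None:
            df = manifest.df.copy()
            df["fold"] = df["recording_id"].map(payload["fold_of_recording"])
            counts = df.pivot_table(
                index="fold", columns="class_id", values="segment_index",
                aggfunc="count", fill_value=0,
            )
        return cls(
            n_folds=int(payload["n_folds"]),
            fold_of_recording={str(k): int(v) for k, v in payload["fold_of_recording"].items()},
            per_fold_class_counts=counts,
            seed=int(payload["seed"]),
        )


def grouped_kfold(manifest: CorpusManifest, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign whole recordings to ``n_folds`` folds, balancing class quotas.

    Per-fold quotas are ``class_total // n_folds`` with the remainder spread
    over the lowest-indexed folds. Recordings are shuffled (seeded) within
    each class and each is assigned to the fold with the largest remaining
    quota for its class (lowest fold index on ties) — overshooting a quota is
    allowed at the tail, where whole-recording atomicity makes exact balance
    impossible.

    Raises
    ------
    SplitInfeasibleError
        If any class has fewer recordings than folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    df = manifest.df
    rng = np.random.default_rng(seed)

    rec_sizes = df.groupby("recording_id").size()
    rec_class = df.groupby("recording_id")["class_id"].first()
    fold_of: dict[str, int] = {}
    quota: dict[int, np.ndarray] = {}
    for cid, group in rec_class.groupby(rec_class):
        n_recs = len(group)
        if n_recs < n_folds:
            raise SplitInfeasibleError(
                f"class {cid} has only {n_recs} recordings for {n_folds} folds"
            )
        total = int(rec_sizes[group.index].sum())
        base, rem = divmod(total, n_folds)
        quota[cid] = np.array([base + (1 if k < rem else 0) for k in range(n_folds)], dtype=float)

    for cid in sorted(quota):
        recs = sorted(rec_class.index[rec_class == cid])
        order = rng.permutation(len(recs))
        for i in order:
            rid = recs[i]
            k = int(np.argmax(quota[cid]))  # argmax takes the lowest index on ties
            fold_of[rid] = k
            quota[cid][k] -= rec_sizes[rid]

    dfa = df.copy()
    dfa["fold"] = dfa["recording_id"].map(fold_of)
    counts = dfa.pivot_table(
        index="fold", columns="class_id", values="segment_index",
        aggfunc="count", fill_value=0,
    ).reindex(range(n_folds), fill_value=0)
    if (counts.sum(axis=1) == 0).any():
        # cannot happen with >= n_folds recordings per class and max-quota assignment,
        # but the contract forbids empty folds outright
        raise SplitInfeasibleError("a fold received no recordings")
    return FoldAssignment(n_folds=n_folds, fold_of_recording=fold_of,
                          per_fold_class_counts=counts, seed=seed)


@dataclass
class LeakageReport:
    passed: bool
    violating_recording_ids: list[str]


def verify_no_leakage(
    assignment: FoldAssignment | dict[str, int] | np.ndarray,
    manifest: CorpusManifest,
) -> LeakageReport:
    """Check that no recording's segments land in more than one fold.

    ``assignment`` may be a :class:`FoldAssignment`, a recording→fold mapping,
    or a per-segment fold array aligned with the manifest rows (the form a
    naive segment-level split produces).
    """
    df = manifest.df
    if isinstance(assignment, FoldAssignment):
        missing = set(df["recording_id"]) - set(assignment.fold_of_recording)
        if missing:
            raise ValueError(f"assignment does not cover recordings: {sorted(missing)[:5]}")
        seg_folds = assignment.segment_folds(manifest)
    elif isinstance(assignment, dict):
        missing = set(df["recording_id"]) - set(assignment)
        if missing:
            raise ValueError(f"assignment does not cover recordings: {sorted(missing)[:5]}")
        seg_folds = df["recording_id"].map(assignment).to_numpy()
    else:
        seg_folds = np.asarray(assignment)
        if seg_folds.shape[0] != len(df):
            raise ValueError("per-segment fold array length does not match the manifest")
    tmp = pd.DataFrame({"recording_id": df["recording_id"].to_numpy(), "fold": seg_folds})
    nfolds_per_rec = tmp.groupby("recording_id")["fold"].nunique()
    violators = sorted(nfolds_per_rec.index[nfolds_per_rec > 1])
    return LeakageReport(passed=not violators, violating_recording_ids=violators)
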