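"""Containers and file I/O for drug–target interaction (DTI) data.

A DTI dataset is a binary interaction matrix ``M`` (drugs × targets)
together with a drug–drug similarity matrix ``DS`` and a target–target
similarity matrix ``TS``, all aligned to explicit string identifier
lists.  Two on-disk dialects are supported for the interaction matrix:

* ``yamanishi_tsv`` — a rectangular labeled table: header row of target
  IDs, first column of drug IDs, tab-separated 0/1 cells (the layout of
  the public nuclear-receptor / GPCR / ion-channel / enzyme gold-standard
  files).
* ``pair_list`` — a two-column ``drug_id<sep>target_id`` file of positive
  pairs (DrugBank-style); every listed drug and target becomes a row or
  column, and unlisted combinations default to 0.

Similarity tables are labeled square matrices.  On load they are
reindexed to the dataset's ID order, symmetrized as ``(S + S.T) / 2``,
clipped to ``[0, 1]`` and given a unit diagonal, so that downstream code
can rely on a well-formed kernel-like matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DTIDataset",
    "InteractionTable",
    "PredictionMatrix",
    "read_interaction_table",
    "write_interaction_table",
    "read_similarity_table",
    "write_similarity_table",
    "load_dataset",
    "dataset_stats",
    "stats_from_counts",
]

_SYM_TOL = 1e-8


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


def _check_similarity(S: np.ndarray, n: int, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.max(np.abs(S - S.T)) > _SYM_TOL:
        raise ValueError(f"{name} is not symmetric within {_SYM_TOL}")
    if S.min() < -_SYM_TOL or S.max() > 1 + _SYM_TOL:
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if np.max(np.abs(np.diag(S) - 1.0)) > _SYM_TOL:
        raise ValueError(f"{name} diagonal must be 1")
    return S


@dataclass(frozen=True)
class DTIDataset:
    """Interaction matrix plus the two similarity matrices, ID-aligned.

    Invariants (checked on construction): ``M`` is exactly 0/1 with shape
    ``(len(drug_ids), len(target_ids))``; ``DS`` and ``TS`` are symmetric
    within 1e-8, valued in ``[0, 1]`` and have unit diagonals.
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    M: np.ndarray
    DS: np.ndarray
    TS: np.ndarray

    def __post_init__(self) -> None:
        d, t = len(self.drug_ids), len(self.target_ids)
        if len(set(self.drug_ids)) != d:
            raise ValueError("duplicate drug IDs")
        if len(set(self.target_ids)) != t:
            raise ValueError("duplicate target IDs")
        M = np.asarray(self.M)
        if M.shape != (d, t):
            raise ValueError(f"M must be {d}x{t}, got {M.shape}")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("M entries must be exactly 0 or 1")
        object.__setattr__(self, "M", M.astype(np.int8))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))
        object.__setattr__(self, "DS", _check_similarity(self.DS, d, "DS"))
        object.__setattr__(self, "TS", _check_similarity(self.TS, t, "TS"))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def observed_set(self) -> set[tuple[int, int]]:
        """Index pairs (i, j) of validated interactions (M_ij = 1)."""
        return set(zip(*np.nonzero(self.M)))


@dataclass(frozen=True)
class InteractionTable:
    """Interaction matrix with its ID lists, before similarities attach."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    M: np.ndarray


@dataclass(frozen=True)
class PredictionMatrix:
    """Completed score matrix with ID alignment to the source dataset."""

    X: np.ndarray
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError("X shape does not match ID lists")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite scores")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))

    def ranking(self) -> list[tuple[str, str, float]]:
        """All pairs sorted by descending score, ties by (drug, target) ID."""
        d, t = self.X.shape
        entries = [
            (self.drug_ids[i], self.target_ids[j], float(self.X[i, j]))
            for i in range(d)
            for j in range(t)
        ]
        entries.sort(key=lambda e: (-e[2], e[0], e[1]))
        return entries


def _dedupe_preserve(ids: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in ids:
        seen.setdefault(x, None)
    return list(seen)


def read_interaction_table(path: str | Path, dialect: str = "yamanishi_tsv") -> InteractionTable:
    """Read a binary interaction matrix in one of the supported dialects.

    ID order is defined by first appearance in the file.  Duplicate rows
    in ``yamanishi_tsv`` are collapsed when identical and rejected when
    conflicting; duplicate pairs in ``pair_list`` collapse to one 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty interaction file: {path}")

    if dialect == "yamanishi_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.empty:
            raise FormatError(f"no data rows in {path}")
        target_ids = [str(c) for c in df.columns]
        rows: dict[str, np.ndarray] = {}
        order: list[str] = []
        for drug, raw in zip(df.index.astype(str), df.to_numpy()):
            vals = np.empty(len(raw), dtype=np.int8)
            for j, cell in enumerate(raw):
                text = str(cell).strip()
                if text not in ("0", "1"):
                    raise FormatError(
                        f"non-binary cell {text!r} at row {drug!r}, column {target_ids[j]!r}"
                    )
                vals[j] = int(text)
            if drug in rows:
                if not np.array_equal(rows[drug], vals):
                    raise FormatError(f"duplicate drug ID {drug!r} with conflicting rows")
            else:
                rows[drug] = vals
                order.append(drug)
        M = np.vstack([rows[d] for d in order])
        return InteractionTable(tuple(order), tuple(target_ids), M)

    if dialect == "pair_list":
        df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise FormatError(f"pair list {path} must have two columns")
        pairs = [(str(r[0]).strip(), str(r[1]).strip()) for r in df.itertuples(index=False)]
        drug_ids = _dedupe_preserve(p[0] for p in pairs)
        target_ids = _dedupe_preserve(p[1] for p in pairs)
        di = {x: i for i, x in enumerate(drug_ids)}
        ti = {x: j for j, x in enumerate(target_ids)}
        M = np.zeros((len(drug_ids), len(target_ids)), dtype=np.int8)
        for a, b in pairs:
            M[di[a], ti[b]] = 1
        return InteractionTable(tuple(drug_ids), tuple(target_ids), M)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_interaction_table(table: InteractionTable | DTIDataset, path: str | Path) -> None:
    """Write an interaction matrix in the ``yamanishi_tsv`` dialect."""
    df = pd.DataFrame(np.asarray(table.M, dtype=int),
                      index=list(table.drug_ids), columns=list(table.target_ids))
    df.to_csv(path, sep="\t", index_label="drug")


def read_similarity_table(path: str | Path, expected_ids: Sequence[str]) -> np.ndarray:
    """Read a labeled square similarity matrix, reindexed to ``expected_ids``.

    The file's ID set must be a superset of ``expected_ids``.  The returned
    matrix is symmetrized as ``(S + S.T) / 2``, clipped to ``[0, 1]`` and
    has its diagonal forced to 1, so it satisfies the ``DTIDataset``
    similarity invariants unconditionally.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [i for i in expected_ids if i not in df.index or i not in df.columns]
    if missing:
        raise FormatError(f"similarity table {path} is missing IDs: {missing}")
    sub = df.loc[list(expected_ids), list(expected_ids)].to_numpy(dtype=float)
    if np.isnan(sub).any():
        i, j = np.argwhere(np.isnan(sub))[0]
        raise FormatError(
            f"NaN similarity at ({expected_ids[i]!r}, {expected_ids[j]!r}) in {path}"
        )
    S = (sub + sub.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def write_similarity_table(S: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(np.asarray(S, dtype=float), index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def load_dataset(
    interactions: str | Path,
    drug_similarity: str | Path,
    target_similarity: str | Path,
    dialect: str = "yamanishi_tsv",
) -> DTIDataset:
    """Assemble a full dataset from the three files."""
    table = read_interaction_table(interactions, dialect=dialect)
    DS = read_similarity_table(drug_similarity, table.drug_ids)
    TS = read_similarity_table(target_similarity, table.target_ids)
    return DTIDataset(table.drug_ids, table.target_ids, table.M, DS, TS)


def _round2(x: float) -> float:
    # half-away-from-zero, 2 decimals (matches conventional table printing)
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


def stats_from_counts(n_drugs: int, n_targets: int, n_interactions: int) -> dict[str, float]:
    """Summary statistics derivable from the three counts alone.

    Sparsity is ``100 * (1 - |E| / (d * t))``; the per-drug and per-target
    averages are ``|E| / d`` and ``|E| / t``.  All reported to 2 decimals,
    half-away-from-zero.
    """
    if n_drugs <= 0 or n_targets <= 0:
        raise ValueError("dataset must have at least one drug and one target")
    d, t, e = n_drugs, n_targets, n_interactions
    return {
        "n_drugs": d,
        "n_targets": t,
        "n_interactions": e,
        "avg_drugs_per_target": _round2(e / t),
        "avg_targets_per_drug": _round2(e / d),
        "sparsity_pct": _round2(100.0 * (1.0 - e / (d * t))),
    }


def dataset_stats(ds: DTIDataset | InteractionTable) -> dict[str, float]:
    """Summary statistics of an interaction matrix.

    Extends :func:`stats_from_counts` with the percentage of drugs having
    exactly one interaction and likewise for targets.
    """
    M = np.asarray(ds.M)
    d, t = M.shape
    stats = stats_from_counts(d, t, int(M.sum()))
    row_deg = M.sum(axis=1)
    col_deg = M.sum(axis=0)
    stats["pct_drugs_single_interaction"] = _round2(100.0 * float(np.mean(row_deg == 1)))
    stats["pct_targets_single_interaction"] = _round2(100.0 * float(np.mean(col_deg == 1)))
    return stats
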