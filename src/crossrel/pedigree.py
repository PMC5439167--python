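"""Pedigree storage, numerator relationship blocks and inbreeding.

The additive (numerator) relationship matrix A is computed by the tabular
method, swept one pedigree level at a time so that only animals still
needed (targets and parents of later animals) are held in memory.  This
keeps arbitrary rectangular A blocks between candidate and reference sets
tractable for deep simulated pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "AMatrixBlock", "build_a_block", "mean_inbreeding"]

UNKNOWN = 0  # parent code for "unknown": treated as an unrelated founder


@dataclass
class Pedigree:
    """Pedigree records: animal, sire, dam (0 = unknown), sex, generation,
    population label.  Parents must precede offspring (no cycles)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        ids = self.records["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate animal ids in pedigree")
        self._index = {int(a): i for i, a in enumerate(ids)}
        self._sire = self.records["sire"].to_numpy(dtype=np.int64)
        self._dam = self.records["dam"].to_numpy(dtype=np.int64)
        self._ids = ids.astype(np.int64)
        self._levels = self._topological_levels()

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path))

    def _topological_levels(self) -> np.ndarray:
        """Level = 1 + max(level of parents); founders are level 0.

        Raises on a cyclic pedigree or a parent that is its own ancestor.
        """
        n = len(self._ids)
        levels = np.full(n, -1, dtype=np.int64)
        # iterative DFS with cycle detection
        for start in range(n):
            if levels[start] >= 0:
                continue
            stack = [(start, 0)]
            onpath = set()
            while stack:
                node, stage = stack.pop()
                if stage == 0:
                    if levels[node] >= 0:
                        continue
                    if node in onpath:
                        raise ValueError("cyclic pedigree: an animal is its own ancestor")
                    onpath.add(node)
                    stack.append((node, 1))
                    for parent in (self._sire[node], self._dam[node]):
                        if parent != UNKNOWN:
                            if parent not in self._index:
                                raise ValueError(f"parent {parent} not in pedigree")
                            pidx = self._index[int(parent)]
                            if levels[pidx] < 0:
                                stack.append((pidx, 0))
                else:
                    lv = 0
                    for parent in (self._sire[node], self._dam[node]):
                        if parent != UNKNOWN:
                            pidx = self._index[int(parent)]
                            if levels[pidx] < 0:
                                raise ValueError(
                                    "cyclic pedigree: an animal is its own ancestor"
                                )
                            lv = max(lv, levels[pidx] + 1)
                    levels[node] = lv
                    onpath.discard(node)
        return levels

    def __len__(self) -> int:
        return len(self._ids)

    def contains(self, ids) -> bool:
        return all(int(i) in self._index for i in ids)


@dataclass
class AMatrixBlock:
    """A requested rows x cols slice of A plus per-animal inbreeding F."""

    values: np.ndarray
    row_ids: np.ndarray
    col_ids: np.ndarray
    inbreeding: dict = field(default_factory=dict)  # id -> F


def _ancestor_closure(ped: Pedigree, targets: np.ndarray) -> np.ndarray:
    """Indices of targets plus all their ancestors."""
    seen = set()
    stack = [ped._index[int(t)] for t in targets]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        for parent in (ped._sire[node], ped._dam[node]):
            if parent != UNKNOWN:
                stack.append(ped._index[int(parent)])
    return np.fromiter(seen, dtype=np.int64)


def build_a_block(ped: Pedigree, rows, cols) -> AMatrixBlock:
    """Numerator relationship block A[rows, cols] and inbreeding of targets.

    Founders (and unknown parents) are unrelated and non-inbred; every other
    relationship follows a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)}) and
    a_ii = 1 + 0.5 a_{sire(i),dam(i)}.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    targets = np.unique(np.concatenate([rows, cols]))
    for t in targets:
        if int(t) not in ped._index:
            raise KeyError(f"animal {t} not in pedigree")

    closure = _ancestor_closure(ped, targets)
    levels = ped._levels[closure]
    order = np.argsort(levels, kind="stable")
    closure = closure[order]
    levels = levels[order]

    target_set = set(int(ped._ids[i]) for i in targets_idx(ped, targets))
    # last level at which each closure animal is still needed
    last_needed = {}
    max_level = int(levels.max()) if len(levels) else 0
    for node, lv in zip(closure, levels):
        aid = int(ped._ids[node])
        last_needed[aid] = max_level if aid in target_set else int(lv)
    for node in closure:
        for parent in (ped._sire[node], ped._dam[node]):
            if parent != UNKNOWN:
                p = int(parent)
                last_needed[p] = max(last_needed.get(p, -1), int(ped._levels[node]))

    active_ids: list[int] = []
    active_pos: dict[int, int] = {}
    A = np.zeros((0, 0))
    F: dict[int, float] = {}

    for lv in range(max_level + 1):
        new_nodes = closure[levels == lv]
        if len(new_nodes) == 0:
            continue
        n_new = len(new_nodes)
        n_act = len(active_ids)
        # parent incidence into the active set
        P = np.zeros((n_new, n_act))
        f_new = np.zeros(n_new)
        for r, node in enumerate(new_nodes):
            s, d = int(ped._sire[node]), int(ped._dam[node])
            if s != UNKNOWN:
                P[r, active_pos[s]] += 0.5
            if d != UNKNOWN:
                P[r, active_pos[d]] += 0.5
            if s != UNKNOWN and d != UNKNOWN:
                f_new[r] = 0.5 * A[active_pos[s], active_pos[d]]
        cross = P @ A  # new x active
        within = P @ A @ P.T
        np.fill_diagonal(within, 1.0 + f_new)
        for r, node in enumerate(new_nodes):
            F[int(ped._ids[node])] = float(f_new[r])

        # grow the active matrix, then drop animals no longer needed
        n_total = n_act + n_new
        A_next = np.empty((n_total, n_total))
        A_next[:n_act, :n_act] = A
        A_next[n_act:, :n_act] = cross
        A_next[:n_act, n_act:] = cross.T
        A_next[n_act:, n_act:] = within
        ids_next = active_ids + [int(ped._ids[node]) for node in new_nodes]
        keep = [i for i, aid in enumerate(ids_next) if last_needed.get(aid, -1) > lv
                or aid in target_set]
        A = A_next[np.ix_(keep, keep)]
        active_ids = [ids_next[i] for i in keep]
        active_pos = {aid: i for i, aid in enumerate(active_ids)}

    ridx = [active_pos[int(i)] for i in rows]
    cidx = [active_pos[int(i)] for i in cols]
    values = A[np.ix_(ridx, cidx)]
    inbreeding = {int(i): F[int(i)] for i in targets}
    return AMatrixBlock(values=values, row_ids=rows, col_ids=cols, inbreeding=inbreeding)


def targets_idx(ped: Pedigree, targets: np.ndarray) -> np.ndarray:
    return np.array([ped._index[int(t)] for t in targets], dtype=np.int64)


def mean_inbreeding(ped: Pedigree, ids) -> float:
    """Mean pedigree inbreeding coefficient over ``ids``."""
    ids = np.asarray(ids, dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("empty id set")
    block = build_a_block(ped, ids[:1], ids[:1]) if len(ids) == 1 else build_a_block(
        ped, ids, ids[:1]
    )
    return float(np.mean([block.inbreeding[int(i)] for i in ids]))
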