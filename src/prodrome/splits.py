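"""Day-block construction and the four-way data split.

Each participant's day sequence is cut into equal-length nonoverlapping
blocks.  Healthy-only blocks feed the training/validation sets (H_R / H_CV);
blocks touching a near-relapse window form the mixed pool that a stratified
Monte Carlo procedure repeatedly partitions into N_CV / N_T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import LABEL_DRH, LABEL_NR30

SWEEP_PCTS = (0, 20, 40, 60, 80)


@dataclass(frozen=True)
class Block:
    participant_id: str
    index: int
    dates: tuple
    labels: tuple
    is_remainder: bool = False

    @property
    def n_nr30(self) -> int:
        return sum(1 for l in self.labels if l == LABEL_NR30)

    @property
    def all_drh(self) -> bool:
        return all(l == LABEL_DRH for l in self.labels)

    def key(self):
        return (self.participant_id, self.index)


@dataclass
class DataSplits:
    h_r: list = field(default_factory=list)
    h_cv: list = field(default_factory=list)
    n_pool: list = field(default_factory=list)
    pct_drh_in_train: int = 80
    block_len_days: int = 5
    seed: int = 0

    def assert_purity(self):
        for b in self.h_r + self.h_cv:
            if b.n_nr30 or not b.all_drh:
                raise AssertionError(f"non-DRH block {b.key()} leaked into H sets")


def make_blocks(dates, labels, block_len_days: int = 5, participant_id: str = "?") -> list[Block]:
    """Cut one participant's day sequence into consecutive equal blocks; a
    final short remainder becomes its own (flagged) block."""
    if block_len_days < 1:
        raise ValueError("block_len_days must be >= 1")
    dates = list(dates)
    labels = list(labels)
    if len(dates) != len(labels):
        raise ValueError("dates and labels must align")
    if not dates:
        return []
    if len(dates) < block_len_days:
        warnings.warn("fewer days than one block; emitting a single short block", stacklevel=2)
    blocks = []
    n_full = len(dates) // block_len_days
    for i in range(n_full):
        sl = slice(i * block_len_days, (i + 1) * block_len_days)
        blocks.append(
            Block(participant_id, i, tuple(dates[sl]), tuple(labels[sl]), False)
        )
    rem = len(dates) - n_full * block_len_days
    if rem:
        sl = slice(n_full * block_len_days, len(dates))
        blocks.append(
            Block(participant_id, n_full, tuple(dates[sl]), tuple(labels[sl]), n_full > 0)
        )
    return blocks


def blocks_for_participant(pid: str, day_labels: pd.Series, block_len_days: int = 5) -> list[Block]:
    return make_blocks(
        list(day_labels.index), list(day_labels.to_numpy()), block_len_days, participant_id=pid
    )


def assign_splits(
    blocks: list[Block],
    pct_drh_in_train: int,
    seed: int,
    relapse_participants: set,
    block_len_days: int = 5,
    allow_any_pct: bool = False,
) -> DataSplits:
    """Route blocks into H_R / H_CV / N_pool.

    Relapse participants: ``pct`` percent of their healthy-only blocks are
    sampled into the H sets (then 80/20 H_R/H_CV per participant); everything
    else of theirs — NR30-touching blocks and unsampled healthy blocks — goes
    to the mixed pool.  Nonrelapse participants' blocks all go to the H sets
    at 80/20.  A remainder block follows its participant's final full block.
    """
    if pct_drh_in_train not in SWEEP_PCTS and not allow_any_pct:
        raise ValueError(f"pct_drh_in_train must be one of {SWEEP_PCTS}")
    rng = np.random.default_rng(seed)
    splits = DataSplits(pct_drh_in_train=pct_drh_in_train, block_len_days=block_len_days, seed=seed)

    by_pid: dict = {}
    for b in blocks:
        by_pid.setdefault(b.participant_id, []).append(b)
    for pid in sorted(by_pid):
        pblocks = sorted(by_pid[pid], key=lambda b: b.index)
        remainder = None
        if pblocks and pblocks[-1].is_remainder and len(pblocks) > 1:
            remainder = pblocks.pop()
        assignment: dict = {}
        if pid in relapse_participants:
            healthy = [b for b in pblocks if b.all_drh]
            mixed = [b for b in pblocks if not b.all_drh]
            n_h = int(round(pct_drh_in_train / 100.0 * len(healthy)))
            chosen = set(
                rng.choice(len(healthy), size=n_h, replace=False).tolist()
            ) if n_h else set()
            h_blocks = [b for i, b in enumerate(healthy) if i in chosen]
            for b in mixed + [b for i, b in enumerate(healthy) if i not in chosen]:
                assignment[b.key()] = "n_pool"
            _split_h(h_blocks, rng, assignment)
        else:
            _split_h(pblocks, rng, assignment)
        if remainder is not None:
            tail_set = assignment[pblocks[-1].key()]
            if not remainder.all_drh and tail_set in ("h_r", "h_cv"):
                tail_set = "n_pool"
            assignment[remainder.key()] = tail_set
            pblocks.append(remainder)
        for b in pblocks:
            getattr(splits, assignment[b.key()]).append(b)
    splits.assert_purity()
    return splits


def _split_h(h_blocks, rng, assignment):
    n = len(h_blocks)
    if n == 0:
        return
    n_r = int(round(0.8 * n))
    chosen = set(rng.choice(n, size=n_r, replace=False).tolist()) if n_r else set()
    for i, b in enumerate(h_blocks):
        assignment[b.key()] = "h_r" if i in chosen else "h_cv"


def monte_carlo_partition(
    n_pool: list[Block], iteration: int, base_seed: int
) -> tuple[list[Block], list[Block]]:
    """Split the mixed pool into N_CV / N_T for one Monte Carlo iteration.

    Per participant, NR30-bearing blocks are balanced greedily by NR30 day
    count (difference bounded by one block); healthy blocks split 50/50.
    Fully deterministic in (base_seed, iteration).
    """
    if not n_pool:
        raise ValueError("N_pool is empty")
    rng = np.random.default_rng([base_seed, iteration])
    n_cv: list[Block] = []
    n_t: list[Block] = []
    by_pid: dict = {}
    for b in n_pool:
        by_pid.setdefault(b.participant_id, []).append(b)
    for pid in sorted(by_pid):
        pblocks = by_pid[pid]
        nr = [b for b in pblocks if b.n_nr30 > 0]
        drh = [b for b in pblocks if b.n_nr30 == 0]
        if len(nr) == 1:
            warnings.warn(
                f"{pid} has a single NR30 block; alternating across iterations", stacklevel=2
            )
            (n_cv if iteration % 2 == 0 else n_t).append(nr[0])
        else:
            order = sorted(
                range(len(nr)), key=lambda i: (-nr[i].n_nr30, rng.random())
            )
            tot = [0, 0]
            sides = [n_cv, n_t]
            for i in order:
                side = 0 if tot[0] < tot[1] else 1 if tot[1] < tot[0] else int(rng.integers(2))
                sides[side].append(nr[i])
                tot[side] += nr[i].n_nr30
        perm = rng.permutation(len(drh))
        half = len(drh) // 2 + (len(drh) % 2) * int(rng.integers(2))
        for j, i in enumerate(perm):
            (n_cv if j < half else n_t).append(drh[i])
    return n_cv, n_t


def block_hours(blocks: list[Block], values: pd.DataFrame) -> pd.DataFrame:
    """Select the hourly rows of a feature matrix covered by ``blocks``."""
    keys = set()
    for b in blocks:
        for d in b.dates:
            keys.add((b.participant_id, d))
    idx = pd.MultiIndex.from_frame(values[["participant_id", "date"]])
    return values[idx.isin(keys)]


def manifest(splits: DataSplits) -> dict:
    return {
        name: sorted([f"{b.participant_id}:{b.index}" for b in getattr(splits, name)])
        for name in ("h_r", "h_cv", "n_pool")
    }
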