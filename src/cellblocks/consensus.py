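"""Consensus over an ensemble of fitted models: per-cell marginals and labels.

Every model's hierarchy is projected to cell level at each depth, relabelled
against the best (lowest-sigma) model by maximum-overlap matching, and the
marginal probability of cell c in block r is the fraction of models that
place c in (aligned) block r.  Models shallower than the requested level
contribute their top level (all cells in one block).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .sbm import NestedState, _compact

__all__ = ["ConsensusResult", "align_partitions", "build_consensus"]


def align_partitions(
    reference: np.ndarray, others: list[np.ndarray]
) -> list[np.ndarray]:
    """Relabel each partition to maximise overlap with the reference.

    The Hungarian algorithm is run on the contingency table; blocks left
    unmatched (when a partition has more blocks than the reference) receive
    fresh labels above the reference's range.
    """
    reference = _compact(np.asarray(reference))
    out = []
    n_ref = int(reference.max()) + 1
    for other in others:
        other = _compact(np.asarray(other))
        if other.size != reference.size:
            raise ValueError("partitions cover different numbers of cells")
        n_oth = int(other.max()) + 1
        cont = np.zeros((n_oth, n_ref), dtype=np.int64)
        np.add.at(cont, (other, reference), 1)
        rows, cols = linear_sum_assignment(-cont)
        mapping = -np.ones(n_oth, dtype=np.int64)
        mapping[rows] = cols
        nxt = n_ref
        for r in range(n_oth):
            if mapping[r] < 0:
                mapping[r] = nxt
                nxt += 1
        out.append(mapping[other])
    return out


@dataclass
class ConsensusResult:
    """Per-level marginals (cells x blocks, row-stochastic), argmax labels,
    hierarchy-nested labels and provenance."""

    marginals: list[np.ndarray]
    labels: list[np.ndarray]
    nested_labels: list[np.ndarray]
    block_counts: list[int]
    n_models: int
    seed: int | None = None

    @property
    def n_levels(self) -> int:
        return len(self.marginals)

    def write(self, outdir: str | Path, cell_ids: list[str] | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = self.labels[0].size
        idx = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
        for l, M in enumerate(self.marginals):
            pd.DataFrame(M, index=idx).to_csv(outdir / f"marginals_level{l}.csv")
        pd.DataFrame(
            {f"level_{l}": lab for l, lab in enumerate(self.labels)}, index=idx
        ).to_csv(outdir / "consensus_labels.tsv", sep="\t", index_label="cell")


def build_consensus(
    ensemble: list[NestedState], seed: int | None = None
) -> ConsensusResult:
    """Aggregate an ensemble (sorted or not) into a consensus.

    The best-sigma state is the alignment reference at every level; the
    consensus label is the argmax marginal (ties broken toward the smaller
    block index).  ``nested_labels`` re-maps the level-0 consensus through
    the best state's hierarchy so that labels are nested across levels by
    construction.
    """
    if not ensemble:
        raise ValueError("consensus needs at least one model")
    best = min(ensemble, key=lambda s: s.sigma)
    n_cells = best.graph.n_nodes
    n_levels = max(s.n_levels for s in ensemble)

    marginals: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    counts: list[int] = []
    for level in range(n_levels):
        ref = best.project(min(level, best.n_levels - 1))
        projected = [
            s.project(min(level, s.n_levels - 1)) for s in ensemble
        ]
        aligned = align_partitions(ref, projected)
        n_blocks = max(int(a.max()) + 1 for a in aligned)
        M = np.zeros((n_cells, n_blocks))
        for a in aligned:
            M[np.arange(n_cells), a] += 1.0
        M /= len(ensemble)
        marginals.append(M)
        labels.append(np.argmax(M, axis=1))  # argmax takes the first (lowest) index on ties
        counts.append(n_blocks)

    nested = [labels[0].copy()]
    acc = np.arange(int(best.project(0).max()) + 1, dtype=np.int64)
    for level in range(1, n_levels):
        if level < best.n_levels:
            acc = best.partition.levels[level][acc]
        lab0 = np.clip(labels[0], 0, acc.size - 1)
        nested.append(acc[lab0])

    return ConsensusResult(
        marginals=marginals,
        labels=labels,
        nested_labels=nested,
        block_counts=counts,
        n_models=len(ensemble),
        seed=seed,
    )
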