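"""The adaptive density-modularity (ADM) clustering algorithm.

The procedure, starting from one module per protein:

1. *Sweep*: visit every node in a seeded random order; compare its internal
   closely associated degree R_in against its best external score R_out and
   relocate the node when R_in < R_out.  Scores are computed live, so each
   decision sees the effect of every earlier accepted move.
2. *Stabilize*: repeat sweeps until a pass makes no move, then record the
   density modularity D of the stabilized partition as a snapshot.
3. *Merge*: evaluate the proportional merge gain for every pair of modules
   joined by at least one edge, apply the best merge (maximum increment or
   minimum reduction), and go back to 1 so nodes can escape merged modules.
4. When no connected pair remains, return the recorded snapshot with the
   largest D, together with the trajectory of all snapshots and the
   module set surviving the minimum-size filter.

The only source of randomness is the per-sweep node visiting order, so a
(seed, network) pair fully determines the run.  The multi-restart protocol
repeats the run with seeds seed, seed+1, ... and keeps the restart whose
best snapshot has the greatest D.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .graph_io import ModuleSet, PPINetwork
from .density_modularity import (
    CAD_FORMS,
    Partition,
    external_cad,
    internal_cad,
    merge_gain,
    partition_density,
)

__all__ = [
    "ADMConfig",
    "ADMResult",
    "TrajectoryRecord",
    "initialize_singletons",
    "sweep",
    "stabilize",
    "best_pair_merge",
    "filter_modules",
    "run_adm",
    "multi_restart",
]


@dataclass(frozen=True)
class ADMConfig:
    """Tunables of an ADM run.

    Parameters
    ----------
    seed
        Base RNG seed; restart ``i`` uses ``seed + i``.
    restarts
        Number of independent runs in the multi-restart protocol
        (default 20, the published protocol).
    min_module_size
        Minimum protein count for a reported module (default 3, matching
        the reference-complex filter).
    cad_form
        ``"consistent"`` (default) scores R_in with the same functional
        form as R_out; ``"eq5_as_printed"`` uses the published final
        simplification of the internal score instead.
    max_sweeps
        Safety cap on move-making sweeps per stabilization.
    """

    seed: int = 0
    restarts: int = 20
    min_module_size: int = 3
    cad_form: str = "consistent"
    max_sweeps: int = 1000

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.cad_form not in CAD_FORMS:
            raise ValueError(f"unknown cad_form {self.cad_form!r}")


@dataclass(frozen=True)
class TrajectoryRecord:
    """One recorded (stabilized) state of a run."""

    restart: int
    stage: str
    n_modules: int
    D: float


@dataclass
class ADMResult:
    """Outcome of one ADM run (or of the winning restart).

    ``best_membership`` is the node -> module-id map of the snapshot with
    maximum density modularity; ``best_partition`` rebuilds it as a live
    :class:`Partition`.  ``trajectory`` lists every recorded snapshot;
    ``restart_scores`` holds the per-restart best D values.
    """

    network: PPINetwork
    best_membership: dict[str, int]
    best_D: float
    trajectory: list[TrajectoryRecord]
    filtered_modules: ModuleSet
    restart_scores: list[float] = field(default_factory=list)

    @property
    def best_partition(self) -> Partition:
        return Partition(self.network, self.best_membership)

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.restart, r.stage, r.n_modules, r.D) for r in self.trajectory],
            columns=["restart", "stage", "module_count", "D"])


def initialize_singletons(network: PPINetwork) -> Partition:
    """Step 1: every protein node is its own module."""
    return Partition.singletons(network)


def sweep(partition: Partition, rng: random.Random,
          cad_form: str = "consistent") -> int:
    """One adaptive pass over all nodes in rng-shuffled order.

    Each node moves to its best external module when R_in < R_out (strict;
    on a tie the node stays).  Returns the number of accepted moves.
    """
    nodes = sorted(partition.membership)
    rng.shuffle(nodes)
    moved = 0
    for node in nodes:
        r_out = external_cad(partition, node)
        if r_out.target is None:
            continue
        r_in = internal_cad(partition, node, form=cad_form)
        if r_in.value < r_out.value:
            partition.move(node, r_out.target)
            moved += 1
    return moved


def stabilize(partition: Partition, rng: random.Random,
              max_sweeps: int = 1000, cad_form: str = "consistent") -> int:
    """Repeat sweeps until a pass makes no move; return productive sweeps.

    An already-stable partition costs one confirming pass and returns 0.
    If ``max_sweeps`` productive sweeps do not reach a fixed point (possible
    only under the non-monotone printed internal-score form), a warning is
    issued and the current state is kept.
    """
    count = 0
    while True:
        if count >= max_sweeps:
            warnings.warn(
                f"stabilize: no fixed point after {max_sweeps} sweeps; "
                "proceeding with the current partition", stacklevel=2)
            break
        if sweep(partition, rng, cad_form) == 0:
            break
        count += 1
    return count


def best_pair_merge(partition: Partition
                    ) -> tuple[tuple[int, int], float] | None:
    """Best module pair to merge, by proportional gain; not yet applied.

    Only pairs connected by at least one edge are candidates.  Returns
    ``((a, b), gain)`` with the maximum gain (ties resolve to the smallest
    id pair), or ``None`` when fewer than two modules remain or no
    connected pair exists.
    """
    if partition.n_modules < 2:
        return None
    best: tuple[tuple[int, int], float] | None = None
    for pair in sorted(partition.e):
        gain = merge_gain(partition, pair[0], pair[1], mode="proportional")
        if best is None or gain > best[1]:
            best = (pair, gain)
    return best


def filter_modules(partition: Partition, min_size: int) -> ModuleSet:
    """Modules with at least ``min_size`` proteins, largest first.

    Labels are ``m1, m2, ...`` in decreasing size order; equal sizes are
    ordered by their lexicographically smallest member.
    """
    keep = [sorted(s) for s in partition.members.values()
            if len(s) >= min_size]
    keep.sort(key=lambda members: (-len(members), members[0]))
    return ModuleSet.from_sets(keep)


def run_adm(network: PPINetwork, config: ADMConfig | None = None,
            seed_offset: int = 0) -> ADMResult:
    """One full ADM run: sweeps, agglomeration, max-D snapshot selection.

    Snapshots of D are recorded at every stabilized state; the loop merges
    the best connected module pair after each stabilization and terminates
    when no connected pair remains.  The returned result carries the
    snapshot with maximum D (first encountered on ties).
    """
    config = config or ADMConfig()
    if network.L == 0:
        raise ValueError("ADM requires a network with at least one edge")
    rng = random.Random(int(config.seed) + int(seed_offset))
    part = initialize_singletons(network)
    snapshots: list[tuple[float, dict[str, int]]] = []
    trajectory: list[TrajectoryRecord] = []
    stage = 0
    while True:
        stabilize(part, rng, config.max_sweeps, config.cad_form)
        D = partition_density(part)
        trajectory.append(
            TrajectoryRecord(seed_offset, f"stable-{stage}", part.n_modules, D))
        snapshots.append((D, dict(part.membership)))
        proposal = best_pair_merge(part)
        if proposal is None:
            break
        part.merge(*proposal[0])
        stage += 1
    best_D, best_membership = max(snapshots, key=lambda snap: snap[0])
    filtered = filter_modules(Partition(network, best_membership),
                              config.min_module_size)
    return ADMResult(network, best_membership, best_D, trajectory, filtered,
                     restart_scores=[best_D])


def multi_restart(network: PPINetwork,
                  config: ADMConfig | None = None) -> ADMResult:
    """The published 20-restart protocol: keep the run with greatest D.

    Restart ``i`` seeds its node-visit shuffles with ``config.seed + i``.
    The winner's result is returned with the concatenated trajectory of all
    restarts and the list of per-restart best D values (ties go to the
    earliest restart).
    """
    config = config or ADMConfig()
    results = [run_adm(network, config, seed_offset=i)
               for i in range(config.restarts)]
    scores = [r.best_D for r in results]
    winner = results[scores.index(max(scores))]
    winner.restart_scores = scores
    winner.trajectory = [rec for r in results for rec in r.trajectory]
    return winner
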