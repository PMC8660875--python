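"""Synthetic fluency cohorts with controlled ground-truth semantic structure.

The raw study data are not public, so pipeline testing relies on cohorts
whose ground truth is known.  Each group's semantic memory is modelled as a
planted-partition graph over a shared concept universe (modules play the
role of semantic subcategories, e.g. farm animals within "animals"); a
participant's fluency list is a censored random walk over that graph — the
walk emits a concept only on its first visit, with occasional uniform
restarts — truncated at a per-participant target length drawn from a
truncated normal.  Tuning the between-module edge probability moves the
ground-truth (and hence estimated) modularity, which is the lever the
group-difference tests exercise.

Defaults mirror the study conditions: groups of 36 and 31 participants,
list lengths averaging ~16.4 (SD 5.0) and ~14.8 (SD 5.8), and a shared
120-concept universe in six subcategories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .fluency_io import FluencyRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthConfig",
    "CohortConfig",
    "generate_ground_truth",
    "simulate_fluency_list",
    "generate_cohort",
    "study_cohort",
]


@dataclass(frozen=True)
class GroundTruthConfig:
    """Planted-partition ground-truth graph parameters."""

    n_concepts: int = 120
    n_modules: int = 6
    p_in: float = 0.35
    p_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_concepts >= self.n_modules >= 1):
            raise ValueError("need n_concepts >= n_modules >= 1")
        if not (0 <= self.p_out < self.p_in <= 1) and not (
            self.p_in == self.p_out == 1.0
        ):
            raise ValueError("need 0 <= p_out < p_in <= 1 (or both equal to 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level walk parameters for one group."""

    n_participants: int = 36
    list_length_mean: float = 15.5
    list_length_sd: float = 5.0
    jump_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.list_length_mean <= 0:
            raise ValueError("list_length_mean must be positive")
        if self.list_length_sd < 0:
            raise ValueError("list_length_sd must be nonnegative")
        if not 0 <= self.jump_prob <= 1:
            raise ValueError("jump_prob must lie in [0, 1]")


def generate_ground_truth(cfg: GroundTruthConfig, max_retries: int = 50) -> nx.Graph:
    """Connected planted-partition graph with concept labels c000, c001, ...

    Module sizes are as equal as possible.  Disconnected draws are rejected
    and redrawn; exhausting the retry budget (parameters too sparse) raises.
    """
    base = cfg.n_concepts // cfg.n_modules
    rem = cfg.n_concepts % cfg.n_modules
    sizes = [base + (1 if k < rem else 0) for k in range(cfg.n_modules)]
    probs = [
        [cfg.p_in if i == j else cfg.p_out for j in range(cfg.n_modules)]
        for i in range(cfg.n_modules)
    ]
    for attempt in range(max_retries):
        gseed = int(np.random.default_rng([cfg.seed, attempt]).integers(2**31))
        g = nx.stochastic_block_model(sizes, probs, seed=gseed)
        if nx.is_connected(g):
            if attempt:
                logger.info("ground truth connected after %d redraws", attempt)
            mapping = {i: f"c{i:03d}" for i in g.nodes()}
            truth = nx.relabel_nodes(g, mapping)
            truth.graph.clear()
            truth.graph["modules"] = {
                mapping[i]: blk for i, blk in enumerate(
                    np.repeat(range(cfg.n_modules), sizes)
                )
            }
            return truth
    raise RuntimeError(
        f"no connected planted-partition graph in {max_retries} draws; "
        f"parameters too sparse (p_in={cfg.p_in}, p_out={cfg.p_out})"
    )


def _draw_target_length(rng: np.random.Generator, cfg: CohortConfig, n: int) -> int:
    # Truncated normal on [1, n] by rejection; falls back to clamping only
    # if the window has negligible mass.
    for _ in range(1000):
        x = rng.normal(cfg.list_length_mean, cfg.list_length_sd)
        if 1 <= round(x) <= n:
            return int(round(x))
    return int(min(max(round(cfg.list_length_mean), 1), n))


def simulate_fluency_list(
    truth: nx.Graph, cfg: CohortConfig, participant_seed
) -> list[str]:
    """One participant's ordered, duplicate-free fluency list.

    Censored random walk: start uniform; each step moves to a uniform random
    neighbour, or with probability ``jump_prob`` restarts at a uniform node;
    a concept is emitted only on first visit.  The walk stops at the drawn
    target length or after a step cap of 50x the target (logged).
    """
    if not nx.is_connected(truth):
        raise ValueError("ground-truth graph must be connected")
    nodes = sorted(truth.nodes())
    n = len(nodes)
    neighbors = {u: sorted(truth.neighbors(u)) for u in nodes}
    rng = np.random.default_rng(participant_seed)
    target = _draw_target_length(rng, cfg, n)
    current = nodes[rng.integers(n)]
    emitted = [current]
    visited = {current}
    cap = 50 * target
    steps = 0
    while len(emitted) < target and steps < cap:
        steps += 1
        if rng.random() < cfg.jump_prob or not neighbors[current]:
            current = nodes[rng.integers(n)]
        else:
            nbrs = neighbors[current]
            current = nbrs[rng.integers(len(nbrs))]
        if current not in visited:
            visited.add(current)
            emitted.append(current)
    if len(emitted) < target:
        logger.info(
            "walk truncated at step cap: emitted %d of target %d", len(emitted), target
        )
    return emitted


def generate_cohort(
    truth_a: nx.Graph,
    truth_b: nx.Graph,
    cfg_a: CohortConfig,
    cfg_b: CohortConfig,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[list[FluencyRecord], list[FluencyRecord]]:
    """Fluency records for two groups walking their own ground truths.

    Both truths must share one concept-label universe so downstream node
    equating is meaningful.
    """
    out: list[list[FluencyRecord]] = []
    for truth, cfg, label in ((truth_a, cfg_a, labels[0]), (truth_b, cfg_b, labels[1])):
        records = []
        for i in range(cfg.n_participants):
            seq = simulate_fluency_list(truth, cfg, participant_seed=[cfg.seed, i])
            records.append(
                FluencyRecord(f"{label}{i + 1:03d}", label, tuple(seq))
            )
        out.append(records)
    return out[0], out[1]


def study_cohort(
    master_seed: int,
    p_out_a: float = 0.08,
    p_out_b: float = 0.02,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[list[FluencyRecord], list[FluencyRecord], nx.Graph, nx.Graph]:
    """Study-scale two-group cohort with a planted modularity contrast.

    Group A walks a less modular ground truth (higher between-module edge
    probability) than group B; everything else — concept universe, module
    count, within-module density, group sizes and list-length targets —
    follows the study conditions.  Returns ``(records_a, records_b,
    truth_a, truth_b)``.
    """
    rng = np.random.default_rng(master_seed)
    seeds = [int(rng.integers(2**31)) for _ in range(4)]
    truth_a = generate_ground_truth(
        GroundTruthConfig(n_concepts=120, n_modules=6, p_in=0.35, p_out=p_out_a, seed=seeds[0])
    )
    truth_b = generate_ground_truth(
        GroundTruthConfig(n_concepts=120, n_modules=6, p_in=0.35, p_out=p_out_b, seed=seeds[1])
    )
    cfg_a = CohortConfig(
        n_participants=36, list_length_mean=16.4, list_length_sd=5.0, seed=seeds[2]
    )
    cfg_b = CohortConfig(
        n_participants=31, list_length_mean=14.8, list_length_sd=5.8, seed=seeds[3]
    )
    rec_a, rec_b = generate_cohort(truth_a, truth_b, cfg_a, cfg_b, labels=labels)
    return rec_a, rec_b, truth_a, truth_b
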