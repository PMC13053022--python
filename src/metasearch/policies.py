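"""Search policies, termination-threshold optimization, and the ablation harness.

``Fixate_MAP`` is the resource-rational reference policy: fixate the object
currently most likely to be the target, and stop as soon as that maximum
posterior exceeds a confidence threshold theta. Baselines (uniform-random
fixation, a target-knowing oracle) bracket its performance. Theta trades
accuracy against fixation cost and is representation-dependent, so it is
optimized per representation by grid search on simulated mean return.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .metamdp import TERMINATE, BeliefState, MetaMDPParams, run_episode
from .scenes import Scene, restrict_features


def _check_theta(theta: float) -> float:
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    return float(theta)


def fixate_map_policy(theta: float):
    """Policy: terminate if max p_o > theta, else fixate the MAP object.

    Ties in the argmax break to the lowest object index. Phantoms carry zero
    posterior mass and are therefore never fixated.
    """
    _check_theta(theta)

    def policy(belief: BeliefState, rng: np.random.Generator) -> int:
        if belief.p.max() > theta:
            return TERMINATE
        return int(np.argmax(belief.p))

    return policy


def random_policy(theta: float):
    """Fixate uniformly at random over non-phantoms; same stopping rule."""
    _check_theta(theta)

    def policy(belief: BeliefState, rng: np.random.Generator) -> int:
        if belief.p.max() > theta:
            return TERMINATE
        candidates = np.flatnonzero(~belief.phantom_mask)
        return int(rng.choice(candidates))

    return policy


def greedy_oracle_policy(scene: Scene, theta: float):
    """Upper-bound baseline that always fixates the true target."""
    _check_theta(theta)
    target = int(scene.target_index)

    def policy(belief: BeliefState, rng: np.random.Generator) -> int:
        if belief.p.max() > theta:
            return TERMINATE
        return target

    return policy


def simulate_policy(
    scenes: list[Scene],
    policy_factory,
    params: MetaMDPParams,
    n_episodes: int,
    rng_seed: int,
):
    """Run ``n_episodes`` episodes cycling over ``scenes``; returns the traces.

    ``policy_factory(scene)`` builds the per-scene policy (scene-independent
    policies may ignore the argument). Episode seeds are child seeds of
    ``rng_seed``, so results are reproducible and, for a fixed seed, common
    across policies compared on the same ensemble (common random numbers).
    """
    if not scenes:
        raise ValueError("empty scene ensemble")
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_episodes)
    traces = []
    for i in range(n_episodes):
        scene = scenes[i % len(scenes)]
        policy = policy_factory(scene)
        traces.append(
            run_episode(scene, policy, params, int(seeds[i]), scene_id=f"scene_{i % len(scenes)}")
        )
    return traces


def mean_return(traces) -> float:
    return float(np.mean([t.return_ for t in traces]))


def logit_grid(n_points: int, low: float = 0.5, high: float = 0.999) -> np.ndarray:
    """Theta grid equally spaced in logit space over (low, high).

    Logit spacing concentrates grid points near 1, where the return surface
    is steepest.
    """
    if n_points < 1:
        raise ValueError("grid must have at least one point")
    if not 0.0 < low < high < 1.0:
        raise ValueError("grid range must satisfy 0 < low < high < 1")
    if n_points == 1:
        return np.array([low])
    return expit(np.linspace(logit(low), logit(high), n_points))


@dataclass(frozen=True)
class ThresholdResult:
    """Grid-search output: optimal theta plus the full evaluated surface."""

    theta: float
    grid: np.ndarray
    mean_returns: np.ndarray
    n_sims: int
    seed: int


def optimize_threshold(
    scenes: list[Scene],
    params: MetaMDPParams,
    n_sims: int = 1000,
    grid_size: int = 25,
    rng_seed: int = 0,
    grid: np.ndarray | None = None,
) -> ThresholdResult:
    """Grid-search theta to maximize mean Fixate_MAP return.

    The grid is logit-spaced over (0.5, 0.999). Every grid point is evaluated
    with the same episode seeds (common random numbers), which removes
    between-point simulation noise from the comparison. The returned theta is
    the grid argmax (ties to the lowest theta). The reference evaluation uses
    10,000 simulated episodes; ``n_sims`` defaults lower for quick runs.
    """
    if not scenes:
        raise ValueError("empty scene ensemble")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    grid = logit_grid(grid_size) if grid is None else np.asarray(grid, dtype=float)
    means = np.empty(len(grid))
    for i, theta in enumerate(grid):
        p = dc_replace(params, theta=float(theta))
        traces = simulate_policy(
            scenes, lambda sc: fixate_map_policy(float(theta)), p, n_sims, rng_seed
        )
        means[i] = mean_return(traces)
    best = int(np.argmax(means))
    return ThresholdResult(
        theta=float(grid[best]), grid=grid, mean_returns=means, n_sims=n_sims, seed=rng_seed
    )


@dataclass(frozen=True)
class AblationResult:
    """One cell of the representation x dimensionality ablation."""

    space: str
    n_pcs: int
    theta: float
    mean_return: float
    sd_return: float
    mean_fixations: float
    sd_fixations: float
    n_agents: int
    seed: int


def ablate(
    scenes_by_space: dict[str, list[Scene]],
    pcs: list[int],
    n_agents: int,
    params: MetaMDPParams,
    rng_seed: int,
    n_sims_opt: int = 500,
    episodes_per_agent: int | None = None,
    grid_size: int = 15,
) -> list[AblationResult]:
    """Simulate Fixate_MAP per (feature space, #principal components) cell.

    Scene features are assumed ordered by component rank, so a cell with k
    components sees only the first k feature columns. Per cell the threshold
    is optimized first, then ``n_agents`` independent agents (independent
    seeds of the same policy) each run one episode per scene; the cell
    records the across-agent mean and sd of return and fixation count.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    results = []
    root = np.random.SeedSequence(rng_seed)
    for space, scenes in scenes_by_space.items():
        if not scenes:
            raise ValueError(f"ablation cell ({space}): empty scene list")
        for k in pcs:
            if k > scenes[0].n_features:
                raise ValueError(
                    f"ablation cell ({space}, k={k}): only "
                    f"{scenes[0].n_features} feature columns available"
                )
            cell_seed = int(
                np.random.SeedSequence([rng_seed, _stable_hash(space), k]).generate_state(1)[0]
            )
            cut = [restrict_features(sc, k) for sc in scenes]
            opt = optimize_threshold(
                cut, params, n_sims=n_sims_opt, grid_size=grid_size, rng_seed=cell_seed
            )
            n_ep = episodes_per_agent or len(cut)
            agent_seeds = np.random.SeedSequence(cell_seed + 1).generate_state(n_agents)
            agent_returns, agent_fix = [], []
            p = dc_replace(params, theta=opt.theta)
            for aseed in agent_seeds:
                traces = simulate_policy(
                    cut, lambda sc: fixate_map_policy(opt.theta), p, n_ep, int(aseed)
                )
                agent_returns.append(mean_return(traces))
                agent_fix.append(float(np.mean([t.n_fixations for t in traces])))
            results.append(
                AblationResult(
                    space=space,
                    n_pcs=k,
                    theta=opt.theta,
                    mean_return=float(np.mean(agent_returns)),
                    sd_return=float(np.std(agent_returns, ddof=1)) if n_agents > 1 else 0.0,
                    mean_fixations=float(np.mean(agent_fix)),
                    sd_fixations=float(np.std(agent_fix, ddof=1)) if n_agents > 1 else 0.0,
                    n_agents=n_agents,
                    seed=cell_seed,
                )
            )
    return results


def _stable_hash(text: str) -> int:
    import zlib

    return zlib.crc32(text.encode())


def ablation_to_frame(results: list[AblationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "space": r.space,
                "n_pcs": r.n_pcs,
                "theta": r.theta,
                "mean_return": r.mean_return,
                "sd_return": r.sd_return,
                "mean_fixations": r.mean_fixations,
                "sd_fixations": r.sd_fixations,
                "n_agents": r.n_agents,
                "seed": r.seed,
            }
            for r in results
        ]
    )
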