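"""Model-gaze comparison metrics.

Simulated fixation traces and human fixation records are compared through a
shared set of summaries: relative looking-time distributions (proportion of
fixation samples per object), cross-entropy against an empirical distribution
with a fitted lapse rate, fixation-transition matrices compared by a Mantel
permutation test on their distance structure, a linear fixations-to-seconds
reaction-time mapping, and a correct / wrong-target / timeout performance
breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LookingTimeDistribution:
    """Proportion of fixation samples per object in one scene."""

    scene_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("looking-time distribution must be a probability vector")


@dataclass(frozen=True)
class TransitionMatrix:
    """Average row-stochastic transition matrix between fixated objects.

    Each contributing trace yields a matrix whose rows with outgoing
    transitions sum to 1 and whose unvisited rows are all-zero; the average
    across traces therefore has row sums in [0, 1] (a row sums to the
    fraction of traces that ever left that object).
    """

    scene_id: str
    matrix: np.ndarray
    n_traces: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        sums = m.sum(axis=1)
        if np.any(m < -1e-12) or np.any(sums > 1.0 + 1e-9):
            raise ValueError("rows must be non-negative with sums in [0, 1]")


@dataclass
class ComparisonResult:
    """Bundle of model-human alignment summaries."""

    cross_entropy: float
    baseline_cross_entropy: float
    baseline_difference: float
    lapse_rate: float
    mantel_r: float | None = None
    mantel_p: float | None = None
    tau_s: float | None = None
    performance: dict | None = None


def looking_time_distribution(
    fixation_lists: list[list[int]], n_objects: int, scene_id: str = ""
) -> LookingTimeDistribution:
    """Pool fixation samples across traces/participants and normalize."""
    counts = np.zeros(n_objects)
    total = 0
    for fixations in fixation_lists:
        for obj in fixations:
            if not 0 <= obj < n_objects:
                raise ValueError(f"fixation on invalid object index {obj}")
            counts[obj] += 1
            total += 1
    if total == 0:
        raise ValueError("no fixations recorded")
    return LookingTimeDistribution(scene_id=scene_id, probs=counts / total)


def lapse_smooth(model_probs: np.ndarray, eps: float) -> np.ndarray:
    """Mix the model distribution with uniform: (1 - eps) p + eps / N."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError("lapse rate must lie in [0, 1]")
    p = np.asarray(model_probs, dtype=float)
    return (1.0 - eps) * p + eps / len(p)


def cross_entropy_score(
    model_probs: np.ndarray, empirical_probs: np.ndarray, eps: float = 0.0
) -> float:
    """CE = -sum_o q_o log[(1-eps) p_o + eps/N] against empirical q.

    Infinite when eps = 0 and the model assigns zero mass to a fixated
    object; any positive lapse keeps it finite.
    """
    p = lapse_smooth(model_probs, eps)
    q = np.asarray(empirical_probs, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must cover the same objects")
    with np.errstate(divide="ignore"):
        logs = np.log(p)
    terms = np.where(q > 0, q * logs, 0.0)
    return float(-terms.sum())


def baseline_difference(
    model_probs: np.ndarray, empirical_probs: np.ndarray, eps: float = 0.0
) -> float:
    """CE(uniform, q) - CE(model, q): higher means a better-than-chance match."""
    n = len(model_probs)
    uniform = np.full(n, 1.0 / n)
    return cross_entropy_score(uniform, empirical_probs, 0.0) - cross_entropy_score(
        model_probs, empirical_probs, eps
    )


def fit_lapse_rate(
    model_dists: list[np.ndarray], empirical_dists: list[np.ndarray], grid_size: int = 2001
) -> float:
    """Lapse rate minimizing total cross-entropy over a dense grid on [0, 1].

    Summed CE over scenes is convex in eps (log of an affine function), so a
    dense-grid minimum is global to grid resolution.
    """
    if not model_dists or len(model_dists) != len(empirical_dists):
        raise ValueError("need matching, non-empty model and empirical distributions")
    grid = np.linspace(0.0, 1.0, grid_size)
    totals = np.zeros_like(grid)
    for p, q in zip(model_dists, empirical_dists):
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        # CE as a function of eps, vectorized over the grid.
        mix = (1.0 - grid[:, None]) * p[None, :] + grid[:, None] / len(p)
        with np.errstate(divide="ignore"):
            logs = np.log(mix)
        logs[:, q <= 0] = 0.0
        totals += -(q[None, :] * logs).sum(axis=1)
    return float(grid[int(np.argmin(totals))])


def transition_matrix(
    fixation_lists: list[list[int]],
    n_objects: int,
    scene_id: str = "",
    include_self: bool = True,
) -> TransitionMatrix:
    """Average of per-trace row-normalized consecutive-fixation count matrices.

    Traces with fewer than two fixations are ignored; if none remain an error
    is raised. ``include_self`` keeps self-transitions (refixations), which a
    MAP-fixating model produces naturally.
    """
    per_trace = []
    for fixations in fixation_lists:
        pairs = [
            (i, j)
            for i, j in zip(fixations[:-1], fixations[1:])
            if include_self or i != j
        ]
        if not pairs:
            continue
        counts = np.zeros((n_objects, n_objects))
        for i, j in pairs:
            if not (0 <= i < n_objects and 0 <= j < n_objects):
                raise ValueError("transition references invalid object index")
            counts[i, j] += 1
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            norm = np.where(sums > 0, counts / sums, 0.0)
        per_trace.append(norm)
    if not per_trace:
        raise ValueError("no trace with >= 2 fixations")
    return TransitionMatrix(
        scene_id=scene_id, matrix=np.mean(per_trace, axis=0), n_traces=len(per_trace)
    )


def transition_profile_distances(matrix: np.ndarray, strategy: str = "row+column") -> np.ndarray:
    """Object-object distance matrix from transition profiles.

    Each object's profile is its outgoing row, optionally concatenated with
    its incoming column; entries are Euclidean distances between profiles.
    """
    m = np.asarray(matrix, dtype=float)
    if strategy == "row+column":
        profiles = np.hstack([m, m.T])
    elif strategy == "row":
        profiles = m
    else:
        raise ValueError("strategy must be 'row' or 'row+column'")
    diff = profiles[:, None, :] - profiles[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _upper_triangle(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel_compare(
    simulated: TransitionMatrix | np.ndarray,
    empirical: TransitionMatrix | np.ndarray,
    n_perm: int = 999,
    rng_seed: int = 0,
    strategy: str = "row+column",
) -> tuple[float, float]:
    """Mantel test between the two systems' transition-distance structure.

    Builds an object x object Euclidean distance matrix over transition
    profiles for each system, correlates their off-diagonal upper triangles
    (Pearson r), and estimates a one-sided permutation p-value by relabeling
    the objects of one matrix: p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    sim = simulated.matrix if isinstance(simulated, TransitionMatrix) else np.asarray(simulated)
    emp = empirical.matrix if isinstance(empirical, TransitionMatrix) else np.asarray(empirical)
    if sim.shape != emp.shape:
        raise ValueError("transition matrices must cover the same object set")
    d_sim = transition_profile_distances(sim, strategy)
    d_emp = transition_profile_distances(emp, strategy)
    x = _upper_triangle(d_sim)
    y = _upper_triangle(d_emp)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    n = d_sim.shape[0]
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(rng_seed)
    xc = x - x.mean()
    x_ss = np.sqrt((xc**2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d_perm = d_emp[np.ix_(perm, perm)]
        yp = d_perm[iu]
        yc = yp - yp.mean()
        r_perm = float((xc * yc).sum() / (x_ss * np.sqrt((yc**2).sum())))
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def fit_tau(mean_rt_s: float, mean_fixations: float) -> float:
    """Seconds-per-fixation constant tau = m / f linking model fixations to RT."""
    if mean_rt_s <= 0 or mean_fixations <= 0:
        raise ValueError("mean RT and mean fixations must be positive")
    return mean_rt_s / mean_fixations


def rt_from_fixations(n_fixations, tau_s: float):
    """Per-trial reaction time: tau * number of fixations (linear, origin 0)."""
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    n = np.asarray(n_fixations, dtype=float)
    if np.any(n < 0):
        raise ValueError("fixation counts must be non-negative")
    out = tau_s * n
    return float(out) if out.ndim == 0 else out


def performance_summary(traces, tau_s: float = 4.55 / 12.39) -> dict:
    """Correct / wrong-target / timeout fractions plus RT quantiles.

    Correct and wrong-target trials terminated via the confidence threshold;
    timeouts exhausted the fixation budget. RTs use the linear fixation-to-
    seconds mapping; quantiles are reported for correct trials (and overall).
    """
    if not traces:
        raise ValueError("no traces supplied")
    n = len(traces)
    correct = sum(1 for t in traces if t.termination == "threshold" and t.correct == 1)
    wrong = sum(1 for t in traces if t.termination == "threshold" and t.correct == 0)
    timeout = sum(1 for t in traces if t.termination == "budget")
    rts = rt_from_fixations([t.n_fixations for t in traces], tau_s)
    rts_correct = rt_from_fixations(
        [t.n_fixations for t in traces if t.termination == "threshold" and t.correct == 1],
        tau_s,
    ) if correct else np.array([])
    def q(a, qs=(0.25, 0.5, 0.75)):
        return {f"q{int(100 * x)}": float(np.quantile(a, x)) for x in qs} if len(a) else {}
    return {
        "n_trials": n,
        "fraction_correct": correct / n,
        "fraction_wrong_target": wrong / n,
        "fraction_timeout": timeout / n,
        "rt_quantiles_s": q(rts),
        "rt_quantiles_correct_s": q(rts_correct),
        "mean_fixations": float(np.mean([t.n_fixations for t in traces])),
    }


def read_fixation_records(path) -> pd.DataFrame:
    """Read fixation records (participant_id, scene_id, ordinal, object_id)."""
    if str(path).endswith(".jsonl"):
        import json

        with open(path) as fh:
            df = pd.DataFrame([json.loads(line) for line in fh if line.strip()])
    else:
        df = pd.read_csv(path)
    required = {"participant_id", "scene_id", "ordinal", "object_id"}
    if not required <= set(df.columns):
        raise ValueError(f"fixation records need columns {sorted(required)}")
    return df
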