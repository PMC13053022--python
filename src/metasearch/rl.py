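"""Scaled-down actor-critic training on the meta-MDP.

Demonstrates that a policy-gradient learner, given only the belief-state
tensors and the episodic reward, rediscovers the MAP-fixation threshold
policy. The belief state is encoded as five tensors -- means F, precisions J,
target features, 2-D screen coordinates, and the target posterior -- with
objects *rank-ordered by posterior probability*, so that row 0 and action 0
always refer to the current MAP object. Both actor and critic pass each
input tensor through its own dense layer, concatenate, and continue through
three dense layers; the actor ends in a masked softmax over fixation actions
plus a terminal action, the critic in a scalar value.

Training uses a clipped-surrogate (PPO-style) policy loss with an entropy
bonus, undiscounted returns, generalized advantages of the simple form
G_t - V(s_t), Adam, and exponential learning-rate decay. The networks are
implemented directly in NumPy (the problem is small enough that explicit
backpropagation through a few dense layers is the simplest dependable
route), and every source of randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metamdp import (
    TERMINATE,
    BeliefState,
    MetaMDPParams,
    init_beliefs,
    run_episode,
    step,
)
from .scenes import Scene, project_to_screen

# ---------------------------------------------------------------------------
# State encoding


@dataclass(frozen=True)
class PolicyState:
    """Belief state as the learner sees it: rank-ordered tensors.

    ``perm`` maps encoded rows/actions to original object indices
    (``perm[0]`` is the MAP object). Phantom rows keep zero posterior and sit
    at screen center (0, 0).
    """

    F: np.ndarray
    J: np.ndarray
    f_target: np.ndarray
    x: np.ndarray
    p: np.ndarray
    perm: np.ndarray

    @property
    def n_objects(self) -> int:
        return self.F.shape[0]


def encode_state(belief: BeliefState, scene: Scene, axis: np.ndarray | None = None) -> PolicyState:
    """Rank-order objects by posterior (stable; ties by index) and project
    locations to normalized [-1, 1] screen coordinates."""
    order = np.argsort(-belief.p, kind="stable")
    screen = project_to_screen(scene.locations, axis=axis)
    screen = np.where(scene.phantom_mask[:, None], 0.0, screen)
    return PolicyState(
        F=belief.F[order],
        J=belief.J[order],
        f_target=belief.f_target.copy(),
        x=screen[order],
        p=belief.p[order],
        perm=order,
    )


def decode_action(state: PolicyState, encoded_action: int) -> int:
    """Map an encoded action back to the original object index (or terminate)."""
    if encoded_action == state.n_objects:
        return TERMINATE
    return int(state.perm[encoded_action])


def encoded_fixate_map(theta: float):
    """Hard-coded Fixate_MAP expressed in the encoded action space.

    Matches the ``act(state, phantom_mask, rng, greedy)`` interface of a
    trained agent, so both run through the same diagnostics.
    """

    def act(state: PolicyState, phantom_sorted, rng: np.random.Generator,
            greedy: bool = True) -> int:
        return state.n_objects if state.p[0] > theta else 0

    return act


# ---------------------------------------------------------------------------
# Tiny dense networks with explicit backprop


def _init_dense(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / (n_in + n_out))
    return w, np.zeros(n_out)


class _BranchedNet:
    """Per-block input dense layers -> concat -> 3 dense tanh layers -> linear head."""

    def __init__(self, block_dims: list[int], width: int, n_out: int, rng: np.random.Generator):
        self.block_dims = list(block_dims)
        self.width = width
        self.n_out = n_out
        self.params: dict[str, np.ndarray] = {}
        for i, d in enumerate(block_dims):
            self.params[f"Wb{i}"], self.params[f"bb{i}"] = _init_dense(rng, d, width)
        trunk_in = width * len(block_dims)
        dims = [trunk_in, width, width, width]
        for i in range(3):
            self.params[f"W{i}"], self.params[f"b{i}"] = _init_dense(rng, dims[i], dims[i + 1])
        self.params["Wh"], self.params["bh"] = _init_dense(rng, width, n_out)

    def forward(self, blocks: list[np.ndarray], cache: dict | None = None) -> np.ndarray:
        """``blocks[i]`` is (batch, block_dims[i]); returns (batch, n_out)."""
        hs = []
        for i, x in enumerate(blocks):
            hs.append(np.tanh(x @ self.params[f"Wb{i}"] + self.params[f"bb{i}"]))
        z = np.concatenate(hs, axis=1)
        acts = [z]
        for i in range(3):
            z = np.tanh(z @ self.params[f"W{i}"] + self.params[f"b{i}"])
            acts.append(z)
        out = z @ self.params["Wh"] + self.params["bh"]
        if cache is not None:
            cache["blocks"] = blocks
            cache["hs"] = hs
            cache["acts"] = acts
        return out

    def backward(self, cache: dict, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of sum(loss) given d loss / d out; mean over batch is the
        caller's responsibility (scale dout)."""
        grads: dict[str, np.ndarray] = {}
        acts = cache["acts"]
        grads["Wh"] = acts[-1].T @ dout
        grads["bh"] = dout.sum(axis=0)
        dz = dout @ self.params["Wh"].T
        for i in reversed(range(3)):
            da = dz * (1.0 - acts[i + 1] ** 2)  # tanh'
            grads[f"W{i}"] = acts[i].T @ da
            grads[f"b{i}"] = da.sum(axis=0)
            dz = da @ self.params[f"W{i}"].T
        # split the concat gradient back into blocks
        offset = 0
        for i, h in enumerate(cache["hs"]):
            dh = dz[:, offset : offset + self.width]
            da = dh * (1.0 - h**2)
            grads[f"Wb{i}"] = cache["blocks"][i].T @ da
            grads[f"bb{i}"] = da.sum(axis=0)
            offset += self.width
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def update(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training


@dataclass(frozen=True)
class TrainingConfig:
    """Reduced-scale training configuration.

    Defaults train on 8-object, 2-feature scenes with a hidden width equal to
    the object count (mirroring the full-scale 113-unit layers). The clip and
    entropy coefficients and the exponential learning-rate decay (factor
    ``lr_decay`` every ``lr_decay_every`` updates) are stability defaults.
    """

    n_objects: int = 8
    n_features: int = 2
    width: int | None = None  # default: n_objects
    episodes: int = 60_000
    episodes_per_update: int = 100
    epochs_per_update: int = 4
    lr: float = 3e-3
    lr_decay: float = 0.99
    lr_decay_every: int = 1000
    clip: float = 0.2
    entropy_coef: float = 0.01
    entropy_decay: float = 1.0  # optional per-update annealing of exploration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")

    @property
    def hidden_width(self) -> int:
        return self.width or self.n_objects


class TrainedAgent:
    """Actor-critic policy over encoded belief states."""

    def __init__(self, actor: _BranchedNet, critic: _BranchedNet, config: TrainingConfig,
                 params: MetaMDPParams, curve: np.ndarray):
        self.actor = actor
        self.critic = critic
        self.config = config
        self.mdp_params = params
        self.curve = curve  # per-episode returns over training

    def _blocks(self, state: PolicyState) -> list[np.ndarray]:
        return [
            state.F.ravel()[None, :],
            state.J.ravel()[None, :],
            state.f_target[None, :],
            state.x.ravel()[None, :],
            state.p[None, :],
        ]

    def action_probs(self, state: PolicyState, phantom_sorted: np.ndarray) -> np.ndarray:
        logits = self.actor.forward(self._blocks(state))[0]
        return _masked_softmax(logits[None, :], phantom_sorted[None, :])[0]

    def act(self, state: PolicyState, phantom_sorted: np.ndarray,
            rng: np.random.Generator, greedy: bool = False) -> int:
        probs = self.action_probs(state, phantom_sorted)
        if greedy:
            return int(np.argmax(probs))
        return int(rng.choice(len(probs), p=probs))

    def as_raw_policy(self, scene: Scene):
        """Adapter to the ``policy(belief, rng) -> raw action`` interface."""

        def policy(belief: BeliefState, rng: np.random.Generator) -> int:
            state = encode_state(belief, scene)
            mask = scene.phantom_mask[state.perm]
            a = self.act(state, mask, rng, greedy=True)
            return decode_action(state, a)

        return policy

    def save_metadata(self, path) -> None:
        import json
        from dataclasses import asdict

        meta = {"config": asdict(self.config), "curve_tail_mean": float(np.mean(self.curve[-1000:]))}
        with open(path, "w") as fh:
            json.dump(meta, fh)

    def save(self, directory) -> None:
        """Checkpoint: weights as .npz plus a JSON metadata sidecar."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "actor.npz", **self.actor.params)
        np.savez(d / "critic.npz", **self.critic.params)
        np.savetxt(d / "learning_curve.csv", self.curve, delimiter=",",
                   header="episode_return", comments="")
        self.save_metadata(d / "metadata.json")

    @classmethod
    def load(cls, directory, params: MetaMDPParams) -> "TrainedAgent":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        config = TrainingConfig(**meta["config"])
        rng = np.random.default_rng(config.seed)
        n_o, n_f = config.n_objects, config.n_features
        block_dims = [n_o * n_f, n_o * n_f, n_f, n_o * 2, n_o]
        actor = _BranchedNet(block_dims, config.hidden_width, n_o + 1, rng)
        critic = _BranchedNet(block_dims, config.hidden_width, 1, rng)
        with np.load(d / "actor.npz") as z:
            actor.params = {k: z[k] for k in z.files}
        with np.load(d / "critic.npz") as z:
            critic.params = {k: z[k] for k in z.files}
        curve = np.loadtxt(d / "learning_curve.csv", delimiter=",", skiprows=1)
        return cls(actor, critic, config, params, np.atleast_1d(curve))


def _masked_softmax(logits: np.ndarray, phantom_mask_sorted: np.ndarray) -> np.ndarray:
    """Softmax over fixation+terminate logits with phantom fixations masked out."""
    masked = logits.copy()
    n_obj = phantom_mask_sorted.shape[1]
    masked[:, :n_obj][phantom_mask_sorted] = -np.inf
    masked -= masked.max(axis=1, keepdims=True)
    e = np.exp(masked)
    return e / e.sum(axis=1, keepdims=True)


def train_agent(
    config: TrainingConfig,
    scenes: list[Scene],
    params: MetaMDPParams,
) -> TrainedAgent:
    """Train an actor-critic agent on a scene ensemble; fully seeded.

    Raises ``FloatingPointError`` with a diagnostic if the loss diverges.
    """
    if not scenes:
        raise ValueError("empty scene ensemble")
    n_o, n_f = config.n_objects, config.n_features
    for sc in scenes:
        if sc.n_objects != n_o or sc.n_features != n_f:
            raise ValueError("all scenes must match the configured (n_objects, n_features)")
    rng = np.random.default_rng(config.seed)
    block_dims = [n_o * n_f, n_o * n_f, n_f, n_o * 2, n_o]
    actor = _BranchedNet(block_dims, config.hidden_width, n_o + 1, rng)
    critic = _BranchedNet(block_dims, config.hidden_width, 1, rng)
    opt_a = _Adam(actor.params, config.lr)
    opt_c = _Adam(critic.params, config.lr)
    agent = TrainedAgent(actor, critic, config, params, np.empty(0))

    curve = []
    n_updates = max(1, config.episodes // config.episodes_per_update)
    lr = config.lr
    entropy_coef = config.entropy_coef
    update_count = 0
    for _ in range(n_updates):
        batch_blocks: list[list[np.ndarray]] = [[] for _ in range(5)]
        batch_actions: list[int] = []
        batch_logp: list[float] = []
        batch_returns: list[float] = []
        batch_masks: list[np.ndarray] = []
        for _ep in range(config.episodes_per_update):
            scene = scenes[int(rng.integers(len(scenes)))]
            belief = init_beliefs(scene, params, rng)
            rewards: list[float] = []
            ep_blocks, ep_actions, ep_logp, ep_masks = [], [], [], []
            for _t in range(params.fixation_budget):
                state = encode_state(belief, scene)
                mask = scene.phantom_mask[state.perm]
                blocks = agent._blocks(state)
                probs = agent.action_probs(state, mask)
                a = int(rng.choice(len(probs), p=probs))
                ep_blocks.append(blocks)
                ep_actions.append(a)
                ep_logp.append(float(np.log(probs[a])))
                ep_masks.append(mask)
                raw = decode_action(state, a)
                belief, reward, done, _ = step(scene, belief, raw, params, rng)
                rewards.append(reward)
                if done:
                    break
            # undiscounted return-to-go
            g = np.cumsum(rewards[::-1])[::-1]
            for blocks, a, lp, m, gt in zip(ep_blocks, ep_actions, ep_logp, ep_masks, g):
                for j in range(5):
                    batch_blocks[j].append(blocks[j][0])
                batch_actions.append(a)
                batch_logp.append(lp)
                batch_returns.append(float(gt))
                batch_masks.append(m)
            curve.append(float(np.sum(rewards)))

        blocks_mat = [np.asarray(b) for b in batch_blocks]
        actions = np.asarray(batch_actions)
        logp_old = np.asarray(batch_logp)
        returns = np.asarray(batch_returns)
        masks = np.asarray(batch_masks)
        T = len(actions)

        values = critic.forward(blocks_mat)[:, 0]
        adv = returns - values
        adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)

        for _epoch in range(config.epochs_per_update):
            cache_a: dict = {}
            logits = actor.forward(blocks_mat, cache_a)
            probs = _masked_softmax(logits, masks)
            p_a = probs[np.arange(T), actions]
            logp = np.log(p_a + 1e-300)
            ratio = np.exp(logp - logp_old)
            unclipped = ratio * adv_n
            clipped = np.clip(ratio, 1 - config.clip, 1 + config.clip) * adv_n
            use_unclipped = unclipped <= clipped  # min selects the unclipped branch
            loss_pi = -np.minimum(unclipped, clipped).mean()
            if not np.isfinite(loss_pi):
                raise FloatingPointError(
                    f"policy loss diverged (loss={loss_pi}) at update {update_count}"
                )
            # d(-min surrogate)/dlogits
            onehot = np.zeros_like(probs)
            onehot[np.arange(T), actions] = 1.0
            coef = np.where(use_unclipped, -adv_n * ratio, 0.0)
            dlogits = coef[:, None] * (onehot - probs) / T
            # entropy bonus: d(-beta*H)/dlogits = beta * p * (log p + H)
            with np.errstate(divide="ignore", invalid="ignore"):
                logp_all = np.where(probs > 0, np.log(probs), 0.0)
            H = -(probs * logp_all).sum(axis=1, keepdims=True)
            dlogits += entropy_coef * probs * (logp_all + H) / T
            grads_a = actor.backward(cache_a, dlogits)
            opt_a.update(actor.params, grads_a, lr)

            cache_c: dict = {}
            v = critic.forward(blocks_mat, cache_c)[:, 0]
            dv = (2.0 * (v - returns) / T)[:, None]
            grads_c = critic.backward(cache_c, dv)
            opt_c.update(critic.params, grads_c, lr)

        update_count += 1
        entropy_coef *= config.entropy_decay
        if update_count % config.lr_decay_every == 0:
            lr *= config.lr_decay

    agent.curve = np.asarray(curve)
    return agent


# ---------------------------------------------------------------------------
# Diagnostics


@dataclass
class PolicyDiagnostics:
    """Termination curve, action-rank frequencies, and Fixate_MAP agreement."""

    termination_prob_by_fixation: np.ndarray
    rank_frequency: np.ndarray  # (timepoint, rank) row-normalized
    agreement: float
    mean_return: float
    returns: np.ndarray = field(default_factory=lambda: np.empty(0))


def policy_diagnostics(
    act_fn,
    scenes: list[Scene],
    params: MetaMDPParams,
    n_episodes: int,
    rng_seed: int = 0,
    greedy: bool = True,
) -> PolicyDiagnostics:
    """Roll out an encoded-action policy and summarize its decisions.

    ``act_fn(state, phantom_mask_sorted, rng, greedy)`` returns an encoded
    action (rank index, or n_objects for terminate). Agreement is the
    fraction of non-terminal decisions whose action is rank 0 (the MAP
    object).
    """
    rng = np.random.default_rng(rng_seed)
    budget = params.fixation_budget
    term_counts = np.zeros(budget + 1)
    alive_counts = np.zeros(budget + 1)
    rank_counts = np.zeros((budget, len(scenes[0].object_ids) + 1))
    n_map, n_fix_decisions = 0, 0
    returns = np.empty(n_episodes)
    for e in range(n_episodes):
        scene = scenes[e % len(scenes)]
        belief = init_beliefs(scene, params, rng)
        rewards = []
        for t in range(budget):
            state = encode_state(belief, scene)
            mask = scene.phantom_mask[state.perm]
            a = act_fn(state, mask, rng, greedy)
            alive_counts[t] += 1
            if a == state.n_objects:
                term_counts[t] += 1
                belief, r, _, _ = step(scene, belief, TERMINATE, params, rng)
                rewards.append(r)
                break
            rank_counts[t, a] += 1
            n_fix_decisions += 1
            n_map += int(a == 0)
            belief, r, _, _ = step(scene, belief, int(state.perm[a]), params, rng)
            rewards.append(r)
        returns[e] = sum(rewards)
    with np.errstate(invalid="ignore"):
        term_prob = np.where(alive_counts > 0, term_counts / alive_counts, 0.0)
    row_sums = rank_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        rank_freq = np.where(row_sums > 0, rank_counts / row_sums, 0.0)
    return PolicyDiagnostics(
        termination_prob_by_fixation=term_prob[:budget],
        rank_frequency=rank_freq,
        agreement=n_map / n_fix_decisions if n_fix_decisions else float("nan"),
        mean_return=float(returns.mean()),
        returns=returns,
    )
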