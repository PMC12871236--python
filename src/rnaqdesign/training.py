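"""Experience collection and twice-shifted action-value training.

The learning loop alternates two phases:

* **play** — decode a sequence per target with epsilon-greedy action
  selection under the valid-action mask, fold it with the environment, and
  record the per-position binary rewards;
* **train** — regress the policy network's Q-value at each taken action
  onto the temporal-difference target built from the frozen target
  network's next-state maximum.

"Twice-shifted" refers to the two temporal offsets of the scheme: the
decoder input is the sequence shifted right with a START token, and the TD
target at position t uses the next-state maximum shifted left from t+1.
Rewards are exponentially reweighted by their sequence-level mean so that
nearly-perfect sequences receive a disproportionately strong learning
signal, and the discount factor decays linearly along the sequence so that
early positions — which dominate global structure formation — look further
ahead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from .environment import (
    COMPLEMENTS,
    DesignTarget,
    Predictor,
    ShapeThresholds,
    compute_rewards,
    predict_structure,
)
from .qnet import (
    BASES,
    START_TOKEN,
    QNetwork,
    decode_full,
    decode_step,
    encode,
    tokenize_sequence,
    tokenize_structure,
)
from .structures import SecondaryStructure, contact_matrix, parse_dotbracket, render_dotbracket

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpisodeRecord:
    """One replay element: target, generated sequence, per-position rewards."""

    target: DesignTarget
    sequence: str
    rewards: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=float))
        L = self.target.structure.length
        if not len(self.sequence) == L == self.rewards.shape[0]:
            raise ValueError("sequence, target and reward lengths disagree")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the outer learning loop.

    ``gamma_start``/``gamma_end`` bound the linearly decayed per-position
    discount; ``epsilon`` is the per-position random-action probability
    during play; ``target_sync_epochs`` counts epochs between target-network
    synchronizations; ``train_passes`` is the number of gradient passes over
    the freshly played episodes per round.
    """

    gamma_start: float = 0.95
    gamma_end: float = 0.5
    epsilon: float = 0.2
    learning_rate: float = 3e-3
    batch_size: int = 32
    target_sync_epochs: int = 1
    grad_clip: float = 1.0
    train_passes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_start < 1.0:
            raise ValueError("gamma_start must lie in [0, 1)")
        if not 0.0 <= self.gamma_end <= self.gamma_start:
            raise ValueError("gamma_end must lie in [0, gamma_start]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for name in ("learning_rate", "grad_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("batch_size", "target_sync_epochs", "train_passes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")


def valid_actions(
    target: SecondaryStructure, position: int, partial_sequence: str
) -> np.ndarray:
    """Boolean mask over {A, C, G, U} of actions legal at ``position``.

    When the target pairs ``position`` with an already-decoded partner
    ``i < position``, only canonical complements of the base at ``i`` are
    allowed (A-U, G-C, G-U); otherwise all four bases are legal.
    """
    if position >= target.length:
        raise ValueError("position beyond target length")
    partner = target.partner.get(position)
    if partner is None or partner > position:
        return np.ones(4, dtype=bool)
    base = partial_sequence[partner]
    mask = np.zeros(4, dtype=bool)
    for b in COMPLEMENTS[base]:
        mask[BASES.index(b)] = True
    return mask


def reweight_rewards(rewards: np.ndarray) -> np.ndarray:
    """Scale the reward vector by ``exp(mean(rewards))``.

    Boosts nearly-perfect episodes: an all-ones vector is scaled by e, an
    all-zeros vector is unchanged.  Never changes which entries are zero.
    """
    rewards = np.asarray(rewards, dtype=float)
    if rewards.size == 0:
        raise ValueError("cannot reweight an empty reward vector")
    return rewards * np.exp(rewards.mean())


def discount_schedule(L: int, gamma_start: float, gamma_end: float) -> np.ndarray:
    """Linearly decayed discount: gamma_start at t=0 down to gamma_end at t=L-1."""
    if L < 1:
        raise ValueError("L must be at least 1")
    if L == 1:
        return np.array([gamma_start])
    t = np.arange(L, dtype=float)
    return gamma_start - (t / (L - 1)) * (gamma_start - gamma_end)


def shift_left(values: np.ndarray) -> np.ndarray:
    """Shift a per-position vector left by one, filling the end with 0."""
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    out[..., :-1] = values[..., 1:]
    return out


def td_targets(
    rewards: np.ndarray, next_max_q: np.ndarray, discounts: np.ndarray
) -> np.ndarray:
    """TD target Q̂_t = r_t + γ_t · max_a' Q⁻(s_{t+1}, a').

    ``next_max_q`` is the frozen network's per-position maximum already
    shifted left; the final position has no successor, so its future term
    is forced to zero and its target equals the (reweighted) reward.
    """
    rewards = np.asarray(rewards, dtype=float)
    next_max_q = np.asarray(next_max_q, dtype=float)
    discounts = np.asarray(discounts, dtype=float)
    if not rewards.shape == next_max_q.shape:
        raise ValueError("rewards and next_max_q shapes disagree")
    if discounts.shape[-1] != rewards.shape[-1]:
        raise ValueError("discount schedule length disagrees with rewards")
    future = next_max_q.copy()
    future[..., -1] = 0.0
    return rewards + discounts * future


# ---------------------------------------------------------------------------
# Playing

def decode_sequence(
    network: QNetwork,
    target: DesignTarget,
    epsilon: float = 0.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Autoregressive epsilon-greedy decode of one sequence for a target."""
    structure = target.structure
    ctx = network.encode_structure(structure)
    cache = network.init_cache(ctx)
    flags = structure.paired_flags()
    token = START_TOKEN
    seq: list[str] = []
    for t in range(structure.length):
        q = decode_step(cache, token, int(flags[t]))[0]
        mask = valid_actions(structure, t, "".join(seq))
        if epsilon > 0 and rng is not None and rng.random() < epsilon:
            action = int(rng.choice(np.flatnonzero(mask)))
        else:
            masked = np.where(mask, q, -np.inf)
            action = int(np.argmax(masked))
        seq.append(BASES[action])
        token = action
    return "".join(seq)


def play_episodes(
    network: QNetwork,
    predictor: Predictor,
    targets: list[DesignTarget],
    epsilon: float = 0.0,
    seed: int = 0,
    use_shape: bool = False,
    thresholds: ShapeThresholds = ShapeThresholds(),
    fold_threshold: float = 0.5,
) -> tuple[list[EpisodeRecord], float]:
    """Play one episode per target; returns records and mean episode reward.

    The mean episode reward is the mean over episodes of the per-position
    reward fraction (so 1.0 means every position of every episode earned
    its reward).  Environment failures skip the episode with a warning.
    """
    rng = np.random.default_rng(seed)
    records: list[EpisodeRecord] = []
    for target in targets:
        try:
            seq = decode_sequence(network, target, epsilon, rng)
            predicted = predict_structure(predictor, seq, threshold=fold_threshold)
            shape = None
            if use_shape:
                from .scoring import normalize_shape

                shape = normalize_shape(predictor.shape(seq))
            thr = target.shape_thresholds or thresholds
            rewards = compute_rewards(predicted, target.structure, shape, thr)
        except Exception:  # noqa: BLE001 - environment errors skip the episode
            logger.warning("episode failed for target %s; skipping", target.name, exc_info=True)
            continue
        records.append(EpisodeRecord(target=target, sequence=seq, rewards=rewards))
    mean_reward = (
        float(np.mean([r.rewards.mean() for r in records])) if records else 0.0
    )
    return records, mean_reward


# ---------------------------------------------------------------------------
# Training

class AdamOptimizer:
    """Adam over a nested dict/list parameter tree with global-norm clipping."""

    def __init__(self, lr: float, grad_clip: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.grad_clip = grad_clip
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, params, grads):
        leaves_g = _tree_leaves(grads)
        norm = float(np.sqrt(sum(float(np.sum(g**2)) for g in leaves_g)))
        scale = self.grad_clip / norm if norm > self.grad_clip else 1.0
        if self.m is None:
            self.m = _tree_map(lambda g: np.zeros_like(g), grads)
            self.v = _tree_map(lambda g: np.zeros_like(g), grads)
        self.t += 1
        b1, b2 = self.beta1, self.beta2

        def upd(p, g, m, v):
            g = g * scale
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            return p - self.lr * mhat / (np.sqrt(vhat) + self.eps)

        return _tree_map4(upd, params, grads, self.m, self.v)


def _tree_map(fn, node):
    if isinstance(node, dict):
        return {k: _tree_map(fn, v) for k, v in node.items()}
    if isinstance(node, list):
        return [_tree_map(fn, v) for v in node]
    return fn(node)


def _tree_map4(fn, a, b, c, d):
    if isinstance(a, dict):
        return {k: _tree_map4(fn, a[k], b[k], c[k], d[k]) for k in a}
    if isinstance(a, list):
        return [_tree_map4(fn, *vs) for vs in zip(a, b, c, d)]
    return fn(a, b, c, d)


def _tree_leaves(node):
    if isinstance(node, dict):
        return [leaf for v in node.values() for leaf in _tree_leaves(v)]
    if isinstance(node, list):
        return [leaf for v in node for leaf in _tree_leaves(v)]
    return [node]


def _batch_arrays(episodes: list[EpisodeRecord]):
    """Stack same-length episodes into training arrays."""
    L = episodes[0].target.structure.length
    enc_tokens = np.stack(
        [tokenize_structure(render_dotbracket(e.target.structure)) for e in episodes]
    )
    contacts = np.stack([contact_matrix(e.target.structure) for e in episodes]).astype(float)
    actions = np.stack([tokenize_sequence(e.sequence) for e in episodes])
    dec_input = np.full((len(episodes), L), START_TOKEN, dtype=np.int64)
    dec_input[:, 1:] = actions[:, :-1]
    flags = np.stack([e.target.structure.paired_flags() for e in episodes])
    rewards = np.stack([reweight_rewards(e.rewards) for e in episodes])
    return enc_tokens, contacts, dec_input, flags, actions, rewards


def train_epoch(
    network: QNetwork,
    frozen_network: QNetwork,
    episodes: list[EpisodeRecord],
    config: TrainingConfig,
    optimizer: AdamOptimizer | None = None,
) -> float:
    """One gradient pass over the episodes; returns the mean TD loss.

    Episodes are grouped by target length and split into batches.  For each
    batch the decoder input is the action sequence shifted right with a
    START token; the frozen network supplies the left-shifted next-state
    maxima for the TD targets (Q̂ = r̃ + γ_t · max'), and the squared error
    between the policy network's Q-value at each taken action and Q̂ is
    minimized with Adam under global-norm gradient clipping.
    """
    if not episodes:
        raise ValueError("train_epoch requires at least one episode")
    if network.config != frozen_network.config:
        raise ValueError("policy and target network configs disagree")
    if optimizer is None:
        optimizer = AdamOptimizer(config.learning_rate, config.grad_clip)
    n_heads = network.config.attention_heads

    by_length: dict[int, list[EpisodeRecord]] = {}
    for e in episodes:
        by_length.setdefault(e.target.structure.length, []).append(e)

    losses: list[float] = []
    sizes: list[int] = []
    for L, group in sorted(by_length.items()):
        for start in range(0, len(group), config.batch_size):
            batch = group[start : start + config.batch_size]
            enc_tokens, contacts, dec_input, flags, actions, rewards = _batch_arrays(batch)
            B = len(batch)

            frozen_ctx = frozen_network.encode(enc_tokens, contacts)
            frozen_grid = decode_full(
                frozen_network.params, dec_input, flags, frozen_ctx, n_heads
            )
            next_max = shift_left(np.max(np.asarray(frozen_grid), axis=-1))
            discounts = discount_schedule(L, config.gamma_start, config.gamma_end)
            targets = td_targets(rewards, next_max, discounts)

            rows = np.repeat(np.arange(B), L)
            cols = np.tile(np.arange(L), B)
            acts = actions.reshape(-1)

            def loss_fn(params):
                ctx = encode(params, enc_tokens, contacts, n_heads)
                grid = decode_full(params, dec_input, flags, ctx, n_heads)
                q_sel = anp.reshape(grid[rows, cols, acts], (B, L))
                return anp.mean((q_sel - targets) ** 2)

            loss, grads = value_and_grad(loss_fn)(network.params)
            losses.append(float(loss))
            sizes.append(B)
            network.params = optimizer.step(network.params, grads)

    return float(np.average(losses, weights=sizes))


def sync_target(network: QNetwork, frozen_network: QNetwork) -> None:
    """Copy policy parameters into the frozen target network."""
    if network.config != frozen_network.config:
        raise ValueError("cannot sync networks with different configs")
    from .qnet import _tree_copy

    frozen_network.params = _tree_copy(network.params)


# ---------------------------------------------------------------------------
# Experience files: "id <TAB> dotbracket <TAB> sequence <TAB> r0,r1,..."

def write_episodes(path: str, episodes: list[EpisodeRecord], append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for e in episodes:
            rewards = ",".join(f"{v:g}" for v in e.rewards)
            fh.write(
                f"{e.target.name}\t{render_dotbracket(e.target.structure)}\t"
                f"{e.sequence}\t{rewards}\n"
            )


def read_episodes(path: str) -> list[EpisodeRecord]:
    episodes: list[EpisodeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                name, db, seq, rewards_s = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed episode record") from exc
            target = DesignTarget(structure=parse_dotbracket(db), name=name)
            rewards = np.array([float(x) for x in rewards_s.split(",")])
            episodes.append(EpisodeRecord(target=target, sequence=seq, rewards=rewards))
    return episodes
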