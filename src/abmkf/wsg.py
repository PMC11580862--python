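"""Stochastic Wolf-Sheep-Grass predator-prey agent-based model.

Wolves and sheep are mobile agents on a continuous torus; each carries an
energy counter.  Grass occupies fixed unit patches, is either alive or
regrowing, and regrows on a fixed timer.  Sheep eat grass at their patch,
wolves eat sheep at their patch, both reproduce with a fixed per-step
probability by splitting their energy with the child, and agents whose
energy falls below zero die.

The substep order within one synchronous step is move -> eat -> reproduce ->
die -> regrow, matching the classic reference model.  Movement is a random
walk: a uniform turn in [-50 deg, +50 deg], one patch forward, one energy
unit spent.

Because the spatial distributions of all three species are close to uniform,
microstate synthesis for this model is plain uniform resampling
(`synthesize_wsg`): agents are added at uniform-random positions or removed
uniformly at random, and grass patches are flipped uniformly among the
eligible ones, until the summary counts match the target macrostate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .macrostate import MacroSchema, MacroVector, default_wsg_schema

__all__ = [
    "WSGParams",
    "AgentArray",
    "WSGMicrostate",
    "init_wsg",
    "step_wsg",
    "summarize_wsg",
    "synthesize_wsg",
]

MAX_TURN_DEG = 50.0


@dataclass(frozen=True)
class WSGParams:
    wolf_reproduce_prob: float = 0.05
    sheep_reproduce_prob: float = 0.04
    wolf_gain_from_food: float = 20.0
    sheep_gain_from_food: float = 4.0
    grass_regrowth_time: int = 30
    world_width: int = 51
    world_height: int = 51
    init_wolves: int = 50
    init_sheep: int = 100
    init_grass_density: float = 0.5

    def __post_init__(self) -> None:
        for name in ("wolf_reproduce_prob", "sheep_reproduce_prob", "init_grass_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("wolf_gain_from_food", "sheep_gain_from_food"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.grass_regrowth_time < 1:
            raise ValueError("grass_regrowth_time must be >= 1")
        if self.world_width < 1 or self.world_height < 1:
            raise ValueError("world dimensions must be >= 1")
        if self.init_wolves < 0 or self.init_sheep < 0:
            raise ValueError("initial agent counts must be nonnegative")

    @property
    def n_patches(self) -> int:
        return self.world_width * self.world_height


@dataclass
class AgentArray:
    """Struct-of-arrays agent collection: positions, headings, energies."""

    positions: np.ndarray  # (n, 2) float, torus coordinates
    headings: np.ndarray  # (n,) float radians
    energies: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.headings = np.asarray(self.headings, dtype=float).ravel()
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        n = len(self.positions)
        if len(self.headings) != n or len(self.energies) != n:
            raise ValueError("agent array lengths differ")

    def __len__(self) -> int:
        return len(self.energies)

    @classmethod
    def empty(cls) -> "AgentArray":
        return cls(np.empty((0, 2)), np.empty(0), np.empty(0))

    def copy(self) -> "AgentArray":
        return AgentArray(self.positions.copy(), self.headings.copy(), self.energies.copy())

    def take(self, idx) -> "AgentArray":
        return AgentArray(self.positions[idx], self.headings[idx], self.energies[idx])

    def concat(self, other: "AgentArray") -> "AgentArray":
        return AgentArray(
            np.concatenate([self.positions, other.positions]),
            np.concatenate([self.headings, other.headings]),
            np.concatenate([self.energies, other.energies]),
        )


@dataclass
class WSGMicrostate:
    wolves: AgentArray
    sheep: AgentArray
    grass_alive: np.ndarray  # (W, H) bool
    grass_counter: np.ndarray  # (W, H) int; 0 iff alive

    def copy(self) -> "WSGMicrostate":
        return WSGMicrostate(
            self.wolves.copy(),
            self.sheep.copy(),
            self.grass_alive.copy(),
            self.grass_counter.copy(),
        )


def _random_agents(
    n: int, params: WSGParams, gain: float, rng: np.random.Generator
) -> AgentArray:
    pos = rng.uniform(
        [0.0, 0.0], [params.world_width, params.world_height], size=(n, 2)
    )
    head = rng.uniform(0.0, 2 * np.pi, size=n)
    # init energy uniform in (0, 2*gain]
    energy = (1.0 - rng.random(n)) * 2.0 * gain
    return AgentArray(pos, head, energy)


def init_wsg(params: WSGParams, rng: np.random.Generator) -> WSGMicrostate:
    """Uniform-random microstate: the model's 'known configuration'."""
    wolves = _random_agents(params.init_wolves, params, params.wolf_gain_from_food, rng)
    sheep = _random_agents(params.init_sheep, params, params.sheep_gain_from_food, rng)
    alive = rng.random((params.world_width, params.world_height)) < params.init_grass_density
    counter = np.zeros_like(alive, dtype=int)
    dead = ~alive
    counter[dead] = rng.integers(1, params.grass_regrowth_time + 1, size=int(dead.sum()))
    return WSGMicrostate(wolves, sheep, alive, counter)


def _patch_linear(positions: np.ndarray, params: WSGParams) -> np.ndarray:
    px = np.floor(positions[:, 0]).astype(int) % params.world_width
    py = np.floor(positions[:, 1]).astype(int) % params.world_height
    return px * params.world_height + py


def _move(agents: AgentArray, params: WSGParams, rng: np.random.Generator) -> None:
    n = len(agents)
    if n == 0:
        return
    turn = np.deg2rad(rng.uniform(-MAX_TURN_DEG, MAX_TURN_DEG, size=n))
    agents.headings = np.mod(agents.headings + turn, 2 * np.pi)
    step = np.stack([np.cos(agents.headings), np.sin(agents.headings)], axis=1)
    agents.positions = np.mod(
        agents.positions + step, [params.world_width, params.world_height]
    )
    agents.energies = agents.energies - 1.0


def _group_ranks(sorted_keys: np.ndarray) -> np.ndarray:
    """Rank of each element within its run of equal keys (keys sorted)."""
    if len(sorted_keys) == 0:
        return np.empty(0, dtype=int)
    starts = np.searchsorted(sorted_keys, sorted_keys, side="left")
    return np.arange(len(sorted_keys)) - starts


def _reproduce(agents: AgentArray, prob: float, rng: np.random.Generator) -> AgentArray:
    n = len(agents)
    if n == 0 or prob == 0.0:
        return agents
    mask = rng.random(n) < prob
    if not mask.any():
        return agents
    agents.energies[mask] *= 0.5
    children = AgentArray(
        agents.positions[mask].copy(),
        rng.uniform(0.0, 2 * np.pi, size=int(mask.sum())),
        agents.energies[mask].copy(),
    )
    return agents.concat(children)


def step_wsg(
    micro: WSGMicrostate, params: WSGParams, rng: np.random.Generator
) -> WSGMicrostate:
    """Advance one synchronous time step; the input microstate is not modified."""
    state = micro.copy()
    wolves, sheep = state.wolves, state.sheep

    # 1. random-walk movement, 1 energy spent
    _move(wolves, params, rng)
    _move(sheep, params, rng)

    # 2a. grazing: each sheep on an alive patch eats it; when several sheep
    # share a patch, a uniformly chosen one gets the energy.
    if len(sheep):
        lin = _patch_linear(sheep.positions, params)
        perm = rng.permutation(len(sheep))
        alive_flat = state.grass_alive.ravel()
        counter_flat = state.grass_counter.ravel()
        cand = perm[alive_flat[lin[perm]]]
        if len(cand):
            cand_lin = lin[cand]
            order = np.argsort(cand_lin, kind="stable")
            ranks = _group_ranks(cand_lin[order])
            eaters = cand[order][ranks == 0]
            sheep.energies[eaters] += params.sheep_gain_from_food
            eaten_patches = cand_lin[order][ranks == 0]
            alive_flat[eaten_patches] = False
            counter_flat[eaten_patches] = params.grass_regrowth_time

    # 2b. predation: each wolf sharing a patch with >= 1 sheep eats exactly
    # one, chosen uniformly among co-located sheep; multiple wolves on a
    # patch each eat a distinct sheep while supply lasts.
    if len(wolves) and len(sheep):
        wlin = _patch_linear(wolves.positions, params)
        slin = _patch_linear(sheep.positions, params)
        wperm = rng.permutation(len(wolves))
        sperm = rng.permutation(len(sheep))
        worder = wperm[np.argsort(wlin[wperm], kind="stable")]
        sorder = sperm[np.argsort(slin[sperm], kind="stable")]
        wkeys = wlin[worder]
        skeys = slin[sorder]
        wranks = _group_ranks(wkeys)
        sheep_here = np.searchsorted(skeys, wkeys, side="right") - np.searchsorted(
            skeys, wkeys, side="left"
        )
        feeding = wranks < sheep_here
        if feeding.any():
            sstart = np.searchsorted(skeys, wkeys[feeding], side="left")
            eaten = sorder[sstart + wranks[feeding]]
            wolves.energies[worder[feeding]] += params.wolf_gain_from_food
            keep = np.ones(len(sheep), dtype=bool)
            keep[eaten] = False
            sheep = sheep.take(keep)

    # 3. reproduction: energy split between parent and child
    wolves = _reproduce(wolves, params.wolf_reproduce_prob, rng)
    sheep = _reproduce(sheep, params.sheep_reproduce_prob, rng)

    # 4. starvation
    wolves = wolves.take(wolves.energies >= 0)
    sheep = sheep.take(sheep.energies >= 0)

    # 5. grass regrowth
    dead = state.grass_counter > 0
    state.grass_counter[dead] -= 1
    regrown = dead & (state.grass_counter == 0)
    state.grass_alive[regrown] = True

    state.wolves, state.sheep = wolves, sheep
    return state


def summarize_wsg(micro: WSGMicrostate, schema: MacroSchema | None = None) -> MacroVector:
    """Summary macrostate: (wolf count, sheep count, alive-grass count)."""
    if schema is None:
        schema = default_wsg_schema()
    values = np.array(
        [len(micro.wolves), len(micro.sheep), int(micro.grass_alive.sum())],
        dtype=float,
    )
    return MacroVector(schema, values)


def _target_counts(target) -> tuple[int, int, int]:
    if isinstance(target, MacroVector):
        vals = [target["wolves"], target["sheep"], target["grass"]]
    else:
        vals = list(np.asarray(target, dtype=float)[:3])
    counts = [int(round(v)) for v in vals]
    if any(c < 0 for c in counts):
        raise ValueError("target counts must be nonnegative")
    return counts[0], counts[1], counts[2]


def _adjust_agents(
    agents: AgentArray,
    target: int,
    params: WSGParams,
    gain: float,
    rng: np.random.Generator,
) -> AgentArray:
    n = len(agents)
    if target == n:
        return agents
    if target < n:
        keep = rng.choice(n, size=target, replace=False)
        return agents.take(np.sort(keep))
    extra = target - n
    new = _random_agents(extra, params, gain, rng)
    if n > 0:
        # continuity: new agents resample energy from survivors
        new.energies = rng.choice(agents.energies, size=extra, replace=True)
    return agents.concat(new)


def synthesize_wsg(
    target,
    seed: WSGMicrostate,
    params: WSGParams,
    rng: np.random.Generator,
) -> WSGMicrostate:
    """Uniform-random synthesis of a microstate matching the target counts.

    ``summarize_wsg`` of the result equals the (rounded) target exactly.
    """
    n_wolves, n_sheep, n_grass = _target_counts(target)
    if n_grass > params.n_patches:
        raise ValueError("target grass count exceeds number of patches")
    state = seed.copy()
    state.wolves = _adjust_agents(
        state.wolves, n_wolves, params, params.wolf_gain_from_food, rng
    )
    state.sheep = _adjust_agents(
        state.sheep, n_sheep, params, params.sheep_gain_from_food, rng
    )
    alive_flat = state.grass_alive.ravel()
    counter_flat = state.grass_counter.ravel()
    current = int(alive_flat.sum())
    if n_grass > current:
        dead_idx = np.flatnonzero(~alive_flat)
        flip = rng.choice(dead_idx, size=n_grass - current, replace=False)
        alive_flat[flip] = True
        counter_flat[flip] = 0
    elif n_grass < current:
        alive_idx = np.flatnonzero(alive_flat)
        flip = rng.choice(alive_idx, size=current - n_grass, replace=False)
        alive_flat[flip] = False
        counter_flat[flip] = rng.integers(1, params.grass_regrowth_time + 1, size=len(flip))
    return state
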