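"""Minimal spatial viral-infection agent-based model.

A deliberately small lattice model of an epithelial sheet under viral attack,
built to exercise spatially aware microstate synthesis: infection spreads by
local virus diffusion, so infected sites form growing hot-spots rather than a
well-mixed distribution.

State components per lattice site:

* epithelium — one of five categories: Healthy, Infected, Necrosed,
  Apoptosed, Empty;
* endothelium — Normal, Activated, or Dead;
* molecular fields — extracellular virus plus three cytokine-like fields
  (antiviral, proinflammatory, damage signal), each diffusing by an explicit
  5-point stencil with zero-flux boundaries and decaying multiplicatively.

Mobile immune agents chemotax up the proinflammatory gradient and kill
co-located infected cells.  A running counter tracks epithelial cells
apoptosed by the virus itself (immune kills are not counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .macrostate import MacroSchema, MacroVector, log_eps, scale, identity

__all__ = [
    "EPI_CATEGORIES",
    "ENDO_CATEGORIES",
    "ViralParams",
    "MolecularField",
    "ImmuneAgent",
    "ViralMicrostate",
    "default_viral_schema",
    "init_viral",
    "step_viral",
    "summarize_viral",
    "diffuse",
]

EPI_CATEGORIES = ("Healthy", "Infected", "Necrosed", "Apoptosed", "Empty")
HEALTHY, INFECTED, NECROSED, APOPTOSED, EMPTY = range(5)

ENDO_CATEGORIES = ("Normal", "Activated", "Dead")
NORMAL, ACTIVATED, DEAD = range(3)

CYTOKINE_NAMES = ("antiviral", "proinflammatory", "damage")


@dataclass(frozen=True)
class ViralParams:
    infect_rate: float = 0.5
    virus_production: float = 1.0
    initial_virus: float = 1.0
    apoptosis_rate: float = 0.03
    necrosis_rate: float = 0.01
    antiviral_production: float = 0.2
    proinflammatory_production: float = 1.0
    damage_production: float = 1.0
    virus_diffusion: float = 0.2
    cytokine_diffusion: float = 0.2
    virus_decay: float = 0.05
    cytokine_decay: float = 0.1
    immune_recruitment: float = 0.0005
    immune_kill_prob: float = 0.5
    activation_threshold: float = 2.0
    death_threshold: float = 5.0
    width: int = 51
    height: int = 51

    def __post_init__(self) -> None:
        for name in (
            "infect_rate", "virus_production", "initial_virus", "antiviral_production",
            "proinflammatory_production", "damage_production", "virus_decay",
            "cytokine_decay", "immune_recruitment", "activation_threshold",
            "death_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("apoptosis_rate", "necrosis_rate", "immune_kill_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("virus_diffusion", "cytokine_diffusion"):
            # explicit-Euler 5-point stencil is stable for D <= 1/4
            if not 0.0 <= getattr(self, name) <= 0.25:
                raise ValueError(f"{name} must be in [0, 0.25] for stability")
        if not 0.0 <= self.virus_decay <= 1.0 or not 0.0 <= self.cytokine_decay <= 1.0:
            raise ValueError("decay rates must be in [0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be >= 1")

    @property
    def shape(self) -> tuple:
        return (self.width, self.height)

    @property
    def n_sites(self) -> int:
        return self.width * self.height


@dataclass
class MolecularField:
    name: str
    values: np.ndarray
    diffusion_coeff: float = 0.2
    decay_rate: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("molecular field values must be nonnegative")

    def copy(self) -> "MolecularField":
        return MolecularField(self.name, self.values.copy(), self.diffusion_coeff, self.decay_rate)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class ImmuneAgent:
    """Mobile killer agent at an integer lattice site."""

    position: tuple
    kill_prob: float = 0.5


@dataclass
class ViralMicrostate:
    epithelium: np.ndarray  # (W, H) int in 0..4
    endothelium: np.ndarray  # (W, H) int in 0..2
    virus: MolecularField
    cytokines: dict  # name -> MolecularField
    immune_agents: list  # of ImmuneAgent
    apoptosis_by_virus_count: int = 0

    def copy(self) -> "ViralMicrostate":
        return ViralMicrostate(
            self.epithelium.copy(),
            self.endothelium.copy(),
            self.virus.copy(),
            {k: v.copy() for k, v in self.cytokines.items()},
            [ImmuneAgent(a.position, a.kill_prob) for a in self.immune_agents],
            self.apoptosis_by_virus_count,
        )

    @property
    def shape(self) -> tuple:
        return self.epithelium.shape


MACRO_NAMES = (
    "total_antiviral",
    "total_proinflammatory",
    "total_damage",
    "total_virus",
    "epi_healthy",
    "epi_infected",
    "epi_necrosed",
    "epi_apoptosed",
    "epi_empty",
    "endo_normal",
    "endo_activated",
    "endo_dead",
    "immune_count",
    "apoptosis_by_virus",
)


def default_viral_schema(
    n_sites: int = 51 * 51, parameter_names=()
) -> MacroSchema:
    """Macro schema: field totals on a shifted log scale, counts scaled to
    cell-coverage order of magnitude, small counts left closer to unity."""
    comps = []
    for name in MACRO_NAMES[:4]:
        comps.append((name, log_eps(1e-3), False))
    count_scale = scale(100.0 / n_sites)  # lattice counts ~ O(100) -> O(10)
    for name in MACRO_NAMES[4:12]:
        comps.append((name, count_scale, False))
    comps.append(("immune_count", scale(0.1), False))
    comps.append(("apoptosis_by_virus", scale(0.1), False))
    comps += [(n, identity(), True) for n in parameter_names]
    return MacroSchema.build(comps)


def _zero_field(name: str, params: ViralParams, diffusion: float, decay: float) -> MolecularField:
    return MolecularField(name, np.zeros(params.shape), diffusion, decay)


def init_viral(
    params: ViralParams, n_seed_infections: int, rng: np.random.Generator
) -> ViralMicrostate:
    """Onset configuration: healthy sheet with uniformly placed seed infections."""
    if n_seed_infections > params.n_sites:
        raise ValueError("more seed infections than lattice sites")
    epi = np.full(params.shape, HEALTHY, dtype=int)
    endo = np.full(params.shape, NORMAL, dtype=int)
    virus = _zero_field("virus", params, params.virus_diffusion, params.virus_decay)
    if n_seed_infections > 0:
        sites = rng.choice(params.n_sites, size=n_seed_infections, replace=False)
        epi.ravel()[sites] = INFECTED
        virus.values.ravel()[sites] = params.initial_virus
    cytokines = {
        name: _zero_field(name, params, params.cytokine_diffusion, params.cytokine_decay)
        for name in CYTOKINE_NAMES
    }
    return ViralMicrostate(epi, endo, virus, cytokines, [], 0)


def diffuse(values: np.ndarray, coeff: float) -> np.ndarray:
    """One explicit-Euler step of the 5-point Laplacian with zero-flux edges.

    Convex mixing: conserves total mass on the closed lattice and preserves
    nonnegativity for ``coeff <= 1/4``.
    """
    if coeff == 0.0:
        return values.copy()
    padded = np.pad(values, 1, mode="edge")
    lap = (
        padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
        - 4.0 * values
    )
    return values + coeff * lap


def _field_step(fld: MolecularField) -> None:
    fld.values = diffuse(fld.values, fld.diffusion_coeff) * (1.0 - fld.decay_rate)


def _neighborhood_max_move(
    pos: tuple, fld: np.ndarray, rng: np.random.Generator
) -> tuple:
    w, h = fld.shape
    x, y = pos
    best_val = -np.inf
    best: list = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                v = fld[nx, ny]
                if v > best_val + 1e-15:
                    best_val = v
                    best = [(nx, ny)]
                elif abs(v - best_val) <= 1e-15:
                    best.append((nx, ny))
    return best[rng.integers(len(best))]


def step_viral(
    micro: ViralMicrostate, params: ViralParams, rng: np.random.Generator
) -> ViralMicrostate:
    """Advance one step; the input microstate is not modified."""
    state = micro.copy()
    epi = state.epithelium
    virus = state.virus
    anti = state.cytokines["antiviral"]
    pro = state.cytokines["proinflammatory"]
    dmg = state.cytokines["damage"]

    # new infections driven by local virus (applied after transitions below)
    healthy = epi == HEALTHY
    p_inf = 1.0 - np.exp(-params.infect_rate * virus.values)
    newly_infected = healthy & (rng.random(epi.shape) < p_inf)

    infected = epi == INFECTED
    # secretion by currently infected sites
    virus.values[infected] += params.virus_production
    pro.values[infected] += params.proinflammatory_production
    anti.values[infected] += params.antiviral_production

    # infected-cell fate: apoptosis (promoted by local antiviral signal) vs necrosis
    u = rng.random(epi.shape)
    p_apop = np.clip(params.apoptosis_rate * (1.0 + anti.values), 0.0, 1.0)
    apop = infected & (u < p_apop)
    necro = infected & ~apop & (u < np.clip(p_apop + params.necrosis_rate, 0.0, 1.0))
    epi[apop] = APOPTOSED
    epi[necro] = NECROSED
    state.apoptosis_by_virus_count += int(apop.sum())

    # necrotic debris releases damage signal
    dmg.values[epi == NECROSED] += params.damage_production

    epi[newly_infected] = INFECTED

    # molecular transport
    _field_step(virus)
    for fld in state.cytokines.values():
        _field_step(fld)

    # immune agents: chemotax up proinflammatory, kill infected cells in place
    for agent in state.immune_agents:
        agent.position = _neighborhood_max_move(agent.position, pro.values, rng)
        x, y = agent.position
        if epi[x, y] == INFECTED and rng.random() < agent.kill_prob:
            epi[x, y] = APOPTOSED  # immune kill, not counted as virus-killed

    # recruitment proportional to total proinflammatory signal
    total_pro = pro.values.sum()
    n_new = rng.poisson(params.immune_recruitment * total_pro)
    if n_new > 0:
        if total_pro > 0:
            p = (pro.values / total_pro).ravel()
            sites = rng.choice(pro.values.size, size=n_new, p=p)
        else:
            sites = rng.integers(pro.values.size, size=n_new)
        for s in sites:
            state.immune_agents.append(
                ImmuneAgent(tuple(np.unravel_index(s, pro.values.shape)), params.immune_kill_prob)
            )

    # endothelium responds to local signal levels
    endo = state.endothelium
    endo[(endo == NORMAL) & (pro.values > params.activation_threshold)] = ACTIVATED
    endo[dmg.values > params.death_threshold] = DEAD
    return state


def summarize_viral(
    micro: ViralMicrostate, schema: MacroSchema | None = None
) -> MacroVector:
    """Ordered macro summary: field totals, category counts, immune and
    virus-kill counters."""
    if schema is None:
        schema = default_viral_schema(micro.epithelium.size)
    epi_counts = np.bincount(micro.epithelium.ravel(), minlength=5)
    endo_counts = np.bincount(micro.endothelium.ravel(), minlength=3)
    values = np.array(
        [
            micro.cytokines["antiviral"].total,
            micro.cytokines["proinflammatory"].total,
            micro.cytokines["damage"].total,
            micro.virus.total,
            *epi_counts.astype(float),
            *endo_counts.astype(float),
            float(len(micro.immune_agents)),
            float(micro.apoptosis_by_virus_count),
        ]
    )
    full = np.zeros(len(schema))
    full[: len(values)] = values
    return MacroVector(schema, full)
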