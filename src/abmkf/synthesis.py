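"""Microstate synthesis: realizing filtered macrostates as full model states.

The filter acts on low-dimensional macrostates; the simulators need full
microstates.  The synthesis step bridges the two under a *continuity*
principle — a posterior macrostate close to a predictive one should be
realized by editing the paired predictive microstate as little as possible —
and a *local-similarity* principle: in spatial models, edits should respect
local neighborhood structure.

Components:

* `pair_ensembles` — Gale-Shapley stable matching between predictive and
  posterior macro samples under mutual distance preferences, so each
  posterior sample is synthesized from a nearby predictive member's
  microstate.
* `simple_synthesis_viral` — minimal random relabeling: changes exactly half
  the L1 distance between category-count vectors, ignoring geometry.
* one-hot -> rescale -> quantize/error-diffuse — the spatially aware route
  for categorical lattices: encode categories as standard basis vectors,
  rescale componentwise so site sums hit the target counts, then quantize
  each site back to a basis vector while diffusing the quantization residual
  into not-yet-quantized neighbors so aggregate counts are conserved.
* `rescale_molecular` — multiplicative scaling of a nonnegative field to a
  target total; preserves spatial correlations exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .macrostate import MacroVector
from .viral import (
    ENDO_CATEGORIES,
    EPI_CATEGORIES,
    ImmuneAgent,
    MolecularField,
    ViralMicrostate,
)

__all__ = [
    "Matching",
    "pair_ensembles",
    "largest_remainder",
    "one_hot_encode",
    "one_hot_decode",
    "rescale_onehot",
    "QuantizationConfig",
    "NeighborhoodModel",
    "build_neighborhood_model",
    "quantize_error_diffuse",
    "rescale_molecular",
    "simple_synthesis_viral",
    "spatial_synthesis_viral",
]


# ---------------------------------------------------------------------------
# ensemble pairing


@dataclass
class Matching:
    """Stable bijection between posterior-sample and predictive-member indices."""

    post_to_pred: np.ndarray

    def __post_init__(self) -> None:
        self.post_to_pred = np.asarray(self.post_to_pred, dtype=int)
        n = len(self.post_to_pred)
        if sorted(self.post_to_pred.tolist()) != list(range(n)):
            raise ValueError("matching is not a bijection")

    def __len__(self) -> int:
        return len(self.post_to_pred)

    @property
    def pred_to_post(self) -> np.ndarray:
        inv = np.empty_like(self.post_to_pred)
        inv[self.post_to_pred] = np.arange(len(self.post_to_pred))
        return inv


def pair_ensembles(pred: np.ndarray, post: np.ndarray) -> Matching:
    """Gale-Shapley stable matching minimizing pairwise macro change.

    Posterior samples propose; both sides rank the other by ascending
    Euclidean distance in transformed macro space, ties broken by lower
    index.  The result contains no blocking pair.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    if pred.shape != post.shape:
        raise ValueError("ensembles must have equal size and dimension")
    n = pred.shape[0]
    d2 = ((post[:, None, :] - pred[None, :, :]) ** 2).sum(axis=-1)
    pref = np.argsort(d2, axis=1, kind="stable")  # proposer preference lists
    next_choice = np.zeros(n, dtype=int)
    holder = np.full(n, -1, dtype=int)  # pred j currently holds posterior holder[j]
    free = list(range(n - 1, -1, -1))
    while free:
        i = free.pop()
        j = int(pref[i, next_choice[i]])
        next_choice[i] += 1
        k = holder[j]
        if k == -1:
            holder[j] = i
        elif (d2[i, j], i) < (d2[k, j], k):
            holder[j] = i
            free.append(k)
        else:
            free.append(i)
    post_to_pred = np.empty(n, dtype=int)
    post_to_pred[holder] = np.arange(n)
    return Matching(post_to_pred)


# ---------------------------------------------------------------------------
# rounding and one-hot machinery


def largest_remainder(values, total: int | None = None) -> np.ndarray:
    """Round nonnegative reals to integers preserving their (rounded) sum.

    Floors every entry, then distributes the remaining units to the largest
    fractional parts (ties to lower index).  If ``total`` is given the result
    sums to it exactly.
    """
    values = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if total is None:
        total = int(round(values.sum()))
    base = np.floor(values).astype(int)
    short = total - int(base.sum())
    if short < 0:
        # target total below the floor sum: trim from smallest fractional parts
        order = np.lexsort((np.arange(len(values)), values - base))
        for i in order:
            if short == 0:
                break
            take = min(base[i], -short)
            base[i] -= take
            short += take
        return base
    frac = values - base
    order = np.lexsort((np.arange(len(values)), -frac))
    base[order[:short]] += 1
    return base


def one_hot_encode(grid: np.ndarray, n_categories: int) -> np.ndarray:
    """Map a categorical lattice to a lattice of standard basis vectors."""
    grid = np.asarray(grid)
    if grid.min(initial=0) < 0 or grid.max(initial=0) >= n_categories:
        raise ValueError("grid contains categories outside the declared list")
    return np.eye(n_categories)[grid]


def one_hot_decode(field: np.ndarray) -> np.ndarray:
    return np.argmax(field, axis=-1)


def rescale_onehot(field: np.ndarray, old_counts, new_counts) -> np.ndarray:
    """Componentwise rescale so that the site-sum equals ``new_counts``.

    Component j is multiplied by ``new_counts[j] / old_counts[j]``; a
    category absent from the seed but demanded by the target is spread
    uniformly over all sites.
    """
    field = np.asarray(field, dtype=float)
    old_counts = np.asarray(old_counts, dtype=float)
    new_counts = np.asarray(new_counts, dtype=float)
    if np.any(new_counts < 0):
        raise ValueError("new_counts must be nonnegative")
    if not math.isclose(old_counts.sum(), new_counts.sum(), rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("old and new count totals differ")
    ratio = np.ones_like(old_counts)
    nz = old_counts > 0
    ratio[nz] = new_counts[nz] / old_counts[nz]
    out = field * ratio
    n_sites = field.size // field.shape[-1]
    born = (~nz) & (new_counts > 0)
    out[..., born] = new_counts[born] / n_sites
    return out


# ---------------------------------------------------------------------------
# quantization with error diffusion


@dataclass(frozen=True)
class QuantizationConfig:
    """Loss weights and numerics for the quantize/error-diffuse pass.

    The per-site loss is ``l1*|q - s|^2 + l2*(-log(c.q + smoothing)) +
    l3*(-log p_model(neighborhood))`` where ``c`` counts categories among the
    site's 8 neighbors and ``p_model`` is an empirical neighborhood model
    fitted on earlier runs.
    """

    l1: float = 1.0
    l2: float = 1.0
    l3: float = 1.0
    smoothing: float = 1.0
    n_field_bins: int = 8

    def __post_init__(self) -> None:
        if self.l1 < 0 or self.l2 < 0 or self.l3 < 0:
            raise ValueError("loss weights must be nonnegative")
        if not (self.l1 > 0 or self.l2 > 0 or self.l3 > 0):
            raise ValueError("at least one loss weight must be positive")
        if self.smoothing <= 0:
            raise ValueError("smoothing constant must be positive")


_PAD = -1  # off-lattice sentinel in neighborhood keys


class NeighborhoodModel:
    """Smoothed histogram over discretized 3x3 local configurations.

    A configuration is the tuple of the nine cell categories (off-lattice
    positions padded with -1) together with a log-binned local field level at
    the center.  Add-one smoothing reserves one unit of mass for any unseen
    configuration, so ``-log p`` is finite for every query.
    """

    def __init__(self, counts: dict, total: int, bin_edges: np.ndarray):
        self.counts = counts
        self.total = total
        self.bin_edges = np.asarray(bin_edges, dtype=float)

    @classmethod
    def fit(cls, grids, fields, n_bins: int = 8) -> "NeighborhoodModel":
        """Histogram all 3x3 configurations of the training grids.

        ``grids`` and ``fields`` are parallel collections of categorical
        lattices and nonnegative field lattices (for the level binning).
        """
        grids = [np.asarray(g) for g in grids]
        fields = [np.asarray(f, dtype=float) for f in fields]
        if not grids:
            raise ValueError("empty training set")
        log_vals = np.concatenate([np.log1p(f).ravel() for f in fields])
        top = float(log_vals.max()) if log_vals.size else 0.0
        if top <= 0:
            edges = np.array([])
        else:
            edges = np.linspace(0.0, top, n_bins + 1)[1:-1]
        counts: dict = {}
        total = 0
        for g, f in zip(grids, fields):
            padded = np.pad(g, 1, mode="constant", constant_values=_PAD)
            w, h = g.shape
            bins = np.digitize(np.log1p(f), edges) if edges.size else np.zeros_like(f, dtype=int)
            for x in range(w):
                for y in range(h):
                    key = (tuple(padded[x : x + 3, y : y + 3].ravel()), int(bins[x, y]))
                    counts[key] = counts.get(key, 0) + 1
                    total += 1
        return cls(counts, total, edges)

    def probability(self, patch3x3, field_value: float) -> float:
        key = (tuple(np.asarray(patch3x3).ravel()), self.bin_of(field_value))
        denom = self.total + len(self.counts) + 1
        return (self.counts.get(key, 0) + 1) / denom

    def bin_of(self, field_value: float) -> int:
        if self.bin_edges.size == 0:
            return 0
        return int(np.digitize(np.log1p(field_value), self.bin_edges))

    def neg_log_prob(self, patch3x3, field_value: float) -> float:
        return -math.log(self.probability(patch3x3, field_value))


def build_neighborhood_model(
    training_microstates, n_bins: int = 8
) -> dict:
    """Fit neighborhood models for both categorical lattices of the viral ABM.

    Uses the proinflammatory cytokine as the local field level, since it
    tracks the infection hot-spots most directly.  Returns a dict with
    ``"epithelium"`` and ``"endothelium"`` models.
    """
    micros = list(training_microstates)
    if not micros:
        raise ValueError("empty training set")
    pro = [m.cytokines["proinflammatory"].values for m in micros]
    return {
        "epithelium": NeighborhoodModel.fit([m.epithelium for m in micros], pro, n_bins),
        "endothelium": NeighborhoodModel.fit([m.endothelium for m in micros], pro, n_bins),
    }


_MOORE = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


def _site_losses(
    s: np.ndarray,
    feasible: np.ndarray,
    cfg: QuantizationConfig,
    neighbor_counts: np.ndarray,
    patch_labels: np.ndarray,
    field_value: float,
    model: "NeighborhoodModel | None",
) -> np.ndarray:
    k = len(s)
    losses = np.full(k, np.inf)
    for c in range(k):
        if not feasible[c]:
            continue
        loss = 0.0
        if cfg.l1 > 0:
            diff = -s.copy()
            diff[c] += 1.0
            loss += cfg.l1 * float(diff @ diff)
        if cfg.l2 > 0:
            loss += cfg.l2 * -math.log(neighbor_counts[c] + cfg.smoothing)
        if cfg.l3 > 0 and model is not None:
            patch = patch_labels.copy()
            patch[4] = c  # center of the flattened 3x3 patch
            loss += cfg.l3 * model.neg_log_prob(patch, field_value)
        losses[c] = loss
    return losses


def _provisional_labels(work: np.ndarray, labels: np.ndarray) -> np.ndarray:
    prov = np.argmax(work, axis=-1)
    assigned = labels >= 0
    prov[assigned] = labels[assigned]
    return prov


def _patch_of(arr: np.ndarray, x: int, y: int) -> np.ndarray:
    w, h = arr.shape
    out = np.full(9, _PAD, dtype=int)
    i = 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                out[i] = arr[nx, ny]
            i += 1
    return out


def _improve_labels(cost: np.ndarray, labels: np.ndarray, max_rounds: int = 200) -> np.ndarray:
    """Greedy repair by lowest-delta relabeling cycles.

    ``cost`` is the (n_sites, k) per-site label cost; counts are preserved
    because relabels are applied along category cycles.  For a separable cost
    this terminates at the transportation optimum (no negative residual
    cycle remains).
    """
    n, k = cost.shape
    labels = labels.copy()
    for _ in range(max_rounds):
        # w[a, b]: cheapest increase from moving one site labeled a to label b
        w = np.full((k, k), np.inf)
        arg = np.full((k, k), -1, dtype=int)
        for a in range(k):
            sites = np.flatnonzero(labels == a)
            if len(sites) == 0:
                continue
            delta = cost[sites] - cost[sites, a][:, None]
            best = np.argmin(delta, axis=0)
            w[a] = delta[best, np.arange(k)]
            arg[a] = sites[best]
            w[a, a] = np.inf
        # negative-cycle search by Floyd-Warshall with path tracking
        dist = w.copy()
        nxt = np.where(np.isfinite(w), np.arange(k)[None, :], -1)
        for m in range(k):
            via = dist[:, m][:, None] + dist[m][None, :]
            better = via < dist - 1e-12
            dist = np.where(better, via, dist)
            nxt = np.where(better, nxt[:, m][:, None], nxt)
        starts = np.flatnonzero(np.diag(dist) < -1e-9)
        if len(starts) == 0:
            break
        a0 = int(starts[np.argmin(np.diag(dist)[starts])])
        # walk the cycle a0 -> ... -> a0, relabel one site per edge
        cycle = [a0]
        cur = a0
        while True:
            cur = int(nxt[cur, a0])
            if cur == a0 or cur in cycle:
                break
            cycle.append(cur)
        cycle.append(a0)
        moved = set()
        ok = True
        for a, b in zip(cycle[:-1], cycle[1:]):
            site = int(arg[a, b])
            if site < 0 or site in moved:
                ok = False
                break
            moved.add(site)
        if not ok:
            break
        for a, b in zip(cycle[:-1], cycle[1:]):
            labels[int(arg[a, b])] = b
    return labels


def quantize_error_diffuse(
    field: np.ndarray,
    target_counts,
    cfg: QuantizationConfig,
    model: "NeighborhoodModel | None",
    rng: np.random.Generator,
    field_levels: np.ndarray | None = None,
    return_details: bool = False,
):
    """Quantize a rescaled one-hot field back to categories, diffusing error.

    Sites are visited in a seeded random permutation.  At each site the
    feasible categories are those whose remaining quota is at least one; the
    minimum-loss basis vector is chosen and the residual ``q - s`` is spread
    uniformly (negated) over the unquantized 8-neighbors, so total vector
    mass is conserved mid-pass; sites with no unquantized neighbor push their
    residual onto a global accumulator.  A final repair phase applies
    lowest-delta label cycles until no strictly loss-reducing relabeling
    remains, keeping counts exactly at ``target_counts``.
    """
    field = np.asarray(field, dtype=float)
    w, h, k = field.shape
    target_counts = np.asarray(target_counts, dtype=int)
    if target_counts.shape != (k,) or np.any(target_counts < 0):
        raise ValueError("target_counts must be k nonnegative integers")
    if int(target_counts.sum()) != w * h:
        raise ValueError("target counts must sum to the number of sites")
    if field_levels is None:
        field_levels = np.zeros((w, h))
    work = field.copy()
    labels = np.full((w, h), -1, dtype=int)
    remaining = target_counts.copy()
    residual = np.zeros(k)
    mass_trace = [float(work.sum() + residual.sum())] if return_details else None
    order = rng.permutation(w * h)
    for lin in order:
        x, y = divmod(int(lin), h)
        s = work[x, y]
        feasible = remaining >= 1
        prov = _provisional_labels(work, labels)
        counts = np.zeros(k)
        unq: list = []
        for dx, dy in _MOORE:
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                counts[prov[nx, ny]] += 1
                if labels[nx, ny] < 0:
                    unq.append((nx, ny))
        patch = _patch_of(prov, x, y) if (cfg.l3 > 0 and model is not None) else np.empty(0, dtype=int)
        losses = _site_losses(s, feasible, cfg, counts, patch, float(field_levels[x, y]), model)
        c = int(np.argmin(losses))  # ties resolve to the lower category index
        labels[x, y] = c
        remaining[c] -= 1
        delta = -s.copy()
        delta[c] += 1.0
        work[x, y] = np.eye(k)[c]
        if unq:
            share = delta / len(unq)
            for nx, ny in unq:
                work[nx, ny] -= share
        else:
            residual -= delta  # absorbs the error so lattice+residual mass is constant
        if return_details:
            mass_trace.append(float(work.sum() + residual.sum()))

    # repair: per-site costs against the *original* field, neighborhood terms
    # in the final label context
    flat_labels = labels.ravel()
    cost = np.empty((w * h, k))
    prov = labels
    for lin in range(w * h):
        x, y = divmod(lin, h)
        counts = np.zeros(k)
        for dx, dy in _MOORE:
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h:
                counts[prov[nx, ny]] += 1
        patch = _patch_of(prov, x, y) if (cfg.l3 > 0 and model is not None) else np.empty(0, dtype=int)
        cost[lin] = _site_losses(
            field[x, y], np.ones(k, dtype=bool), cfg, counts, patch,
            float(field_levels[x, y]), model,
        )
    flat_labels = _improve_labels(cost, flat_labels)
    out = flat_labels.reshape(w, h)
    if np.any(np.bincount(out.ravel(), minlength=k) != target_counts):
        raise AssertionError("quantization failed to meet target counts")
    if return_details:
        return out, {"residual": residual, "mass_trace": np.array(mass_trace)}
    return out


# ---------------------------------------------------------------------------
# molecular fields and whole-microstate synthesis


def rescale_molecular(field: MolecularField, new_total: float) -> MolecularField:
    """Scale a field to a new total; preserves spatial correlations exactly."""
    if new_total < 0:
        raise ValueError("new_total must be nonnegative")
    old_total = field.total
    out = field.copy()
    if new_total == 0.0:
        out.values = np.zeros_like(out.values)
    elif old_total == 0.0:
        out.values = np.full_like(out.values, new_total / out.values.size)
    else:
        out.values = out.values * (new_total / old_total)
    return out


def _viral_targets(target: MacroVector, n_sites: int) -> dict:
    epi = largest_remainder(
        [target[f"epi_{c.lower()}"] for c in EPI_CATEGORIES], total=n_sites
    )
    endo = largest_remainder(
        [target[f"endo_{c.lower()}"] for c in ENDO_CATEGORIES], total=n_sites
    )
    return {
        "epi": epi,
        "endo": endo,
        "totals": {
            "virus": max(0.0, target["total_virus"]),
            "antiviral": max(0.0, target["total_antiviral"]),
            "proinflammatory": max(0.0, target["total_proinflammatory"]),
            "damage": max(0.0, target["total_damage"]),
        },
        "immune": max(0, int(round(target["immune_count"]))),
        "apoptosis": max(0, int(round(target["apoptosis_by_virus"]))),
    }


def _relabel_random(grid: np.ndarray, new_counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Minimal random relabeling: exactly half the L1 count distance changes."""
    k = len(new_counts)
    out = grid.copy()
    flat = out.ravel()
    cur = np.bincount(flat, minlength=k)
    diff = new_counts - cur
    donors: list = []
    for c in np.flatnonzero(diff < 0):
        sites = np.flatnonzero(flat == c)
        donors.extend(rng.choice(sites, size=-diff[c], replace=False).tolist())
    recipients = np.repeat(np.flatnonzero(diff > 0), diff[diff > 0])
    donors = np.array(donors, dtype=int)
    if len(donors) != len(recipients):
        raise ValueError("infeasible relabeling targets")
    if len(donors):
        flat[rng.permutation(donors)] = recipients
    return out


def _match_immune(
    agents: list,
    n_target: int,
    weight_field: np.ndarray | None,
    rng: np.random.Generator,
) -> list:
    agents = list(agents)
    if n_target < len(agents):
        keep = rng.choice(len(agents), size=n_target, replace=False)
        return [agents[i] for i in sorted(keep)]
    n_new = n_target - len(agents)
    if n_new == 0:
        return agents
    kill = agents[0].kill_prob if agents else 0.5
    shape = weight_field.shape if weight_field is not None else None
    if weight_field is not None and weight_field.sum() > 0:
        p = (weight_field / weight_field.sum()).ravel()
        sites = rng.choice(weight_field.size, size=n_new, p=p)
    elif weight_field is not None:
        sites = rng.integers(weight_field.size, size=n_new)
    else:
        raise ValueError("weight_field required to place new agents")
    for s in sites:
        agents.append(ImmuneAgent(tuple(np.unravel_index(int(s), shape)), kill))
    return agents


def simple_synthesis_viral(
    target: MacroVector, seed: ViralMicrostate, rng: np.random.Generator
) -> ViralMicrostate:
    """Geometry-blind synthesis: uniform random relabeling and field scaling."""
    t = _viral_targets(target, seed.epithelium.size)
    out = seed.copy()
    out.epithelium = _relabel_random(seed.epithelium, t["epi"], rng)
    out.endothelium = _relabel_random(seed.endothelium, t["endo"], rng)
    out.virus = rescale_molecular(seed.virus, t["totals"]["virus"])
    for name in ("antiviral", "proinflammatory", "damage"):
        out.cytokines[name] = rescale_molecular(seed.cytokines[name], t["totals"][name])
    uniform = np.ones(seed.epithelium.shape)
    out.immune_agents = _match_immune(seed.immune_agents, t["immune"], uniform, rng)
    out.apoptosis_by_virus_count = t["apoptosis"]
    return out


def spatial_synthesis_viral(
    target: MacroVector,
    seed: ViralMicrostate,
    cfg: QuantizationConfig | None = None,
    models: dict | None = None,
    rng: np.random.Generator | None = None,
) -> ViralMicrostate:
    """Spatially aware synthesis via one-hot -> rescale -> quantize/diffuse.

    Both categorical lattices go through the 3-step pipeline; molecular
    fields are rescaled in place; immune agents are placed proportional to
    the proinflammatory field.
    """
    if rng is None:
        rng = np.random.default_rng()
    if cfg is None:
        cfg = QuantizationConfig(l3=0.0) if models is None else QuantizationConfig()
    t = _viral_targets(target, seed.epithelium.size)
    out = seed.copy()

    out.virus = rescale_molecular(seed.virus, t["totals"]["virus"])
    for name in ("antiviral", "proinflammatory", "damage"):
        out.cytokines[name] = rescale_molecular(seed.cytokines[name], t["totals"][name])
    levels = out.cytokines["proinflammatory"].values

    for attr, cats, tgt, key in (
        ("epithelium", len(EPI_CATEGORIES), t["epi"], "epithelium"),
        ("endothelium", len(ENDO_CATEGORIES), t["endo"], "endothelium"),
    ):
        grid = getattr(seed, attr)
        old_counts = np.bincount(grid.ravel(), minlength=cats)
        encoded = one_hot_encode(grid, cats)
        rescaled = rescale_onehot(encoded, old_counts, tgt)
        model = models.get(key) if models else None
        setattr(
            out,
            attr,
            quantize_error_diffuse(rescaled, tgt, cfg, model, rng, field_levels=levels),
        )

    out.immune_agents = _match_immune(seed.immune_agents, t["immune"], levels, rng)
    out.apoptosis_by_virus_count = t["apoptosis"]
    return out
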