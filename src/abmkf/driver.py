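"""Orchestration of the assimilation loop on agent-based models.

One assimilation cycle comprises five steps: advance the microstate ensemble
with the model, summarize microstates to macrostates, update the macro
ensemble with the ensemble Kalman filter when a measurement arrives, sample
a fresh macro ensemble from the posterior, and synthesize a compatible
microstate for every posterior sample (seeded from its stably-matched
predictive member).  Model parameters that vary between individuals ride
along as extra macro components: each ensemble member is simulated under its
own parameter values, and random-walk process noise is applied to the
parameter block only.

Virtual patients — simulated true trajectories with known parameters — are
the ground truth for twin experiments: parameters are drawn from the prior,
the microstate starts in a known onset configuration, and noisy measurements
of selected transformed macro components are recorded on a fixed schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import viral as viral_mod
from . import wsg as wsg_mod
from .enkf import (
    DEFAULT_JITTER,
    GaussianBelief,
    MeasurementSpec,
    add_parameter_process_noise,
    enkf_update,
    fit_gaussian,
    sample_ensemble,
)
from .evaluation import SurprisalSeries, gaussian_surprisal
from .macrostate import MacroSchema, MacroVector, default_wsg_schema, identity
from .synthesis import (
    QuantizationConfig,
    pair_ensembles,
    simple_synthesis_viral,
    spatial_synthesis_viral,
)

__all__ = [
    "SeedSet",
    "ExperimentConfig",
    "VirtualPatient",
    "AssimilationResult",
    "default_wsg_config",
    "default_viral_config",
    "make_virtual_patient",
    "run_abmkf",
    "twin_cohort",
]

CONFIG_VERSION = "abmkf-config/1"


@dataclass(frozen=True)
class SeedSet:
    """One named seed per random stream."""

    patient: int = 1
    ensemble: int = 2
    filter: int = 3
    synthesis: int = 4


@dataclass(frozen=True)
class ExperimentConfig:
    model: str = "wsg"
    model_params: dict = field(default_factory=dict)
    parameter_names: tuple = ()
    param_bounds: dict = field(default_factory=dict)
    prior_mean: tuple = ()  # transformed space, state then parameters
    prior_cov_diag: tuple = ()
    ensemble_size: int = 50
    horizon: int = 200
    observed: tuple = ("sheep",)
    r_diag: tuple = (0.01,)
    measurement_interval: int = 20
    q_param: tuple = ()
    jitter: float = DEFAULT_JITTER
    synthesis: str = "simple"  # viral model only: simple | spatial
    n_seed_infections: int = 3
    quantization: QuantizationConfig = field(default_factory=lambda: QuantizationConfig(l3=0.0))
    seeds: SeedSet = field(default_factory=SeedSet)

    def __post_init__(self) -> None:
        if self.model not in ("wsg", "viral_min"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.ensemble_size < 2:
            raise ValueError("ensemble size must be >= 2")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.synthesis not in ("simple", "spatial"):
            raise ValueError(f"unknown synthesis algorithm {self.synthesis!r}")

    # -- derived objects ----------------------------------------------------

    def adapter(self) -> "_ModelAdapter":
        if self.model == "wsg":
            return _WSGAdapter(self)
        return _ViralAdapter(self)

    def schema(self) -> MacroSchema:
        return self.adapter().schema

    def schedule(self) -> tuple:
        iv = self.measurement_interval
        if iv <= 0:
            return ()
        return tuple(range(iv, self.horizon + 1, iv))

    def measurement_spec(self) -> MeasurementSpec:
        return MeasurementSpec(self.observed, np.asarray(self.r_diag), self.schedule())

    def prior(self) -> GaussianBelief:
        mean = np.asarray(self.prior_mean, dtype=float)
        cov = np.diag(np.asarray(self.prior_cov_diag, dtype=float))
        if mean.shape[0] != len(self.schema()):
            raise ValueError("prior dimension does not match schema")
        return GaussianBelief(mean, cov)

    # -- functional updates -------------------------------------------------

    def with_measurement(self, observed, r_diag) -> "ExperimentConfig":
        return replace(self, observed=tuple(observed), r_diag=tuple(float(r) for r in r_diag))

    def with_seeds(self, patient, ensemble, filter, synthesis) -> "ExperimentConfig":
        return replace(
            self,
            seeds=SeedSet(int(patient), int(ensemble), int(filter), int(synthesis)),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "version": CONFIG_VERSION,
            "model": self.model,
            "model_params": self.model_params,
            "parameter_names": list(self.parameter_names),
            "param_bounds": {k: list(v) for k, v in self.param_bounds.items()},
            "prior_mean": list(self.prior_mean),
            "prior_cov_diag": list(self.prior_cov_diag),
            "ensemble_size": self.ensemble_size,
            "horizon": self.horizon,
            "observed": list(self.observed),
            "r_diag": list(self.r_diag),
            "measurement_interval": self.measurement_interval,
            "q_param": list(self.q_param),
            "jitter": self.jitter,
            "synthesis": self.synthesis,
            "n_seed_infections": self.n_seed_infections,
            "quantization": {
                "l1": self.quantization.l1,
                "l2": self.quantization.l2,
                "l3": self.quantization.l3,
                "smoothing": self.quantization.smoothing,
                "n_field_bins": self.quantization.n_field_bins,
            },
            "seeds": {
                "patient": self.seeds.patient,
                "ensemble": self.seeds.ensemble,
                "filter": self.seeds.filter,
                "synthesis": self.seeds.synthesis,
            },
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        version = d.pop("version", None)
        if version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version: {version!r}")
        q = d.pop("quantization", {})
        s = d.pop("seeds", {})
        for key in ("parameter_names", "prior_mean", "prior_cov_diag", "observed", "r_diag", "q_param"):
            if key in d:
                d[key] = tuple(d[key])
        if "param_bounds" in d:
            d["param_bounds"] = {k: tuple(v) for k, v in d["param_bounds"].items()}
        try:
            return cls(
                quantization=QuantizationConfig(**q),
                seeds=SeedSet(**s),
                **d,
            )
        except TypeError as exc:
            raise ValueError(f"malformed config: {exc}") from exc


# ---------------------------------------------------------------------------
# model adapters


class _ModelAdapter:
    """Uniform surface over a simulator: init, step, summarize, synthesize."""

    schema: MacroSchema
    n_state: int

    def clamp_params(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, dtype=float)
        for j, name in enumerate(self.param_names):
            lo, hi = self.bounds[name]
            out[j] = min(max(out[j], lo), hi)
        return out


class _WSGAdapter(_ModelAdapter):
    DEFAULT_BOUNDS = {
        "wolf_reproduce_prob": (0.0, 1.0),
        "sheep_reproduce_prob": (0.0, 1.0),
        "wolf_gain_from_food": (0.0, np.inf),
        "sheep_gain_from_food": (0.0, np.inf),
        "grass_regrowth_time": (1, 10_000),
        "init_grass_density": (0.0, 1.0),
    }

    def __init__(self, config: ExperimentConfig):
        self.base_params = wsg_mod.WSGParams(**config.model_params)
        self.param_names = tuple(config.parameter_names)
        self.bounds = {
            n: config.param_bounds.get(n, self.DEFAULT_BOUNDS.get(n, (-np.inf, np.inf)))
            for n in self.param_names
        }
        self.schema = default_wsg_schema(self.param_names)
        self.n_state = 3

    def make_params(self, values: np.ndarray) -> wsg_mod.WSGParams:
        vals = self.clamp_params(values)
        kw = {}
        for name, v in zip(self.param_names, vals):
            kw[name] = int(round(v)) if name == "grass_regrowth_time" else float(v)
        return replace(self.base_params, **kw)

    def init_patient(self, params, rng) -> wsg_mod.WSGMicrostate:
        return wsg_mod.init_wsg(params, rng)

    def init_member(self, state_raw, params, rng) -> wsg_mod.WSGMicrostate:
        base = wsg_mod.init_wsg(params, rng)
        return self.synthesize(state_raw, base, params, rng)

    def step(self, micro, params, rng):
        return wsg_mod.step_wsg(micro, params, rng)

    def summarize(self, micro) -> np.ndarray:
        return wsg_mod.summarize_wsg(micro).values

    def synthesize(self, state_raw, seed_micro, params, rng):
        target = np.clip(np.asarray(state_raw, dtype=float), 0.0, None)
        target[2] = min(target[2], params.n_patches)
        return wsg_mod.synthesize_wsg(target, seed_micro, params, rng)


class _ViralAdapter(_ModelAdapter):
    DEFAULT_BOUNDS = {
        "infect_rate": (0.0, np.inf),
        "virus_production": (0.0, np.inf),
        "apoptosis_rate": (0.0, 1.0),
        "necrosis_rate": (0.0, 1.0),
        "immune_recruitment": (0.0, np.inf),
        "immune_kill_prob": (0.0, 1.0),
    }

    def __init__(self, config: ExperimentConfig):
        self.base_params = viral_mod.ViralParams(**config.model_params)
        self.param_names = tuple(config.parameter_names)
        self.bounds = {
            n: config.param_bounds.get(n, self.DEFAULT_BOUNDS.get(n, (-np.inf, np.inf)))
            for n in self.param_names
        }
        self.schema = viral_mod.default_viral_schema(
            self.base_params.n_sites, self.param_names
        )
        self.n_state = len(viral_mod.MACRO_NAMES)
        self.state_schema = viral_mod.default_viral_schema(self.base_params.n_sites)
        self.n_seed_infections = config.n_seed_infections
        self.synthesis_algorithm = config.synthesis
        self.quantization = config.quantization
        self.models = None  # optional neighborhood models for spatial synthesis

    def make_params(self, values: np.ndarray) -> viral_mod.ViralParams:
        vals = self.clamp_params(values)
        kw = {name: float(v) for name, v in zip(self.param_names, vals)}
        return replace(self.base_params, **kw)

    def init_patient(self, params, rng):
        return viral_mod.init_viral(params, self.n_seed_infections, rng)

    def init_member(self, state_raw, params, rng):
        base = viral_mod.init_viral(params, self.n_seed_infections, rng)
        return self.synthesize(state_raw, base, params, rng)

    def step(self, micro, params, rng):
        return viral_mod.step_viral(micro, params, rng)

    def summarize(self, micro) -> np.ndarray:
        return viral_mod.summarize_viral(micro).values

    def synthesize(self, state_raw, seed_micro, params, rng):
        target = MacroVector(
            self.state_schema, np.clip(np.asarray(state_raw, dtype=float), 0.0, None)
        )
        if self.synthesis_algorithm == "spatial":
            return spatial_synthesis_viral(
                target, seed_micro, self.quantization, self.models, rng
            )
        return simple_synthesis_viral(target, seed_micro, rng)


# ---------------------------------------------------------------------------
# default experiment configurations


def default_wsg_config(**overrides) -> ExperimentConfig:
    """Predator-prey twin experiment at desk scale.

    Prior (transformed space): the onset state is known up to small noise
    (wolves ~ log(eps + 50), sheep ~ 100 x 0.1, grass ~ half coverage x
    0.01); individual variation lives in the two reproduction probabilities.
    """
    params = wsg_mod.WSGParams()
    grass0 = params.init_grass_density * params.n_patches
    defaults = dict(
        model="wsg",
        parameter_names=("wolf_reproduce_prob", "sheep_reproduce_prob"),
        prior_mean=(
            float(np.log(1e-3 + params.init_wolves)),
            0.1 * params.init_sheep,
            0.01 * grass0,
            0.05,
            0.04,
        ),
        prior_cov_diag=(0.1**2, 0.5**2, 0.3**2, 0.02**2, 0.015**2),
        ensemble_size=50,
        horizon=200,
        observed=("sheep",),
        r_diag=(0.01,),
        measurement_interval=20,
        q_param=(1e-6, 1e-6),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


def default_viral_config(**overrides) -> ExperimentConfig:
    """Viral twin experiment on a 25x25 test lattice."""
    width = overrides.pop("width", 25)
    height = overrides.pop("height", 25)
    n_sites = width * height
    schema = viral_mod.default_viral_schema(n_sites)
    onset = np.zeros(len(schema))
    n_seed = 3
    onset[schema.index("epi_healthy")] = n_sites - n_seed
    onset[schema.index("epi_infected")] = n_seed
    onset[schema.index("endo_normal")] = n_sites
    onset[schema.index("total_virus")] = n_seed * 1.0
    mean_t = schema.to_transformed(onset)
    prior_mean = tuple(mean_t) + (0.5, 0.03)
    prior_cov = tuple([0.05**2] * len(schema)) + (0.1**2, 0.01**2)
    defaults = dict(
        model="viral_min",
        model_params={"width": width, "height": height},
        parameter_names=("infect_rate", "apoptosis_rate"),
        prior_mean=prior_mean,
        prior_cov_diag=prior_cov,
        ensemble_size=30,
        horizon=60,
        observed=("total_virus",),
        r_diag=(0.1,),
        measurement_interval=10,
        q_param=(1e-6, 1e-8),
        n_seed_infections=n_seed,
        synthesis="simple",
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


# ---------------------------------------------------------------------------
# virtual patients and the assimilation loop


@dataclass
class VirtualPatient:
    parameters: np.ndarray  # natural units, in parameter_names order
    true_macro: np.ndarray  # (horizon+1, n_state) natural units
    measurements: dict  # time -> transformed observed vector (noise added)
    micro_trajectory: list | None = None

    def true_transformed(self, schema: MacroSchema, t: int) -> np.ndarray:
        full = np.concatenate([self.true_macro[t], self.parameters])
        return schema.to_transformed(full)


@dataclass
class AssimilationResult:
    times: np.ndarray
    predictive_mean: np.ndarray  # (horizon+1, d) transformed
    predictive_std: np.ndarray  # (horizon+1, d) marginal std, transformed
    surprisal: SurprisalSeries  # predictive (pre-update) at every step
    post_surprisal: dict  # measurement time -> post-update surprisal
    posterior_means: dict  # measurement time -> posterior mean (transformed)
    final_ensemble: np.ndarray


def make_virtual_patient(
    config: ExperimentConfig,
    rng: np.random.Generator | None = None,
    store_micro: bool = False,
    max_attempts: int = 100,
) -> VirtualPatient:
    """Simulate one true trajectory with parameters drawn from the prior."""
    if rng is None:
        rng = np.random.default_rng(config.seeds.patient)
    adapter = config.adapter()
    schema = adapter.schema
    prior = config.prior()
    pmask = schema.parameter_mask
    pidx = np.flatnonzero(pmask)

    params_nat = None
    for _ in range(max_attempts):
        draw = sample_ensemble(prior, 2, rng, jitter=0.0)[0]
        nat = schema.from_transformed(draw)
        cand = nat[pidx]
        clamped = adapter.clamp_params(cand)
        if np.allclose(cand, clamped, atol=1e-12):
            params_nat = clamped
            break
    if params_nat is None:
        # fall back to the clamped draw rather than refusing the patient
        params_nat = adapter.clamp_params(cand)
    params = adapter.make_params(params_nat)

    micro = adapter.init_patient(params, rng)
    macro = [adapter.summarize(micro)]
    micros = [micro] if store_micro else None
    for _ in range(config.horizon):
        micro = adapter.step(micro, params, rng)
        macro.append(adapter.summarize(micro))
        if store_micro:
            micros.append(micro)
    true_macro = np.array(macro)

    obs_idx = schema.indices(config.observed)
    r_diag = np.asarray(config.r_diag, dtype=float)
    measurements = {}
    for t in config.schedule():
        full = np.concatenate([true_macro[t], params_nat])
        z = schema.to_transformed(full)[obs_idx]
        noise = rng.standard_normal(len(obs_idx)) * np.sqrt(r_diag)
        measurements[t] = z + noise
    return VirtualPatient(params_nat, true_macro, measurements, micros)


def twin_cohort(
    config: ExperimentConfig,
    n_patients: int,
    base_seed: int = 0,
    include_baseline: bool = False,
) -> list:
    """Run twin experiments on a cohort of virtual patients.

    Per patient, four stream seeds are derived from ``(base_seed, patient)``;
    when ``include_baseline`` is set the same patient is additionally run as
    a pure ensemble forecast (no measurements).  Returns a list of
    ``(patient, filtered_result, baseline_result_or_None)`` triples.
    """
    out = []
    for i in range(n_patients):
        ss = np.random.SeedSequence([base_seed, i])
        seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(4)]
        cfg = config.with_seeds(*seeds)
        patient = make_virtual_patient(cfg)
        filtered = run_abmkf(cfg, patient)
        baseline = None
        if include_baseline:
            baseline = run_abmkf(replace(cfg, measurement_interval=0), patient)
        out.append((patient, filtered, baseline))
    return out


def run_abmkf(config: ExperimentConfig, patient: VirtualPatient) -> AssimilationResult:
    """Run the five-step assimilation loop against one virtual patient."""
    adapter = config.adapter()
    schema = adapter.schema
    d = len(schema)
    n = config.ensemble_size
    pmask = schema.parameter_mask
    pidx = np.flatnonzero(pmask)
    sidx = np.flatnonzero(~pmask)
    obs_idx = schema.indices(config.observed)
    r_diag = np.asarray(config.r_diag, dtype=float)
    q_param = np.asarray(config.q_param, dtype=float) if len(config.q_param) else np.zeros(len(pidx))
    schedule = set(config.schedule())

    rng_ens = np.random.default_rng(config.seeds.ensemble)
    rng_filter = np.random.default_rng(config.seeds.filter)
    rng_synth = np.random.default_rng(config.seeds.synthesis)

    ens = sample_ensemble(config.prior(), n, rng_ens, jitter=config.jitter)
    micros = []
    for i in range(n):
        nat = schema.from_transformed(ens[i])
        params_i = adapter.make_params(nat[pidx])
        micros.append(adapter.init_member(nat[sidx], params_i, rng_ens))
        # re-summarize so macro and micro agree exactly after rounding
        nat[sidx] = adapter.summarize(micros[i])
        ens[i] = schema.to_transformed(nat)

    T = config.horizon
    pred_mean = np.empty((T + 1, d))
    pred_std = np.empty((T + 1, d))
    surp = np.empty(T + 1)
    post_surprisal: dict = {}
    posterior_means: dict = {}

    def record(t: int) -> GaussianBelief:
        belief = fit_gaussian(ens)
        pred_mean[t] = belief.mean
        pred_std[t] = np.sqrt(np.clip(np.diag(belief.cov), 0.0, None))
        surp[t] = gaussian_surprisal(
            belief, patient.true_transformed(schema, t), jitter=max(config.jitter, 1e-8)
        )
        return belief

    record(0)
    for t in range(1, T + 1):
        for i in range(n):
            nat = schema.from_transformed(ens[i])
            params_i = adapter.make_params(nat[pidx])
            micros[i] = adapter.step(micros[i], params_i, rng_ens)
            nat[sidx] = adapter.summarize(micros[i])
            ens[i] = schema.to_transformed(nat)
        ens = add_parameter_process_noise(ens, q_param, pmask, rng_filter)
        record(t)
        if t in schedule:
            y = patient.measurements[t]
            post_belief, post_ens = enkf_update(
                ens, obs_idx, r_diag, y, rng_filter, jitter=config.jitter
            )
            match = pair_ensembles(ens, post_ens)
            new_micros = []
            for i in range(n):
                seed_micro = micros[int(match.post_to_pred[i])]
                nat = schema.from_transformed(post_ens[i])
                params_i = adapter.make_params(nat[pidx])
                new_micros.append(
                    adapter.synthesize(nat[sidx], seed_micro, params_i, rng_synth)
                )
                nat[sidx] = adapter.summarize(new_micros[i])
                post_ens[i] = schema.to_transformed(nat)
            micros = new_micros
            ens = post_ens
            post_fit = fit_gaussian(ens)
            posterior_means[t] = post_fit.mean
            post_surprisal[t] = gaussian_surprisal(
                post_fit,
                patient.true_transformed(schema, t),
                jitter=max(config.jitter, 1e-8),
            )

    return AssimilationResult(
        times=np.arange(T + 1),
        predictive_mean=pred_mean,
        predictive_std=pred_std,
        surprisal=SurprisalSeries(np.arange(T + 1), surp),
        post_surprisal=post_surprisal,
        posterior_means=posterior_means,
        final_ensemble=ens,
    )
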