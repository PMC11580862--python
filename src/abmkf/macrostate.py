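"""Macrostate vectors and per-component variable transforms.

A *macrostate* is a low-dimensional, named summary of an agent-based model's
full microstate (counts, totals, coverage fractions), optionally augmented
with model parameters that vary between individuals.  The Kalman filter is a
least-squares estimator, so components that differ by orders of magnitude
must be brought into comparable ranges by componentwise transforms before
filtering; counts with distributions concentrated near zero (e.g. a predator
species close to extinction) additionally benefit from a shifted log
transform whose inverse clamps at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Transform",
    "identity",
    "scale",
    "log_eps",
    "MacroSchema",
    "MacroVector",
    "default_wsg_schema",
]


@dataclass(frozen=True)
class Transform:
    """Componentwise monotone transform applied before filtering.

    kind is one of ``identity``, ``scale`` (multiply by ``c > 0``) or
    ``log_eps`` (``x -> log(eps + x)`` with inverse ``max(0, exp(y) - eps)``).
    """

    kind: str = "identity"
    c: float = 1.0
    eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "scale", "log_eps"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "scale" and not self.c > 0:
            raise ValueError("scale constant must be positive")
        if self.kind == "log_eps" and not self.eps > 0:
            raise ValueError("log_eps epsilon must be positive")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "scale":
            return self.c * x
        if np.any(x < 0):
            raise ValueError("log_eps transform requires nonnegative input")
        return np.log(self.eps + x)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        if self.kind == "scale":
            return y / self.c
        return np.maximum(0.0, np.exp(y) - self.eps)


def identity() -> Transform:
    return Transform("identity")


def scale(c: float) -> Transform:
    return Transform("scale", c=c)


def log_eps(eps: float = 1e-3) -> Transform:
    return Transform("log_eps", eps=eps)


@dataclass(frozen=True)
class MacroSchema:
    """Ordered component names with one transform and a parameter flag each."""

    names: tuple
    transforms: tuple
    is_parameter: tuple

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.transforms) == len(self.is_parameter)):
            raise ValueError("names/transforms/is_parameter lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate component names")

    @classmethod
    def build(cls, components: Iterable[tuple]) -> "MacroSchema":
        """Build from an iterable of (name, Transform, is_parameter) triples."""
        names, tfs, flags = [], [], []
        for name, tf, flag in components:
            names.append(name)
            tfs.append(tf)
            flags.append(bool(flag))
        return cls(tuple(names), tuple(tfs), tuple(flags))

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    @property
    def parameter_mask(self) -> np.ndarray:
        return np.array(self.is_parameter, dtype=bool)

    @property
    def state_mask(self) -> np.ndarray:
        return ~self.parameter_mask

    def to_transformed(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != len(self):
            raise ValueError("value length does not match schema")
        out = np.empty_like(values)
        for j, tf in enumerate(self.transforms):
            out[..., j] = tf.forward(values[..., j])
        return out

    def from_transformed(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != len(self):
            raise ValueError("value length does not match schema")
        out = np.empty_like(values)
        for j, tf in enumerate(self.transforms):
            out[..., j] = tf.inverse(values[..., j])
        return out

    def append(self, components: Iterable[tuple]) -> "MacroSchema":
        extra = MacroSchema.build(components)
        return MacroSchema(
            self.names + extra.names,
            self.transforms + extra.transforms,
            self.is_parameter + extra.is_parameter,
        )


@dataclass
class MacroVector:
    """Named macrostate values in natural (untransformed) units."""

    schema: MacroSchema
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError("values shape does not match schema")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])

    def to_transformed(self) -> np.ndarray:
        return self.schema.to_transformed(self.values)

    @classmethod
    def from_transformed(cls, vec, schema: MacroSchema) -> "MacroVector":
        return cls(schema, schema.from_transformed(vec))


def to_transformed(mv: MacroVector) -> np.ndarray:
    """Functional form of :meth:`MacroVector.to_transformed`."""
    return mv.to_transformed()


def from_transformed(vec, schema: MacroSchema) -> MacroVector:
    """Inverse transform a filtered vector back to natural units.

    Count-typed components are left real-valued; consumers that require
    integers (microstate synthesis) round at their end.
    """
    return MacroVector.from_transformed(vec, schema)


def default_wsg_schema(parameter_names: Sequence[str] = ()) -> MacroSchema:
    """Schema for the predator-prey model macrostate.

    Wolf counts concentrate near zero (extinctions are common), so they get
    the shifted log; sheep and grass counts run one and two orders of
    magnitude above the log-wolf scale and are scaled by 0.1 and 0.01 to keep
    all components in similar ranges.  Appended parameters are identity by
    default since they already sit near the log-wolf scale.
    """
    comps = [
        ("wolves", log_eps(1e-3), False),
        ("sheep", scale(0.1), False),
        ("grass", scale(0.01), False),
    ]
    comps += [(n, identity(), True) for n in parameter_names]
    return MacroSchema.build(comps)
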