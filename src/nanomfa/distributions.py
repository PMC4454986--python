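"""Probability distributions for uncertain model inputs.

Every quantity entering the material-flow model — production amounts,
product-allocation shares, transfer coefficients, compartment geometries —
is a nonnegative univariate distribution.  Where only a plausible range is
known a uniform distribution over that range is used; expert estimates with
a best guess become triangular; skewed production data lognormal; divergent
expert opinions an equally-weighted mixture.

Construction is deliberately lenient: :meth:`DistributionSpec.problems`
collects parameter violations as messages so a whole scenario file can be
validated in one pass.  Sampling a spec with problems raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import numpy as np
from scipy import stats

KINDS = (
    "point",
    "uniform",
    "triangular",
    "normal_truncated",
    "lognormal",
    "expert_mixture",
)

#: required numeric parameters per kind (expert_mixture handled separately)
_PARAMS = {
    "point": ("value",),
    "uniform": ("lower", "upper"),
    "triangular": ("lower", "mode", "upper"),
    "normal_truncated": ("mean", "sd"),
    "lognormal": ("mu", "sigma"),
}


class DistributionError(ValueError):
    """Invalid distribution parameters or an invalid sampling request."""


@dataclass(frozen=True)
class DistributionSpec:
    """A nonnegative univariate distribution with a semantic unit tag.

    Parameters
    ----------
    kind:
        One of :data:`KINDS`.
    params:
        Kind-specific parameters: ``point``: value; ``uniform``:
        lower/upper; ``triangular``: lower/mode/upper; ``normal_truncated``:
        mean/sd (truncated at 0); ``lognormal``: mu/sigma of log;
        ``expert_mixture``: ``components`` — a list of DistributionSpec
        sampled with equal weights.
    unit:
        Free-form unit tag ("t/y", "share", "kg", ...); carried through to
        outputs, never interpreted here.
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)
    unit: str = ""

    # -- constructors ------------------------------------------------------

    @classmethod
    def point(cls, value: float, unit: str = "") -> "DistributionSpec":
        return cls("point", {"value": float(value)}, unit)

    @classmethod
    def uniform(cls, lower: float, upper: float, unit: str = "") -> "DistributionSpec":
        return cls("uniform", {"lower": float(lower), "upper": float(upper)}, unit)

    @classmethod
    def triangular(
        cls, lower: float, mode: float, upper: float, unit: str = ""
    ) -> "DistributionSpec":
        return cls(
            "triangular",
            {"lower": float(lower), "mode": float(mode), "upper": float(upper)},
            unit,
        )

    @classmethod
    def normal_truncated(cls, mean: float, sd: float, unit: str = "") -> "DistributionSpec":
        return cls("normal_truncated", {"mean": float(mean), "sd": float(sd)}, unit)

    @classmethod
    def lognormal(cls, mu: float, sigma: float, unit: str = "") -> "DistributionSpec":
        return cls("lognormal", {"mu": float(mu), "sigma": float(sigma)}, unit)

    @classmethod
    def expert_mixture(
        cls, components: list["DistributionSpec"], unit: str = ""
    ) -> "DistributionSpec":
        return cls("expert_mixture", {"components": tuple(components)}, unit)

    # -- validation --------------------------------------------------------

    def problems(self, prefix: str = "") -> list[str]:
        """Return all parameter violations (empty list = valid)."""
        out: list[str] = []
        p = self.params
        if self.kind not in KINDS:
            return [f"{prefix}kind: unknown distribution kind {self.kind!r}"]
        if self.kind == "expert_mixture":
            comps = p.get("components", ())
            if len(comps) < 1:
                out.append(f"{prefix}components: expert_mixture needs >= 1 component")
            for i, c in enumerate(comps):
                if not isinstance(c, DistributionSpec):
                    out.append(f"{prefix}components[{i}]: not a DistributionSpec")
                else:
                    out.extend(c.problems(prefix=f"{prefix}components[{i}]."))
            return out
        for name in _PARAMS[self.kind]:
            v = p.get(name)
            if v is None or not np.isfinite(v):
                out.append(f"{prefix}{name}: missing or non-finite")
        if out:
            return out
        if self.kind == "point":
            if p["value"] < 0:
                out.append(f"{prefix}value: must be >= 0")
        elif self.kind == "uniform":
            if p["lower"] < 0:
                out.append(f"{prefix}lower: must be >= 0")
            if p["lower"] > p["upper"]:
                out.append(f"{prefix}upper: requires lower <= upper")
        elif self.kind == "triangular":
            if p["lower"] < 0:
                out.append(f"{prefix}lower: must be >= 0")
            if not (p["lower"] <= p["mode"] <= p["upper"]):
                out.append(f"{prefix}mode: requires lower <= mode <= upper")
        elif self.kind == "normal_truncated":
            if p["sd"] <= 0:
                out.append(f"{prefix}sd: must be > 0")
        elif self.kind == "lognormal":
            if p["sigma"] <= 0:
                out.append(f"{prefix}sigma: must be > 0")
        return out

    def _require_valid(self) -> None:
        probs = self.problems()
        if probs:
            raise DistributionError("; ".join(probs))

    # -- analytic properties ----------------------------------------------

    def support(self) -> tuple[float, float]:
        """(lower, upper) bounds of the support; upper may be ``inf``."""
        p = self.params
        if self.kind == "point":
            return p["value"], p["value"]
        if self.kind == "uniform":
            return p["lower"], p["upper"]
        if self.kind == "triangular":
            return p["lower"], p["upper"]
        if self.kind in ("normal_truncated", "lognormal"):
            return 0.0, np.inf
        if self.kind == "expert_mixture":
            los, his = zip(*(c.support() for c in p["components"]))
            return min(los), max(his)
        raise DistributionError(f"unknown kind {self.kind!r}")

    def mean(self) -> float:
        """Analytic expectation (used to build deterministic point-mass twins)."""
        self._require_valid()
        p = self.params
        if self.kind == "point":
            return p["value"]
        if self.kind == "uniform":
            return 0.5 * (p["lower"] + p["upper"])
        if self.kind == "triangular":
            return (p["lower"] + p["mode"] + p["upper"]) / 3.0
        if self.kind == "normal_truncated":
            a = (0.0 - p["mean"]) / p["sd"]
            return float(stats.truncnorm.mean(a, np.inf, loc=p["mean"], scale=p["sd"]))
        if self.kind == "lognormal":
            return float(np.exp(p["mu"] + 0.5 * p["sigma"] ** 2))
        if self.kind == "expert_mixture":
            return float(np.mean([c.mean() for c in p["components"]]))
        raise DistributionError(f"unknown kind {self.kind!r}")

    def cdf(self, x) -> np.ndarray:
        """Analytic CDF evaluated at ``x`` (vectorized)."""
        self._require_valid()
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "point":
            return (x >= p["value"]).astype(float)
        if self.kind == "uniform":
            return stats.uniform.cdf(x, loc=p["lower"], scale=p["upper"] - p["lower"])
        if self.kind == "triangular":
            span = p["upper"] - p["lower"]
            c = 0.5 if span == 0 else (p["mode"] - p["lower"]) / span
            return stats.triang.cdf(x, c, loc=p["lower"], scale=span)
        if self.kind == "normal_truncated":
            a = (0.0 - p["mean"]) / p["sd"]
            return stats.truncnorm.cdf(x, a, np.inf, loc=p["mean"], scale=p["sd"])
        if self.kind == "lognormal":
            return stats.lognorm.cdf(x, s=p["sigma"], scale=np.exp(p["mu"]))
        if self.kind == "expert_mixture":
            return np.mean([c.cdf(x) for c in p["components"]], axis=0)
        raise DistributionError(f"unknown kind {self.kind!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"kind": self.kind}
        if self.kind == "expert_mixture":
            d["components"] = [c.to_dict() for c in self.params["components"]]
        else:
            d.update({k: float(v) for k, v in self.params.items()})
        if self.unit:
            d["unit"] = self.unit
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], where: str = "distribution") -> "DistributionSpec":
        """Parse a tagged mapping like ``{kind: uniform, lower: 0, upper: 1}``.

        Raises :class:`DistributionError` naming the offending field for
        structurally unreadable input; *parameter* violations are left to
        :meth:`problems` so scenario validation can report them all at once.
        """
        if not isinstance(d, Mapping):
            raise DistributionError(f"{where}: expected a mapping, got {type(d).__name__}")
        kind = d.get("kind")
        if kind not in KINDS:
            raise DistributionError(
                f"{where}.kind: unknown distribution kind {kind!r} (expected one of {', '.join(KINDS)})"
            )
        unit = str(d.get("unit", ""))
        if kind == "expert_mixture":
            comps = d.get("components")
            if not isinstance(comps, (list, tuple)) or not comps:
                raise DistributionError(f"{where}.components: expected a non-empty list")
            return cls.expert_mixture(
                [cls.from_dict(c, where=f"{where}.components[{i}]") for i, c in enumerate(comps)],
                unit,
            )
        params = {}
        for name in _PARAMS[kind]:
            if name not in d:
                raise DistributionError(f"{where}.{name}: required for kind {kind!r}")
            try:
                params[name] = float(d[name])
            except (TypeError, ValueError):
                raise DistributionError(f"{where}.{name}: not a number: {d[name]!r}") from None
        return cls(kind, params, unit)


def sample_distribution(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from ``spec`` using ``rng``.

    Deterministic for a given (spec, n, generator state); all draws lie in
    the spec's support, hence are nonnegative.
    """
    if n < 1:
        raise DistributionError(f"n: must be >= 1, got {n}")
    spec._require_valid()
    p = spec.params
    if spec.kind == "point":
        return np.full(n, p["value"], dtype=float)
    if spec.kind == "uniform":
        return rng.uniform(p["lower"], p["upper"], size=n)
    if spec.kind == "triangular":
        if p["lower"] == p["upper"]:
            return np.full(n, p["lower"], dtype=float)
        return rng.triangular(p["lower"], p["mode"], p["upper"], size=n)
    if spec.kind == "normal_truncated":
        a = (0.0 - p["mean"]) / p["sd"]
        return stats.truncnorm.rvs(
            a, np.inf, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
        )
    if spec.kind == "lognormal":
        return rng.lognormal(p["mu"], p["sigma"], size=n)
    if spec.kind == "expert_mixture":
        comps = p["components"]
        idx = rng.integers(0, len(comps), size=n)
        out = np.empty(n, dtype=float)
        for j, comp in enumerate(comps):
            mask = idx == j
            k = int(mask.sum())
            if k:
                out[mask] = sample_distribution(comp, k, rng)
        return out
    raise DistributionError(f"unknown kind {spec.kind!r}")


def iter_component_specs(spec: DistributionSpec) -> Iterator[DistributionSpec]:
    """Yield ``spec`` and, for mixtures, all nested components."""
    yield spec
    if spec.kind == "expert_mixture":
        for c in spec.params["components"]:
            yield from iter_component_specs(c)
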