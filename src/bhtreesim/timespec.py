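"""Waiting-time distribution specifications and reproducible draws.

Distributions for the waiting time to speciation or extinction are written
in the generator-call dialect of R's random-number functions, for example
``"rexp(0.5)"``, ``"rweibull(0.4, 3)"`` or ``"rgamma(1.5, 1, 2)"``.  The
implicit leading "number of observations" argument is never written; the
remaining parameters follow the positional order and defaults of the
corresponding R generator.  ``const(x)`` denotes a degenerate (delta)
distribution, and arbitrary user callables can be registered with
:func:`register_generator`.

Every draw returned by :func:`draw` is strictly positive: values of exactly
zero (possible e.g. for ``const(0)`` or ``runif(0, b)``) are resampled up to
a fixed cap, after which :class:`~bhtreesim.errors.ZeroWaitError` is raised.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DrawError,
    ParameterDomainError,
    SpecArityError,
    SpecParseError,
    UnknownFamilyError,
    ZeroWaitError,
)

__all__ = [
    "WaitingTimeSpec",
    "RandomStream",
    "parse_spec",
    "draw",
    "register_generator",
    "unregister_generator",
]

#: maximum number of resamples of a non-positive raw draw before giving up
MAX_RESAMPLES = 100


class RandomStream:
    """A seeded random-number stream with a deterministic replay contract.

    Identical seeds produce identical draw sequences across runs and
    platforms (backed by numpy's PCG64 generator).  Use
    :meth:`for_replicate` to derive independent, individually reproducible
    substreams from a master seed.
    """

    __slots__ = ("seed", "gen")

    def __init__(self, seed: int | None = None):
        self.seed = seed
        self.gen = np.random.default_rng(seed)

    @classmethod
    def for_replicate(cls, master_seed: int, index: int) -> "RandomStream":
        """Substream for replicate ``index`` of a batch run under ``master_seed``."""
        obj = cls.__new__(cls)
        obj.seed = (master_seed, index)
        obj.gen = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=(index,))
        )
        return obj

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStream(seed={self.seed!r})"


# ---------------------------------------------------------------------------
# distribution families


def _positive(name: str, value: float, what: str) -> None:
    if not (value > 0):
        raise ParameterDomainError(f"{name}: {what} must be > 0, got {value!r}")


@dataclass(frozen=True)
class _Family:
    name: str                       # generator name as written, e.g. "rexp"
    label: str                      # family label, e.g. "exponential"
    min_params: int
    max_params: int
    defaults: tuple[float, ...]     # appended for omitted trailing parameters
    validate: Callable[[tuple[float, ...]], None]
    sample: Callable[[np.random.Generator, tuple[float, ...]], float]


def _validate_rexp(p):
    _positive("rexp", p[0], "rate")


def _validate_rweibull(p):
    _positive("rweibull", p[0], "shape")
    _positive("rweibull", p[1], "scale")


def _validate_rgamma(p):
    _positive("rgamma", p[0], "shape")
    _positive("rgamma", p[1], "rate")
    _positive("rgamma", p[2], "scale")


def _validate_runif(p):
    lo, hi = p
    if lo < 0:
        raise ParameterDomainError(
            f"runif: lower bound must be >= 0 for waiting times, got {lo!r}"
        )
    if not (lo <= hi):
        raise ParameterDomainError(f"runif: lower bound {lo!r} exceeds upper bound {hi!r}")


def _validate_rlnorm(p):
    if p[1] < 0:
        raise ParameterDomainError(f"rlnorm: sdlog must be >= 0, got {p[1]!r}")


def _validate_rnorm(p):
    _positive("rnorm", p[1], "sd")


def _validate_const(p):
    if p[0] < 0:
        raise ParameterDomainError(f"const: value must be >= 0, got {p[0]!r}")


_FAMILIES: dict[str, _Family] = {}


def _add_family(fam: _Family) -> None:
    _FAMILIES[fam.name] = fam


_add_family(_Family(
    "rexp", "exponential", 1, 1, (),
    _validate_rexp,
    lambda rng, p: rng.exponential(1.0 / p[0]),
))
_add_family(_Family(
    "rweibull", "weibull", 1, 2, (1.0,),
    _validate_rweibull,
    lambda rng, p: p[1] * rng.weibull(p[0]),
))
# rgamma is resolved positionally as (shape, rate, scale); when a third
# parameter is written it overrides the rate, mirroring rgamma(n, shape,
# rate = 1, scale = 1/rate).  We store the resolved (shape, rate, scale).
_add_family(_Family(
    "rgamma", "gamma", 1, 3, (),
    _validate_rgamma,
    lambda rng, p: rng.gamma(p[0], p[2]),
))
_add_family(_Family(
    "runif", "uniform", 0, 2, (0.0, 1.0),
    _validate_runif,
    lambda rng, p: rng.uniform(p[0], p[1]),
))
_add_family(_Family(
    "rlnorm", "lognormal", 0, 2, (0.0, 1.0),
    _validate_rlnorm,
    lambda rng, p: rng.lognormal(p[0], p[1]),
))
# rnorm specs denote a zero-truncated normal: non-positive raw values are
# resampled by draw(), so only the positive part of the density is realized.
_add_family(_Family(
    "rnorm", "normal-truncated", 0, 2, (0.0, 1.0),
    _validate_rnorm,
    lambda rng, p: rng.normal(p[0], p[1]),
))
_add_family(_Family(
    "const", "constant", 1, 1, (),
    _validate_const,
    lambda rng, p: p[0],
))

# user-registered generator names: name -> callable(rng, *params) -> float
_CUSTOM: dict[str, Callable[..., float]] = {}


def register_generator(name: str, fn: Callable[..., float]) -> None:
    """Register a custom waiting-time generator usable in spec strings.

    ``fn(rng, *params)`` must return a single positive waiting time per
    call, where ``rng`` is a ``numpy.random.Generator``.  After
    registration, ``"name(p1, p2, ...)"`` parses like a built-in family.
    """
    if not name.isidentifier():
        raise SpecParseError(f"invalid generator name {name!r}")
    if name in _FAMILIES:
        raise SpecParseError(f"cannot shadow built-in family {name!r}")
    _CUSTOM[name] = fn


def unregister_generator(name: str) -> None:
    _CUSTOM.pop(name, None)


# ---------------------------------------------------------------------------
# the spec type and parser


@dataclass(frozen=True)
class WaitingTimeSpec:
    """A parsed distribution family plus resolved parameters.

    ``params`` always holds the fully resolved parameter tuple (defaults
    filled in), so two specs compare equal iff they denote the same
    distribution; the original text is retained for provenance but excluded
    from equality.
    """

    family: str
    params: tuple[float, ...]
    source_text: str = field(compare=False, default="")

    @property
    def is_custom(self) -> bool:
        return self.family.startswith("custom:")

    def canonical_text(self) -> str:
        """Spec string that re-parses to an identical spec."""
        name = self.family.split(":", 1)[1] if self.is_custom else _LABEL_TO_NAME[self.family]
        args = ",".join(_fmt_param(p) for p in self.params)
        return f"{name}({args})"

    def __str__(self) -> str:
        return self.canonical_text()


_LABEL_TO_NAME = {fam.label: fam.name for fam in _FAMILIES.values()}


def _fmt_param(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


_CALL_RE = re.compile(r"^\s*([A-Za-z_][A-Za-z0-9_.]*)\s*\((.*)\)\s*$", re.S)


def parse_spec(text: str) -> WaitingTimeSpec:
    """Parse a generator-call spec string into a :class:`WaitingTimeSpec`.

    Raises :class:`UnknownFamilyError`, :class:`SpecArityError` or
    :class:`ParameterDomainError` on the corresponding failure.
    """
    if isinstance(text, WaitingTimeSpec):
        return text
    if not isinstance(text, str):
        raise SpecParseError(f"spec must be a string, got {type(text).__name__}")
    m = _CALL_RE.match(text)
    if m is None:
        raise SpecParseError(f"not a generator call: {text!r}")
    name, argstr = m.group(1), m.group(2).strip()
    raw_args: list[float] = []
    if argstr:
        for tok in argstr.split(","):
            tok = tok.strip()
            try:
                raw_args.append(float(tok))
            except ValueError:
                raise SpecParseError(f"non-numeric parameter {tok!r} in {text!r}") from None

    if name in _CUSTOM:
        return WaitingTimeSpec(family=f"custom:{name}", params=tuple(raw_args),
                               source_text=text)

    fam = _FAMILIES.get(name)
    if fam is None:
        raise UnknownFamilyError(f"unknown distribution family {name!r} in {text!r}")
    if not (fam.min_params <= len(raw_args) <= fam.max_params):
        raise SpecArityError(
            f"{name} takes {fam.min_params}..{fam.max_params} parameters, "
            f"got {len(raw_args)} in {text!r}"
        )
    params = list(raw_args)
    if fam.name == "rgamma":
        # positional (shape[, rate[, scale]]); scale defaults to 1/rate
        if len(params) == 1:
            params += [1.0]
        if len(params) == 2:
            params += [1.0 / params[1]]
    else:
        # the defaults tuple covers the optional parameter tail only
        params = list(raw_args) + list(fam.defaults[len(raw_args) - fam.min_params:])
    params = tuple(params)
    fam.validate(params)
    return WaitingTimeSpec(family=fam.label, params=params, source_text=text)


def _sampler(spec: WaitingTimeSpec) -> Callable[[np.random.Generator], float]:
    if spec.is_custom:
        name = spec.family.split(":", 1)[1]
        fn = _CUSTOM.get(name)
        if fn is None:
            raise UnknownFamilyError(f"custom generator {name!r} is no longer registered")
        return lambda rng: fn(rng, *spec.params)
    fam = _FAMILIES[_LABEL_TO_NAME[spec.family]]
    return lambda rng: fam.sample(rng, spec.params)


def draw(spec: WaitingTimeSpec, factor: float = 1.0, stream: RandomStream | None = None) -> float:
    """One independent waiting time from ``spec``, scaled by ``factor``.

    The raw draw is resampled while non-positive (up to :data:`MAX_RESAMPLES`
    times); the surviving value is multiplied by ``factor``.
    """
    if stream is None:
        raise DrawError("draw() requires an explicit RandomStream")
    if not (factor > 0):
        raise DrawError(f"scaling factor must be > 0, got {factor!r}")
    rng = stream.gen
    sample = _sampler(spec)
    x = sample(rng)
    tries = 0
    while not (x > 0.0):
        tries += 1
        if tries > MAX_RESAMPLES:
            raise ZeroWaitError(
                f"spec {spec.canonical_text()!r} produced {MAX_RESAMPLES + 1} "
                f"consecutive non-positive waiting times"
            )
        x = sample(rng)
    value = x * factor
    if not math.isfinite(value):
        raise DrawError(f"non-finite waiting time {value!r} from {spec.canonical_text()!r}")
    return value
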