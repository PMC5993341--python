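"""Lineage-level branching event loop.

One origin lineage starts at time 0.  Each lineage carries two competing
clocks: a waiting time to speciation and a waiting time to extinction, both
drawn from user-specified distributions and scaled by heritable per-lineage
factors.  Whichever clock rings first decides the lineage's next event
(ties go to speciation, so degenerate delta specs grow rather than stall).

Two speciation semantics are supported:

* ``symmetric`` — at a speciation both descendants are new species of age
  0; the mother terminates.
* ``asymmetric`` (budding) — one descendant is a new species; the mother
  keeps her age and her originally scheduled extinction time and draws a
  fresh speciation waiting time from the event, speciating repeatedly until
  a drawn speciation time falls beyond her extinction.

New species (never the origin lineage) may, independently for speciation
and extinction, receive a scaling-factor shift with a configured
probability; the factor is drawn from a strength distribution, replaces the
inherited factor, and is inherited by all descendants until shifted again.

Simultaneous events across lineages (possible only with degenerate specs)
are processed in ascending lineage-id order so that runs are deterministic
under a fixed seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import EngineLimitError, TreeStructureError
from .timespec import RandomStream, WaitingTimeSpec, draw, parse_spec

__all__ = [
    "Lineage",
    "ShiftConfig",
    "SamplingConfig",
    "SimConfig",
    "SimResult",
    "CountTimeline",
    "resolve_fate",
    "spawn_species",
    "simulate_age",
    "lineage_count_timeline",
]

_INF = math.inf

# lineage fates
ALIVE = "alive"
EXTINCT = "extinct"
TERMINATED = "terminated_by_speciation"

# result statuses
COMPLETED = "completed"
EXTINCT_STATUS = "extinct"
SINGLE_SURVIVOR = "single_survivor"


@dataclass
class Lineage:
    """Life record of one species."""

    id: int
    parent_id: int | None
    origin_time: float
    scheduled_extinction_time: float = _INF
    end_time: float | None = None
    fate: str = ALIVE
    sp_factor: float = 1.0
    ext_factor: float = 1.0
    sp_shifted: bool = False
    ext_shifted: bool = False
    children: list[tuple[int, float]] = field(default_factory=list)
    # internal clock: absolute time of the next scheduled speciation
    next_speciation_time: float = _INF

    @property
    def alive(self) -> bool:
        return self.end_time is None


@dataclass
class ShiftConfig:
    """Probability and strength distribution of a lineage-specific shift."""

    prob: float = 0.0
    strength: WaitingTimeSpec | None = None

    def __post_init__(self):
        if isinstance(self.strength, str):
            self.strength = parse_spec(self.strength)
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError(f"shift probability must be in [0, 1], got {self.prob!r}")
        if self.prob > 0 and self.strength is None:
            raise ValueError("shift strength spec required when shift probability > 0")


@dataclass
class SamplingConfig:
    """Incomplete-sampling settings applied to pruned trees."""

    frac: float = 1.0
    method: str = "uniform"  # or "proportional"

    def __post_init__(self):
        if not (0.0 < self.frac <= 1.0):
            raise ValueError(f"sampling fraction must be in (0, 1], got {self.frac!r}")
        if self.method not in ("uniform", "proportional"):
            raise ValueError(f"unknown sampling method {self.method!r}")


@dataclass
class SimConfig:
    """Full simulation settings.

    ``waitsp``/``waitext`` accept spec strings or parsed
    :class:`~bhtreesim.timespec.WaitingTimeSpec` objects; an absent
    ``waitext`` means no extinction (infinite waiting time).
    """

    waitsp: WaitingTimeSpec
    waitext: WaitingTimeSpec | None = None
    mode: str = "symmetric"  # or "asymmetric"
    shiftsp: ShiftConfig = field(default_factory=ShiftConfig)
    shiftext: ShiftConfig = field(default_factory=ShiftConfig)
    complete: bool = True
    sampling: SamplingConfig | None = None
    seed: int | None = None
    retry_cap: int = 10_000
    # a fresh shift replaces the inherited factor by default; set True to
    # multiply into it instead
    compound_shifts: bool = False
    max_lineages: int = 2_000_000

    def __post_init__(self):
        if isinstance(self.waitsp, str):
            self.waitsp = parse_spec(self.waitsp)
        if isinstance(self.waitext, str):
            self.waitext = parse_spec(self.waitext)
        if isinstance(self.shiftsp, (tuple, list)):
            self.shiftsp = ShiftConfig(*self.shiftsp)
        if isinstance(self.shiftext, (tuple, list)):
            self.shiftext = ShiftConfig(*self.shiftext)
        if isinstance(self.sampling, (tuple, list)):
            self.sampling = SamplingConfig(*self.sampling)
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValueError(f"mode must be 'symmetric' or 'asymmetric', got {self.mode!r}")
        if self.retry_cap < 1:
            raise ValueError("retry_cap must be >= 1")


@dataclass
class SimResult:
    """Outcome of one simulation replicate.

    ``tree`` is present only for ``completed`` status.  The event counters
    and total alive lineage-time are recorded for every status (including
    extinct replicates) so pooled rate estimators stay unbiased.
    """

    status: str
    tree: object | None = None
    attempts: int = 1
    n_extant: int = 0
    n_speciations: int = 0
    n_extinctions: int = 0
    lineage_time: float = 0.0
    n_new_species: int = 0
    n_sp_shifts: int = 0
    n_ext_shifts: int = 0
    lineages: list[Lineage] | None = None
    horizon: float | None = None


def resolve_fate(wait_sp: float, wait_ext_remaining: float) -> str:
    """Decide the next event from the two competing clocks.

    Extinction happens iff the remaining extinction time is strictly
    shorter than the speciation waiting time; ties go to speciation.
    """
    if wait_sp < 0 or wait_ext_remaining < 0:
        raise ValueError("waiting times must be >= 0")
    if math.isinf(wait_sp) and math.isinf(wait_ext_remaining):
        raise ValueError("both clocks are infinite; no event can be resolved")
    return "extinction" if wait_ext_remaining < wait_sp else "speciation"


def spawn_species(
    parent: Lineage,
    t: float,
    config: SimConfig,
    stream: RandomStream,
    lineage_id: int = -1,
) -> Lineage:
    """Create one new species of age 0 at time ``t`` descending from ``parent``.

    With probability ``shiftsp.prob`` the child receives a speciation
    scaling factor drawn from the strength spec (replacing the inherited
    one), and independently likewise for extinction.  The child's extinction
    time is scheduled immediately and never redrawn; its first speciation
    clock is drawn from its own (possibly shifted) factor.
    """
    if t < parent.origin_time or (parent.end_time is not None and t > parent.end_time):
        raise TreeStructureError(
            f"speciation time {t} outside parent lineage {parent.id} lifespan"
        )
    rng = stream.gen
    sp_factor, sp_shifted = parent.sp_factor, False
    sc = config.shiftsp
    if sc.prob > 0 and rng.random() < sc.prob:
        strength = draw(sc.strength, 1.0, stream)
        sp_factor = parent.sp_factor * strength if config.compound_shifts else strength
        sp_shifted = True
    ext_factor, ext_shifted = parent.ext_factor, False
    ec = config.shiftext
    if ec.prob > 0 and rng.random() < ec.prob:
        strength = draw(ec.strength, 1.0, stream)
        ext_factor = parent.ext_factor * strength if config.compound_shifts else strength
        ext_shifted = True

    if config.waitext is not None:
        sched_ext = t + draw(config.waitext, ext_factor, stream)
    else:
        sched_ext = _INF
    child = Lineage(
        id=lineage_id,
        parent_id=parent.id,
        origin_time=t,
        scheduled_extinction_time=sched_ext,
        sp_factor=sp_factor,
        ext_factor=ext_factor,
        sp_shifted=sp_shifted,
        ext_shifted=ext_shifted,
    )
    child.next_speciation_time = t + draw(config.waitsp, sp_factor, stream)
    return child


class EventLoop:
    """Core competing-clock event loop over lineage records.

    Shared by the age-stopping and taxon-count-stopping front ends; exposed
    for the conditioning module, not part of the public API surface.
    """

    def __init__(self, config: SimConfig, stream: RandomStream):
        self.config = config
        self.stream = stream
        self.n_alive = 1
        self.n_speciations = 0
        self.n_extinctions = 0
        self.n_new_species = 0
        self.n_sp_shifts = 0
        self.n_ext_shifts = 0
        root = Lineage(id=0, parent_id=None, origin_time=0.0)
        if config.waitext is not None:
            root.scheduled_extinction_time = draw(config.waitext, 1.0, stream)
        root.next_speciation_time = draw(config.waitsp, 1.0, stream)
        self.lineages: list[Lineage] = [root]
        self._heap: list[tuple[float, int, str]] = []
        self._push(root)

    # -- internals ---------------------------------------------------------

    def _push(self, lin: Lineage) -> None:
        # ties between the two clocks of one lineage go to speciation
        if lin.next_speciation_time <= lin.scheduled_extinction_time:
            heapq.heappush(self._heap, (lin.next_speciation_time, lin.id, "sp"))
        else:
            heapq.heappush(self._heap, (lin.scheduled_extinction_time, lin.id, "ext"))

    def _spawn(self, parent: Lineage, t: float) -> Lineage:
        child = spawn_species(parent, t, self.config, self.stream,
                              lineage_id=len(self.lineages))
        self.lineages.append(child)
        parent.children.append((child.id, t))
        self.n_alive += 1
        self.n_new_species += 1
        if child.sp_shifted:
            self.n_sp_shifts += 1
        if child.ext_shifted:
            self.n_ext_shifts += 1
        self._push(child)
        return child

    def _step(self) -> float:
        """Process the single next event; return its time."""
        t, lid, kind = heapq.heappop(self._heap)
        lin = self.lineages[lid]
        if kind == "sp":
            self.n_speciations += 1
            if self.config.mode == "symmetric":
                lin.fate = TERMINATED
                lin.end_time = t
                self.n_alive -= 1
                self._spawn(lin, t)
                self._spawn(lin, t)
            else:
                self._spawn(lin, t)
                lin.next_speciation_time = t + draw(
                    self.config.waitsp, lin.sp_factor, self.stream
                )
                self._push(lin)
        else:
            lin.fate = EXTINCT
            lin.end_time = t
            self.n_alive -= 1
            self.n_extinctions += 1
        if len(self.lineages) > self.config.max_lineages:
            raise EngineLimitError(
                f"lineage count exceeded max_lineages={self.config.max_lineages}"
            )
        return t

    # -- drivers -----------------------------------------------------------

    def run_age(self, age: float) -> None:
        """Process every event up to and including time ``age``."""
        while self._heap and self._heap[0][0] <= age:
            self._step()

    def run_count(self, target: int) -> float | None:
        """Run until the alive-lineage count first reaches ``target``.

        Returns the first-passage time, or None if the process died out
        first.  Events strictly after the first passage are not processed.
        """
        if self.n_alive >= target:
            return 0.0
        while self._heap:
            t = self._step()
            if self.n_alive >= target:
                return t
        return None

    def counters(self) -> dict:
        return dict(
            n_speciations=self.n_speciations,
            n_extinctions=self.n_extinctions,
            n_new_species=self.n_new_species,
            n_sp_shifts=self.n_sp_shifts,
            n_ext_shifts=self.n_ext_shifts,
        )


def total_lineage_time(lineages: Iterable[Lineage], horizon: float) -> float:
    """Total time alive summed over lineages, censored at ``horizon``."""
    return sum(
        (lin.end_time if lin.end_time is not None else horizon) - lin.origin_time
        for lin in lineages
    )


def simulate_age(
    config: SimConfig, age: float, stream: RandomStream | None = None
) -> SimResult:
    """Simulate from a single origin lineage at time 0 up to time ``age``.

    Lineages alive at ``age`` become extant tips.  Status is ``extinct`` if
    no lineage survives, ``single_survivor`` if exactly one survives and
    ``complete=False`` (mirroring the convention of returning a bare code
    rather than a one-tip reconstructed tree), otherwise ``completed``.
    """
    from .treeops import assemble_tree, prune_extinct, sample_tips  # cycle-free at call time

    if not (age > 0):
        raise ValueError(f"age must be > 0, got {age!r}")
    if stream is None:
        stream = RandomStream(config.seed)
    loop = EventLoop(config, stream)
    loop.run_age(age)

    result = SimResult(
        status=COMPLETED,
        attempts=1,
        n_extant=loop.n_alive,
        lineage_time=total_lineage_time(loop.lineages, age),
        lineages=loop.lineages,
        horizon=age,
        **loop.counters(),
    )
    if loop.n_alive == 0:
        result.status = EXTINCT_STATUS
        return result
    if loop.n_alive == 1 and not config.complete:
        result.status = SINGLE_SURVIVOR
        return result

    tree = assemble_tree(loop.lineages, horizon=age)
    if not config.complete:
        pruned = prune_extinct(tree)
        tree = pruned.tree  # >= 2 extant tips guaranteed here
        if config.sampling is not None and config.sampling.frac < 1.0:
            tree = sample_tips(tree, config.sampling.frac, config.sampling.method, stream)
    result.tree = tree
    return result


# ---------------------------------------------------------------------------
# lineages-through-time step function


class CountTimeline:
    """Piecewise-constant count of coexisting (alive) lineages.

    ``counts[i]`` holds on the half-open interval ``[times[i], times[i+1])``
    (the last count extends to any queried horizon).  Simultaneous events
    are merged, so instantaneous intermediate counts never appear.
    """

    def __init__(self, times: Sequence[float], counts: Sequence[int]):
        if len(times) != len(counts):
            raise ValueError("times and counts must have equal length")
        self.times = list(times)
        self.counts = list(counts)

    def count_at(self, t: float) -> int:
        import bisect

        if not self.times or t < self.times[0]:
            return 0
        i = bisect.bisect_right(self.times, t) - 1
        return self.counts[i]

    def segments(self, horizon: float):
        """Yield ``(start, end, count)`` covering ``[times[0], horizon]``."""
        for i, (t, c) in enumerate(zip(self.times, self.counts)):
            if t > horizon:
                break
            end = self.times[i + 1] if i + 1 < len(self.times) else horizon
            yield t, min(end, horizon), c

    def __eq__(self, other):
        return (
            isinstance(other, CountTimeline)
            and self.times == other.times
            and self.counts == other.counts
        )

    def __repr__(self) -> str:  # pragma: no cover
        pairs = ", ".join(f"{t:g}:{c}" for t, c in zip(self.times, self.counts))
        return f"CountTimeline({pairs})"


def lineage_count_timeline(lineages: Iterable[Lineage]) -> CountTimeline:
    """Build the alive-lineage count step function from lineage records.

    Each birth contributes +1 at its origin time and each death (extinction
    or termination by symmetric speciation) -1 at its end time; deltas at
    identical times are merged.
    """
    deltas: dict[float, int] = {}
    for lin in lineages:
        deltas[lin.origin_time] = deltas.get(lin.origin_time, 0) + 1
        if lin.end_time is not None:
            deltas[lin.end_time] = deltas.get(lin.end_time, 0) - 1
    times = sorted(deltas)
    counts = []
    c = 0
    for t in times:
        c += deltas[t]
        counts.append(c)
    return CountTimeline(times, counts)
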