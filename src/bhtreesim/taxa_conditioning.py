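"""Trees conditioned on a number of coexisting species.

Two stopping rules are offered:

* first-passage (``gsa=False``) — stop the event loop the first time the
  alive-lineage count reaches ``n`` and cut the tree at that instant, so
  the two youngest tips have zero-length pendant edges;
* general sampling approach (``gsa=True``) — simulate until the count
  first reaches a larger target ``m`` (``n << m``), collect every maximal
  time interval on which exactly ``n`` lineages coexist, draw a cut time
  uniformly over the union of those intervals, and truncate there.  This
  avoids the bias toward young trees inherent in first-passage stopping.

Realizations that die out before reaching the target are discarded and
re-simulated, up to ``config.retry_cap`` attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .engine import (
    ALIVE,
    COMPLETED,
    CountTimeline,
    EventLoop,
    Lineage,
    SimConfig,
    SimResult,
    lineage_count_timeline,
    total_lineage_time,
)
from .errors import RetryCapExceededError
from .timespec import RandomStream

__all__ = [
    "NCountInterval",
    "simulate_taxa",
    "n_count_intervals",
    "cut_at_time",
    "choose_cut_time",
]


@dataclass(frozen=True)
class NCountInterval:
    """Maximal time interval on which exactly ``count`` lineages coexist."""

    start: float
    end: float
    count: int

    @property
    def length(self) -> float:
        return self.end - self.start


def n_count_intervals(
    timeline: CountTimeline, n: int, horizon: float
) -> list[NCountInterval]:
    """Maximal positive-length intervals with count ``n``, clipped at ``horizon``.

    Zero-duration count states (possible only with simultaneous degenerate
    events) are excluded: they cannot be sampled uniformly in time.
    """
    intervals: list[NCountInterval] = []
    for start, end, count in timeline.segments(horizon):
        if count != n or end <= start:
            continue
        if intervals and intervals[-1].end == start:
            intervals[-1] = NCountInterval(intervals[-1].start, end, n)
        else:
            intervals.append(NCountInterval(start, end, n))
    return intervals


def choose_cut_time(intervals: Sequence[NCountInterval], stream: RandomStream) -> float:
    """Uniform draw over the union of the intervals.

    Each interval is hit with probability proportional to its length, and
    the cut is uniform within the chosen interval.
    """
    if not intervals:
        raise ValueError("no intervals to choose from")
    total = sum(iv.length for iv in intervals)
    u = stream.gen.uniform(0.0, total)
    for iv in intervals:
        if u < iv.length:
            return iv.start + u
        u -= iv.length
    return intervals[-1].end  # float round-off fallback


def cut_at_time(
    lineages: Sequence[Lineage], t: float, horizon: float | None = None
) -> list[Lineage]:
    """Truncate a lineage set at time ``t``.

    Events after ``t`` are removed; lineages alive at ``t`` (including
    mothers whose later fate falls beyond the cut) are returned as alive
    with open end times; lineages already dead by ``t`` are kept intact, so
    the result still describes a complete (unpruned) history.
    """
    if t < 0:
        raise ValueError(f"cut time must be >= 0, got {t!r}")
    if horizon is not None and t > horizon:
        raise ValueError(f"cut time {t} beyond simulated horizon {horizon}")
    out: list[Lineage] = []
    for lin in lineages:
        if lin.origin_time > t:
            continue
        nl = replace(lin, children=[(c, ct) for c, ct in lin.children if ct <= t])
        if nl.end_time is not None and nl.end_time > t:
            nl.end_time = None
            nl.fate = ALIVE
        out.append(nl)
    return out


def _counters_from_records(lineages: Sequence[Lineage], mode: str) -> dict:
    n_children = sum(len(lin.children) for lin in lineages)
    n_speciations = n_children // 2 if mode == "symmetric" else n_children
    return dict(
        n_speciations=n_speciations,
        n_extinctions=sum(1 for lin in lineages if lin.fate == "extinct"),
        n_new_species=n_children,
        n_sp_shifts=sum(1 for lin in lineages if lin.sp_shifted),
        n_ext_shifts=sum(1 for lin in lineages if lin.ext_shifted),
    )


def simulate_taxa(
    config: SimConfig,
    n: int,
    gsa: bool = False,
    m: int | None = None,
    stream: RandomStream | None = None,
) -> SimResult:
    """Simulate one tree conditioned on ``n`` extant species.

    With ``gsa=False`` the simulation stops the first time ``n`` species
    coexist.  With ``gsa=True`` a realization with ``m`` coexisting species
    is simulated first and a random cut time with exactly ``n`` coexisting
    species is chosen (see module docstring).  A practical heuristic is
    ``m >= 10 * n``; it is not enforced.
    """
    from .treeops import assemble_tree, prune_extinct, sample_tips

    if n < 2:
        raise ValueError(f"n must be >= 2, got {n!r}")
    if gsa:
        if m is None:
            raise ValueError("gsa=True requires m")
        if m <= n:
            raise ValueError(f"gsa requires m > n, got m={m!r}, n={n!r}")
    if stream is None:
        stream = RandomStream(config.seed)

    target = m if gsa else n
    for attempt in range(1, config.retry_cap + 1):
        loop = EventLoop(config, stream)
        t_hit = loop.run_count(target)
        if t_hit is None:
            continue  # died out before reaching the target: discard and retry
        if gsa:
            timeline = lineage_count_timeline(loop.lineages)
            intervals = n_count_intervals(timeline, n, horizon=t_hit)
            if not intervals:
                continue  # only zero-duration visits to n: unusable realization
            t_cut = choose_cut_time(intervals, stream)
            records = cut_at_time(loop.lineages, t_cut, horizon=t_hit)
            horizon = t_cut
        else:
            records = loop.lineages
            horizon = t_hit

        result = SimResult(
            status=COMPLETED,
            attempts=attempt,
            n_extant=sum(1 for lin in records if lin.end_time is None),
            lineage_time=total_lineage_time(records, horizon),
            lineages=records,
            horizon=horizon,
            **_counters_from_records(records, config.mode),
        )
        tree = assemble_tree(records, horizon=horizon)
        if not config.complete:
            tree = prune_extinct(tree).tree
            if config.sampling is not None and config.sampling.frac < 1.0:
                tree = sample_tips(
                    tree, config.sampling.frac, config.sampling.method, stream
                )
        result.tree = tree
        return result

    raise RetryCapExceededError(
        f"failed to reach {target} coexisting species in {config.retry_cap} attempts; "
        "the parameter regime may make the target effectively unreachable",
        attempts=config.retry_cap,
    )
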