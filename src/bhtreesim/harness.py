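"""Batch execution, seeding, summaries and rate-recovery estimators.

Replicate ``k`` of a batch runs on a substream derived deterministically
from ``(master_seed, k)``, so any single replicate can be reproduced in
isolation without re-running the whole batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    COMPLETED,
    EXTINCT_STATUS,
    SINGLE_SURVIVOR,
    SamplingConfig,
    ShiftConfig,
    SimConfig,
    SimResult,
    simulate_age,
)
from .errors import AllExtinctError, BHTreeSimError
from .taxa_conditioning import simulate_taxa
from .timespec import RandomStream
from .treeops import tree_stats

__all__ = [
    "AgeStop",
    "TaxaStop",
    "BatchSummary",
    "run_batch",
    "summarize_batch",
    "estimate_event_rates",
    "load_config",
]

logger = logging.getLogger("bhtreesim")


@dataclass(frozen=True)
class AgeStop:
    age: float


@dataclass(frozen=True)
class TaxaStop:
    n: int
    gsa: bool = False
    m: int | None = None


def run_batch(
    config: SimConfig,
    numbsim: int,
    stopping: AgeStop | TaxaStop,
    master_seed: int,
) -> list[SimResult]:
    """Run ``numbsim`` independent replicates under one stopping rule."""
    if numbsim < 1:
        raise ValueError(f"numbsim must be >= 1, got {numbsim!r}")
    results: list[SimResult] = []
    for k in range(numbsim):
        stream = RandomStream.for_replicate(master_seed, k)
        try:
            if isinstance(stopping, AgeStop):
                res = simulate_age(config, stopping.age, stream)
            elif isinstance(stopping, TaxaStop):
                res = simulate_taxa(config, stopping.n, stopping.gsa, stopping.m, stream)
            else:
                raise TypeError(f"unknown stopping condition {stopping!r}")
        except BHTreeSimError as exc:
            raise type(exc)(f"replicate {k}: {exc}") from exc
        logger.info(
            "replicate %d: status=%s tips=%d attempts=%d",
            k, res.status, res.n_extant, res.attempts,
        )
        results.append(res)
    return results


@dataclass
class BatchSummary:
    """Per-replicate statistics and their batch-level aggregates.

    Extinct and single-survivor replicates carry no tree and are excluded
    from the tree-statistic aggregates but counted in the status tallies.
    """

    table: pd.DataFrame
    n_completed: int
    n_extinct: int
    n_single_survivor: int
    total_attempts: int
    tips_median: float
    tips_ci: tuple[float, float]
    oldest_branching_median: float | None
    oldest_branching_ci: tuple[float, float] | None


def summarize_batch(results: Sequence[SimResult]) -> BatchSummary:
    """Aggregate a batch: medians and central 95% intervals of the number
    of extant tips and of the oldest branching time, over surviving trees."""
    if not results:
        raise ValueError("empty batch")
    rows = []
    for i, res in enumerate(results):
        row = dict(
            replicate=i,
            status=res.status,
            attempts=res.attempts,
            extant_tips=res.n_extant,
            total_tips=np.nan,
            stem_age=np.nan,
            oldest_branching_time=np.nan,
            total_branch_length=np.nan,
        )
        if res.tree is not None:
            st = tree_stats(res.tree)
            row.update(
                extant_tips=st.extant_tips,
                total_tips=st.total_tips,
                stem_age=st.stem_age,
                oldest_branching_time=(
                    st.oldest_branching_time
                    if st.oldest_branching_time is not None
                    else np.nan
                ),
                total_branch_length=st.total_branch_length,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    statuses = table.status.value_counts()
    n_completed = int(statuses.get(COMPLETED, 0))
    if n_completed == 0:
        raise AllExtinctError("no replicate produced a surviving tree")
    surv = table[table.status == COMPLETED]
    tips = surv.extant_tips.astype(float)
    oldest = surv.oldest_branching_time.dropna()
    return BatchSummary(
        table=table,
        n_completed=n_completed,
        n_extinct=int(statuses.get(EXTINCT_STATUS, 0)),
        n_single_survivor=int(statuses.get(SINGLE_SURVIVOR, 0)),
        total_attempts=int(table.attempts.sum()),
        tips_median=float(tips.median()),
        tips_ci=(float(tips.quantile(0.025)), float(tips.quantile(0.975))),
        oldest_branching_median=float(oldest.median()) if len(oldest) else None,
        oldest_branching_ci=(
            (float(oldest.quantile(0.025)), float(oldest.quantile(0.975)))
            if len(oldest)
            else None
        ),
    )


def estimate_event_rates(results: Sequence[SimResult]) -> tuple[float, float]:
    """Pooled constant-rate estimators from complete-tree batches.

    Speciation rate = total speciation events / total alive lineage-time;
    extinction rate likewise.  Counters are recorded for every replicate
    (including those that died out), so the pooled ratios are unbiased.
    """
    total_time = sum(r.lineage_time for r in results)
    if total_time <= 0:
        raise ValueError("zero total lineage-time; cannot estimate rates")
    sp = sum(r.n_speciations for r in results)
    ext = sum(r.n_extinctions for r in results)
    return sp / total_time, ext / total_time


# ---------------------------------------------------------------------------
# flat key-value config files


_TRUE = {"true", "t", "yes", "1"}
_FALSE = {"false", "f", "no", "0"}


def _parse_value(raw: str):
    v = raw.strip().strip('"').strip("'")
    low = v.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    try:
        f = float(v)
        return int(f) if f == int(f) and "." not in v and "e" not in low else f
    except ValueError:
        return v


def load_config(path: str | Path) -> tuple[SimConfig, AgeStop | TaxaStop, int]:
    """Read a flat ``key = value`` configuration file.

    Recognized keys: numbsim, age, n, m, gsa, waitsp, waitext, symmetric,
    complete, shiftsp.prob, shiftsp.strength, shiftext.prob,
    shiftext.strength, frac, sampling_method, seed.  Lines starting with
    ``#`` are comments.  Exactly one of ``age`` / ``n`` must be present.
    """
    kv: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        kv[key.strip()] = _parse_value(raw)

    unknown = set(kv) - {
        "numbsim", "age", "n", "m", "gsa", "waitsp", "waitext", "symmetric",
        "complete", "shiftsp.prob", "shiftsp.strength", "shiftext.prob",
        "shiftext.strength", "frac", "sampling_method", "seed",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "waitsp" not in kv:
        raise ValueError("config must set waitsp")
    if ("age" in kv) == ("n" in kv):
        raise ValueError("config must set exactly one of 'age' or 'n'")

    config = SimConfig(
        waitsp=str(kv["waitsp"]),
        waitext=str(kv["waitext"]) if "waitext" in kv else None,
        mode="symmetric" if kv.get("symmetric", True) else "asymmetric",
        shiftsp=ShiftConfig(
            prob=float(kv.get("shiftsp.prob", 0.0)),
            strength=str(kv["shiftsp.strength"]) if "shiftsp.strength" in kv else None,
        ),
        shiftext=ShiftConfig(
            prob=float(kv.get("shiftext.prob", 0.0)),
            strength=str(kv["shiftext.strength"]) if "shiftext.strength" in kv else None,
        ),
        complete=bool(kv.get("complete", True)),
        sampling=(
            SamplingConfig(
                frac=float(kv["frac"]),
                method=str(kv.get("sampling_method", "uniform")),
            )
            if "frac" in kv
            else None
        ),
        seed=int(kv["seed"]) if "seed" in kv else None,
    )
    if "age" in kv:
        stopping: AgeStop | TaxaStop = AgeStop(age=float(kv["age"]))
    else:
        stopping = TaxaStop(
            n=int(kv["n"]),
            gsa=bool(kv.get("gsa", False)),
            m=int(kv["m"]) if "m" in kv else None,
        )
    numbsim = int(kv.get("numbsim", 1))
    return config, stopping, numbsim
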