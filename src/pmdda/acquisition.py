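"""Targeted-MS/MS injection scheduling under retention-time density limits.

A quadrupole can only cycle through a handful of targets at once, so the
precursor list is split across repeated injections such that within any
single injection no sliding RT interval of ``window`` seconds (default
12 s = 0.2 min) contains more than ``max_per_window`` targets (default 6).

The scheduler randomises target order with a seeded generator and then
first-fits each target into the lowest-index injection that still
satisfies the sliding-window constraint, opening a new injection when
none fits. The sliding-window (not fixed-bin) reading is the stricter
one: the constraint holds over *every* continuous interval of the window
length.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd


class Target(NamedTuple):
    id: str
    mz: float
    rt: float  # seconds


@dataclass
class InjectionPlan:
    """Partition of precursor targets into injections."""

    injections: list[list[Target]]
    window: float = 12.0
    max_per_window: int = 6
    seed: int = 0

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    @property
    def n_targets(self) -> int:
        return sum(len(inj) for inj in self.injections)


@dataclass
class ValidationReport:
    """Outcome of a brute-force plan check."""

    ok: bool
    missing: list[str] = field(default_factory=list)
    unexpected: list[str] = field(default_factory=list)
    duplicated: list[str] = field(default_factory=list)
    violations: list[tuple[int, float, int]] = field(default_factory=list)  # (injection, window start, count)


def _as_targets(precursors) -> list[Target]:
    if isinstance(precursors, pd.DataFrame):
        return [Target(str(r.id), float(r.mz), float(r.rt)) for r in precursors.itertuples()]
    return [Target(str(t[0]), float(t[1]), float(t[2])) for t in precursors]


def _fits(rts: list[float], rt: float, window: float, max_per_window: int) -> bool:
    """Would inserting ``rt`` keep every sliding window at or under capacity?

    A violation after insertion means some max_per_window + 1 targets
    (including the new one) span <= window; only windows overlapping the
    new RT can be affected.
    """
    lo = bisect_left(rts, rt - window)
    hi = bisect_right(rts, rt + window)
    local = rts[lo:hi]
    insort(local, rt)
    k = max_per_window  # window holding k+1 targets -> violation
    for i in range(len(local) - k):
        if local[i + k] - local[i] <= window:
            return False
    return True


def schedule_injections(
    precursors,
    window: float = 12.0,
    max_per_window: int = 6,
    seed: int = 0,
) -> InjectionPlan:
    """Randomly partition precursors into valid injections (seeded, first-fit).

    ``precursors`` is a DataFrame with id/mz/rt columns (seconds) or an
    iterable of (id, mz, rt) triples. Deterministic for a given seed.
    """
    targets = _as_targets(precursors)
    if not targets:
        raise ValueError("precursor list is empty")
    if window <= 0 or max_per_window < 1:
        raise ValueError("window must be > 0 and max_per_window >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(targets))
    injections: list[list[Target]] = []
    inj_rts: list[list[float]] = []
    for i in order:
        t = targets[int(i)]
        for j, rts in enumerate(inj_rts):
            if _fits(rts, t.rt, window, max_per_window):
                injections[j].append(t)
                insort(rts, t.rt)
                break
        else:
            injections.append([t])
            inj_rts.append([t.rt])
    injections = [sorted(inj, key=lambda t: (t.rt, t.mz, t.id)) for inj in injections]
    return InjectionPlan(injections, window, max_per_window, seed)


def validate_plan(plan: InjectionPlan, precursors) -> ValidationReport:
    """Brute-force check: partition property plus sliding-window density.

    Every window of length ``plan.window`` anchored at each target is
    counted explicitly; any window holding more than ``max_per_window``
    targets is reported with its start time.
    """
    targets = _as_targets(precursors)
    expected = [t.id for t in targets]
    got: list[str] = [t.id for inj in plan.injections for t in inj]
    counts = pd.Series(got).value_counts() if got else pd.Series(dtype=int)
    duplicated = sorted(counts[counts > 1].index.tolist())
    missing = sorted(set(expected) - set(got))
    unexpected = sorted(set(got) - set(expected))

    violations: list[tuple[int, float, int]] = []
    for j, inj in enumerate(plan.injections):
        rts = sorted(t.rt for t in inj)
        for i, start in enumerate(rts):
            n = bisect_right(rts, start + plan.window) - i
            if n > plan.max_per_window:
                violations.append((j, start, n))
    ok = not (missing or unexpected or duplicated or violations)
    return ValidationReport(ok, missing, unexpected, duplicated, violations)


def export_injection_lists(plan: InjectionPlan, out_dir) -> list[Path]:
    """Write one inclusion-list CSV per injection.

    Columns: mz, rt_start, rt_end, id with rt_start/rt_end = rt +/- half
    the window, floored at 0 s. File names are injection_01.csv, ...;
    re-export of the same plan is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    half = plan.window / 2.0
    paths = []
    for j, inj in enumerate(plan.injections, start=1):
        df = pd.DataFrame(
            {
                "mz": [t.mz for t in inj],
                "rt_start": [max(t.rt - half, 0.0) for t in inj],
                "rt_end": [t.rt + half for t in inj],
                "id": [t.id for t in inj],
            }
        )
        path = out_dir / f"injection_{j:02d}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
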