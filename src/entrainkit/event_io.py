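"""Reading, validating and writing step-onset annotation tables.

The on-disk format is a plain CSV in the style of event-logger exports
(one row per footfall)::

    time,subject,bout
    0.00,front,bout01
    0.12,hind,bout01
    ...

``time`` is seconds from recording start, ``subject`` is the walker's role
(``front`` or ``hind``), ``bout`` identifies one continuous episode of joint
walking.  Extra columns (e.g. ``date``) are carried as provenance but ignored
by the analysis.  This module also quantifies inter-annotator reliability by
matching the onsets of two independent codings of the same bouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROLE_FRONT = "front"
ROLE_HIND = "hind"
ROLES = (ROLE_FRONT, ROLE_HIND)


class FormatError(ValueError):
    """The file does not conform to the annotation-CSV schema."""


class ValidationError(ValueError):
    """The data violate an invariant (e.g. duplicate onset times)."""


@dataclass(frozen=True)
class StepEvent:
    """A single annotated foot-ground contact."""

    time: float
    subject: str
    bout_id: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"onset time must be >= 0, got {self.time}")
        if self.subject not in ROLES:
            raise ValidationError(
                f"subject must be one of {ROLES}, got {self.subject!r}"
            )


@dataclass
class Bout:
    """One episode of joint walking: the ordered onsets of both walkers."""

    bout_id: str
    events_front: np.ndarray
    events_hind: np.ndarray

    def __post_init__(self) -> None:
        self.events_front = np.asarray(self.events_front, dtype=float)
        self.events_hind = np.asarray(self.events_hind, dtype=float)
        for role, onsets in ((ROLE_FRONT, self.events_front), (ROLE_HIND, self.events_hind)):
            if onsets.size and np.any(np.diff(onsets) <= 0):
                raise ValidationError(
                    f"bout {self.bout_id!r}: {role} onsets must be strictly "
                    "increasing (duplicate or out-of-order timestamps)"
                )

    def onsets(self, subject: str) -> np.ndarray:
        if subject == ROLE_FRONT:
            return self.events_front
        if subject == ROLE_HIND:
            return self.events_hind
        raise KeyError(subject)

    @property
    def all_onsets(self) -> np.ndarray:
        return np.sort(np.concatenate([self.events_front, self.events_hind]))

    @property
    def duration(self) -> float:
        """Last onset minus first onset across both subjects (seconds)."""
        both = np.concatenate([self.events_front, self.events_hind])
        if both.size == 0:
            return 0.0
        return float(both.max() - both.min())

    @property
    def n_steps(self) -> int:
        return int(self.events_front.size + self.events_hind.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bout):
            return NotImplemented
        return (
            self.bout_id == other.bout_id
            and np.array_equal(self.events_front, other.events_front)
            and np.array_equal(self.events_hind, other.events_hind)
        )


@dataclass
class Dataset:
    """An ordered collection of bouts plus free-form provenance metadata."""

    bouts: list[Bout] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.bout_id for b in self.bouts]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate bout ids: {dupes}")

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.bouts == other.bouts

    @property
    def bout_ids(self) -> list[str]:
        return [b.bout_id for b in self.bouts]

    def bout(self, bout_id: str) -> Bout:
        for b in self.bouts:
            if b.bout_id == bout_id:
                return b
        raise KeyError(bout_id)

    @property
    def n_steps(self) -> int:
        return sum(b.n_steps for b in self.bouts)


@dataclass
class ReliabilityReport:
    """Agreement between two annotators coding the same bouts.

    ``ad_statistic``/``ad_p`` are the Anderson-Darling normality test on the
    signed onset differences (annotator A minus annotator B): small, random,
    roughly normal differences indicate frame-level disagreement only.
    """

    n_pairs: int
    median_abs_diff: float
    sd_diff: float
    ad_statistic: float
    ad_p: float
    unmatched_a: int
    unmatched_b: int


def read_events(
    path: str | Path,
    *,
    time_col: str = "time",
    subject_col: str = "subject",
    bout_col: str = "bout",
    role_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Read an annotation CSV into a validated :class:`Dataset`.

    Onsets are re-sorted per bout and subject; the row order of the file is
    never trusted.  ``role_map`` optionally translates custom subject labels
    onto the canonical ``front``/``hind`` roles.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (time_col, subject_col, bout_col) if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    if role_map:
        df[subject_col] = df[subject_col].map(lambda s: role_map.get(s, s))
    bad = set(df[subject_col].unique()) - set(ROLES)
    if bad:
        raise FormatError(f"{path.name}: unknown subject label(s) {sorted(bad)}")
    if (df[time_col] < 0).any():
        raise ValidationError(f"{path.name}: negative onset times")

    bouts: list[Bout] = []
    # preserve first-appearance order of bouts
    for bout_id, grp in df.groupby(bout_col, sort=False):
        onsets = {}
        for role in ROLES:
            t = np.sort(grp.loc[grp[subject_col] == role, time_col].to_numpy(float))
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"bout {bout_id!r}: duplicate onset times for subject {role!r}"
                )
            onsets[role] = t
        bouts.append(Bout(str(bout_id), onsets[ROLE_FRONT], onsets[ROLE_HIND]))
    return Dataset(bouts, provenance={"source": str(path)})


def write_events(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as an annotation CSV; inverse of :func:`read_events`.

    Times are written with full float precision so that
    ``read_events(write_events(d)) == d`` exactly.
    """
    rows = []
    for bout in dataset:
        for role in ROLES:
            for t in bout.onsets(role):
                rows.append({"time": t, "subject": role, "bout": bout.bout_id})
    df = pd.DataFrame(rows, columns=["time", "subject", "bout"])
    df.to_csv(path, index=False)


def _match_greedy(a: np.ndarray, b: np.ndarray, tolerance: float) -> list[tuple[int, int]]:
    """One-to-one greedy nearest-neighbour matching of two onset lists.

    Pairs are taken in order of increasing |time difference|, each onset used
    at most once, pairs beyond ``tolerance`` discarded.
    """
    if a.size == 0 or b.size == 0:
        return []
    diff = np.abs(a[:, None] - b[None, :])
    order = np.argsort(diff, axis=None, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), b.size)
        if diff[i, j] > tolerance:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def reliability(a: Dataset, b: Dataset, tolerance: float = 0.5) -> ReliabilityReport:
    """Inter-annotator reliability over the bouts shared by two codings.

    Onsets are matched greedily by nearest time within ``tolerance``,
    one-to-one, separately per bout and subject.  The report gives the median
    absolute difference, the SD of signed differences (A minus B) and an
    Anderson-Darling normality test of the signed differences.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    shared = [bid for bid in a.bout_ids if bid in set(b.bout_ids)]
    if not shared:
        raise ValueError("datasets share no bout ids")
    diffs: list[float] = []
    unmatched_a = unmatched_b = 0
    for bid in shared:
        ba, bb = a.bout(bid), b.bout(bid)
        for role in ROLES:
            xa, xb = ba.onsets(role), bb.onsets(role)
            pairs = _match_greedy(xa, xb, tolerance)
            diffs.extend(float(xa[i] - xb[j]) for i, j in pairs)
            unmatched_a += xa.size - len(pairs)
            unmatched_b += xb.size - len(pairs)
    d = np.asarray(diffs)
    if d.size == 0:
        raise ValueError("no onsets matched within tolerance")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    if d.size >= 8 and np.ptp(d) > 0:
        ad = stats.anderson(d, dist="norm", method="interpolate")
        ad_stat, ad_p = float(ad.statistic), float(ad.pvalue)
    else:  # AD undefined on tiny/constant samples
        ad_stat, ad_p = math.nan, math.nan
    return ReliabilityReport(
        n_pairs=d.size,
        median_abs_diff=float(np.median(np.abs(d))),
        sd_diff=sd,
        ad_statistic=ad_stat,
        ad_p=ad_p,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )
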