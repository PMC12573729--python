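"""Distance-to-time conversion, congruence classification and turnover rate.

Genetic distances between symbiont isolates (1 - ANI/100, or a direct
p-distance between consensus sequences) are Jukes-Cantor corrected and
translated into divergence-time *ranges* using bounding substitution rates:
for the symbiont, per-site per-host-generation rate bounds estimated from
intraspecific Drosophila lineages; for the host mitochondrion, the two
widely used arthropod clock rates expressed as percent uncorrected pairwise
distance per million years.  Ranges rather than point estimates are the unit
of comparison: a symbiont split is congruent with a host split when the
narrower range is contained in the wider one, or when the midpoint of the
wider range falls inside the narrower one.

The turnover estimator assumes equal rates of symbiont acquisition and
loss, counts strain-set differences between host sister species, and
divides by the total host divergence time in generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

CATEGORY_LABELS = (
    "intraspecific_intrastrain",
    "intraspecific_interstrain",
    "interspecific_intrastrain",
    "interspecific_interstrain",
)


@dataclass(frozen=True)
class ClockConfig:
    """Bounding molecular-clock rates used to turn distances into time ranges.

    wolb_rate_min/max are substitutions/site/host generation (lower bound of
    the first+second codon position credible interval, upper bound of the
    noncoding one).  mito rates are percent uncorrected pairwise distance per
    million years.  divergence_factor is 2 when per-lineage rates are applied
    to a pairwise distance (divergence accrues on both branches); set 1 to
    treat the rate as already pairwise.
    """

    wolb_rate_min: float = 2.76e-10
    wolb_rate_max: float = 1.5e-9
    mito_rate_fast: float = 2.3
    mito_rate_slow: float = 1.5
    generations_per_year_min: float = 1.0
    generations_per_year_max: float = 3.0
    divergence_factor: float = 2.0

    def __post_init__(self) -> None:
        for lo, hi in [
            (self.wolb_rate_min, self.wolb_rate_max),
            (self.mito_rate_slow, self.mito_rate_fast),
            (self.generations_per_year_min, self.generations_per_year_max),
        ]:
            if not 0 < lo < hi:
                raise ValueError("clock bounds must satisfy 0 < min < max")
        if self.divergence_factor not in (1, 2, 1.0, 2.0):
            raise ValueError("divergence_factor must be 1 or 2")


@dataclass(frozen=True)
class TimeRange:
    """A [lo, hi] split-time interval in the stated units."""

    lo: float
    hi: float
    units: str = "generations"

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(f"invalid time range [{self.lo}, {self.hi}]")

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, t: float) -> bool:
        return self.lo <= t <= self.hi

    def contains_range(self, other: "TimeRange") -> bool:
        return self.lo <= other.lo and other.hi <= self.hi


class Isolate(NamedTuple):
    """A symbiont consensus sequence from one host specimen."""

    sample: str
    species: str
    strain: str


@dataclass
class TurnoverInput:
    """Per sister-pair strain sets and host split times (generations)."""

    pairs: list[tuple[frozenset, frozenset, float]]  # (strains_a, strains_b, split_gen)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("need at least one pair")
        if any(t <= 0 for _, _, t in self.pairs):
            raise ValueError("split_gen must be positive")


def ani_to_distance(ani: float) -> float:
    """Genetic distance d = 1 - ANI/100."""
    if not 0 <= ani <= 100:
        raise ValueError("ANI must be in [0, 100]")
    return 1.0 - ani / 100.0


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites, ignoring positions with N or gaps."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    skip = {"N", "-", "n"}
    comparable = 0
    diffs = 0
    for a, b in zip(seq_a, seq_b):
        if a in skip or b in skip:
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable sites")
    return diffs / comparable


def jc_correct(d: float) -> float:
    """Jukes-Cantor corrected distance: -(3/4) ln(1 - (4/3) d)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d >= 0.75:
        raise ValueError("saturated distance: JC correction undefined for d >= 0.75")
    return -0.75 * math.log1p(-(4.0 / 3.0) * d)


def jc_expected_p(d_jc: float) -> float:
    """Inverse of jc_correct: expected p-distance after d_jc substitutions/site."""
    return 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * d_jc))


def wolb_split_range(
    d_jc: float, clock: ClockConfig | None = None
) -> tuple[TimeRange, TimeRange]:
    """Symbiont split-time range in host generations, and in years.

    The generation range combines the JC distance with the fast (lower bound
    of time) and slow (upper bound) substitution rates; the year range
    additionally spans the host generations-per-year bounds.
    """
    clock = clock or ClockConfig()
    if d_jc < 0:
        raise ValueError("d_jc must be non-negative")
    f = clock.divergence_factor
    gen = TimeRange(
        d_jc / (f * clock.wolb_rate_max),
        d_jc / (f * clock.wolb_rate_min),
        units="generations",
    )
    years = TimeRange(
        gen.lo / clock.generations_per_year_max,
        gen.hi / clock.generations_per_year_min,
        units="years",
    )
    return gen, years


def mito_split_range(d: float, clock: ClockConfig | None = None) -> TimeRange:
    """Mitochondrial split-time range in My from a pairwise distance.

    The clock rates are defined as percent pairwise distance per My, so no
    divergence factor applies.
    """
    clock = clock or ClockConfig()
    if d < 0:
        raise ValueError("distance must be non-negative")
    return TimeRange(
        100.0 * d / clock.mito_rate_fast,
        100.0 * d / clock.mito_rate_slow,
        units="My",
    )


def classify_congruence(range_w: TimeRange, range_h: TimeRange) -> str:
    """Compare a symbiont split range against a host split range.

    Congruent if the narrower range is contained in the wider one, or if the
    midpoint of the wider range lies inside the narrower one (bounds
    inclusive).  Otherwise the symbiont split is 'older' if its midpoint
    exceeds the host midpoint, 'younger' if smaller; exact midpoint equality
    without overlap still counts as congruent.
    """
    if range_w.units != range_h.units:
        raise ValueError(f"unit mismatch: {range_w.units} vs {range_h.units}")
    if range_w.width <= range_h.width:
        small, large = range_w, range_h
    else:
        small, large = range_h, range_w
    if large.contains_range(small) or small.contains(large.midpoint):
        return "congruent"
    if range_w.midpoint > range_h.midpoint:
        return "older"
    if range_w.midpoint < range_h.midpoint:
        return "younger"
    return "congruent"


def categorize(isolate_a: Isolate, isolate_b: Isolate) -> str:
    """2x2 classification on (same host species?, same strain?)."""
    intra_sp = isolate_a.species == isolate_b.species
    intra_st = isolate_a.strain == isolate_b.strain
    sp = "intraspecific" if intra_sp else "interspecific"
    st = "intrastrain" if intra_st else "interstrain"
    return f"{sp}_{st}"


def range_summary(ranges: Sequence[TimeRange]) -> TimeRange:
    """Envelope [min of lows, max of highs] across comparisons."""
    if not ranges:
        raise ValueError("empty set of ranges")
    units = ranges[0].units
    if any(r.units != units for r in ranges):
        raise ValueError("mixed units in range summary")
    return TimeRange(min(r.lo for r in ranges), max(r.hi for r in ranges), units=units)


def turnover_rate(inp: TurnoverInput, clock: ClockConfig | None = None) -> float:
    """Strain acquisition/loss events per million host generations.

    D = total symmetric-difference count of strain sets across pairs;
    G = total host divergence in generations (divergence_factor x split_gen
    per pair, counting both branches by default); rate = 1e6 * D / G.
    """
    clock = clock or ClockConfig()
    d_total = sum(len(a ^ b) for a, b, _ in inp.pairs)
    g_total = sum(clock.divergence_factor * t for _, _, t in inp.pairs)
    if g_total <= 0:
        raise ValueError("total branch length is zero")
    return 1e6 * d_total / g_total


def waiting_time(rate: float, gpy: float) -> float:
    """Expected My between turnover events given a rate per million host
    generations and gpy host generations per year."""
    if rate <= 0 or gpy <= 0:
        raise ValueError("rate and gpy must be positive")
    return 1.0 / (rate * gpy)


def plot_split_ranges(table: "pd.DataFrame", path: str, units: str = "generations"):
    """Horizontal range chart of symbiont vs host split-time intervals.

    Expects a compare_ranges_table-style frame with wolb_lo/wolb_hi,
    host_lo/host_hi, category and verdict columns; writes SVG or PNG by
    file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(table))))
    colors = {"congruent": "tab:green", "older": "tab:red", "younger": "tab:blue"}
    for i, row in enumerate(table.itertuples(index=False)):
        ax.hlines(i + 0.15, row.host_lo, row.host_hi, color="grey", lw=6, alpha=0.5)
        ax.hlines(i - 0.15, row.wolb_lo, row.wolb_hi,
                  color=colors.get(row.verdict, "black"), lw=3)
        ax.plot([(row.wolb_lo + row.wolb_hi) / 2], [i - 0.15], "o",
                color=colors.get(row.verdict, "black"), ms=4)
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(
        [f"{r.sample_a} vs {r.sample_b} ({r.category})"
         for r in table.itertuples(index=False)],
        fontsize=7,
    )
    ax.set_xlabel(f"split time ({units})")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def compare_ranges_table(records: Iterable[dict]) -> "pd.DataFrame":
    """Tabulate comparison records (dicts with isolate metadata and ranges)
    into a category / lo / hi / verdict table."""
    import pandas as pd

    rows = []
    for rec in records:
        a, b = rec["isolate_a"], rec["isolate_b"]
        cat = categorize(a, b)
        verdict = classify_congruence(rec["wolb_range"], rec["host_range"])
        rows.append(
            {
                "sample_a": a.sample,
                "sample_b": b.sample,
                "category": cat,
                "wolb_lo": rec["wolb_range"].lo,
                "wolb_hi": rec["wolb_range"].hi,
                "host_lo": rec["host_range"].lo,
                "host_hi": rec["host_range"].hi,
                "units": rec["wolb_range"].units,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)
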