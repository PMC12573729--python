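"""Competitive read mapping and iterative strain assignment.

Each read is placed at its single best (lowest edit distance) location
across all references — reads too divergent from every reference stay
unmapped.  Per-reference pileups yield breadth of coverage, mean depth and
the density of 'heterozygous' sites (positions where mapped reads support
two or more alleles), which signals co-infection: a sample carrying two
strains mapped against one of them shows the inter-strain divergence as
apparent heterozygosity.

The assignment algorithm mirrors a stepwise decision procedure: screen the
sample against all dereplicated representatives; if the best breadth is
negligible the sample is uninfected; otherwise map against the top-ranked
genome only, and while any genome in the current set exceeds the
heterozygous-site threshold (default 10 sites/kb, the density equivalent of
ANI < 99%), add the next genome in the breadth ranking.  Because
dereplicated representatives can still be similar over their aligned
fraction, a final set of three or more triggers a shortcut re-check against
just the first and last added genomes; if those two alone explain the reads
the intermediate genomes are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from wolbshift.simdata import SimRead, StrainGenome, _seq_to_codes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    breadth_infected: float = 0.90
    het_max_per_kb: float = 10.0
    min_allele_support: int = 2
    max_read_divergence: float = 0.10
    uninfected_breadth: float = 0.10
    consensus_min_depth: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.uninfected_breadth < self.breadth_infected <= 1:
            raise ValueError(
                "need 0 < uninfected_breadth < breadth_infected <= 1"
            )
        if self.het_max_per_kb <= 0:
            raise ValueError("het_max_per_kb must be positive")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_id: str
    ref_start: int
    edit_distance: int
    mapped: bool
    read_index: int  # position in the input read list


@dataclass(frozen=True)
class RefCoverageStats:
    ref_id: str
    breadth: float
    mean_depth: float
    covered_bases: int
    het_sites: int

    @property
    def het_per_kb(self) -> float:
        if self.covered_bases == 0:
            return 0.0
        return 1000.0 * self.het_sites / self.covered_bases


@dataclass
class InfectionCall:
    sample_id: str
    status: str  # "infected" | "uninfected"
    strain_ids: list[str]
    iteration_log: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


class Pileup:
    """Per-reference allele-count matrices (L x 4, base order ACGT)."""

    def __init__(self, references: Sequence[StrainGenome]):
        self.refs = {r.id: r for r in references}
        self.counts = {
            r.id: np.zeros((r.length, 4), dtype=np.int32) for r in references
        }

    def depth(self, ref_id: str) -> np.ndarray:
        return self.counts[ref_id].sum(axis=1)


def _align_read(seq: str, ref_seq: str, k: int) -> tuple[int, int, int] | None:
    """Best placement of seq in ref_seq: (edit_distance, start, end) or None."""
    res = edlib.align(seq, ref_seq, mode="HW", task="locations", k=k)
    ed = res["editDistance"]
    if ed < 0:
        return None
    start, end = min(res["locations"])  # leftmost optimal location
    return ed, start, end


def competitive_map(
    reads: Sequence[SimRead],
    references: Sequence[StrainGenome],
    config: DetectionConfig | None = None,
) -> list[ReadAlignment]:
    """Assign each read to its single lowest-edit-distance placement.

    Ties are broken by reference input order, then leftmost position.  A
    read whose best edit distance exceeds max_read_divergence x length is
    reported unmapped.
    """
    config = config or DetectionConfig()
    if not references:
        raise ValueError("need at least one reference")
    alignments: list[ReadAlignment] = []
    for idx, read in enumerate(reads):
        k_max = int(config.max_read_divergence * len(read.sequence))
        best: tuple[int, int, int] | None = None  # (ed, ref_index, start)
        k = k_max
        for ref_index, ref in enumerate(references):
            hit = _align_read(read.sequence, ref.sequence, k)
            if hit is None:
                continue
            ed, start, _ = hit
            if best is None or ed < best[0]:
                best = (ed, ref_index, start)
                # a later reference must beat this strictly
                k = max(ed - 1, 0)
        if best is None:
            alignments.append(
                ReadAlignment(read.id, "", -1, -1, mapped=False, read_index=idx)
            )
        else:
            ed, ref_index, start = best
            alignments.append(
                ReadAlignment(
                    read.id,
                    references[ref_index].id,
                    start,
                    ed,
                    mapped=True,
                    read_index=idx,
                )
            )
    return alignments


_CIGAR_RE = None


def _add_to_pileup(
    pile: Pileup, read: SimRead, aln: ReadAlignment
) -> None:
    import re

    global _CIGAR_RE
    if _CIGAR_RE is None:
        _CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
    ref = pile.refs[aln.ref_id]
    counts = pile.counts[aln.ref_id]
    codes = _seq_to_codes(read.sequence)
    # fast path: ungapped placement (always the case for substitution-only
    # simulated data); otherwise walk the alignment path
    res = edlib.align(
        read.sequence,
        ref.sequence[aln.ref_start : aln.ref_start + len(read.sequence)],
        mode="NW",
        task="distance",
    )
    if res["editDistance"] == aln.edit_distance and aln.ref_start + len(
        read.sequence
    ) <= ref.length:
        span = np.arange(aln.ref_start, aln.ref_start + len(read.sequence))
        counts[span, codes] += 1
        return
    res = edlib.align(read.sequence, ref.sequence, mode="HW", task="path", k=-1)
    start, _ = min(res["locations"])
    rpos, qpos = start, 0
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if op in "=XM":
            counts[np.arange(rpos, rpos + n), codes[qpos : qpos + n]] += 1
            rpos += n
            qpos += n
        elif op == "I":
            qpos += n
        elif op == "D":
            rpos += n


def pileup(
    alignments: Sequence[ReadAlignment],
    reads: Sequence[SimRead],
    references: Sequence[StrainGenome],
) -> Pileup:
    """Accumulate allele counts per reference position from mapped reads."""
    pile = Pileup(references)
    for aln in alignments:
        if not aln.mapped:
            continue
        _add_to_pileup(pile, reads[aln.read_index], aln)
    return pile


def coverage_stats(
    pile: Pileup, ref_id: str, config: DetectionConfig | None = None
) -> RefCoverageStats:
    """Breadth, mean depth and heterozygous-site count for one reference.

    A site is heterozygous iff at least two distinct bases each have
    min_allele_support supporting reads.
    """
    config = config or DetectionConfig()
    counts = pile.counts[ref_id]
    depth = counts.sum(axis=1)
    covered = depth >= 1
    covered_bases = int(covered.sum())
    breadth = covered_bases / counts.shape[0]
    mean_depth = float(depth.mean())
    het_sites = int(((counts >= config.min_allele_support).sum(axis=1) >= 2).sum())
    return RefCoverageStats(ref_id, breadth, mean_depth, covered_bases, het_sites)


@dataclass
class ScreenResult:
    ranking: list[str]  # ref ids by breadth descending
    stats: dict[str, RefCoverageStats]
    preliminary_uninfected: bool


def screen_sample(
    reads: Sequence[SimRead],
    representatives: Sequence[StrainGenome],
    config: DetectionConfig | None = None,
) -> ScreenResult:
    """Competitive map against all representatives and rank by breadth."""
    config = config or DetectionConfig()
    if not representatives:
        raise ValueError("dereplicated representative set is empty")
    alignments = competitive_map(reads, representatives, config)
    pile = pileup(alignments, reads, representatives)
    stats = {r.id: coverage_stats(pile, r.id, config) for r in representatives}
    order = {r.id: i for i, r in enumerate(representatives)}
    ranking = sorted(stats, key=lambda rid: (-stats[rid].breadth, order[rid]))
    max_breadth = max(s.breadth for s in stats.values()) if stats else 0.0
    return ScreenResult(
        ranking=ranking,
        stats=stats,
        preliminary_uninfected=max_breadth < config.uninfected_breadth,
    )


def _map_and_stats(
    reads: Sequence[SimRead],
    genome_set: list[StrainGenome],
    config: DetectionConfig,
) -> tuple[dict[str, RefCoverageStats], Pileup]:
    alignments = competitive_map(reads, genome_set, config)
    pile = pileup(alignments, reads, genome_set)
    return {g.id: coverage_stats(pile, g.id, config) for g in genome_set}, pile


def iterate_strains(
    reads: Sequence[SimRead],
    ranking: Sequence[StrainGenome],
    config: DetectionConfig | None = None,
    sample_id: str = "sample",
) -> InfectionCall:
    """Iterative strain assignment against a breadth-ranked genome list.

    Genomes from the ranking are added while any genome in the current set
    exceeds the heterozygous-site threshold.  If three or more genomes were
    needed, a re-mapping against only the first and last added genomes
    checks whether the intermediate genomes were redundant.
    """
    config = config or DetectionConfig()
    if not ranking:
        raise ValueError("empty ranking")
    call = InfectionCall(sample_id=sample_id, status="uninfected", strain_ids=[])
    genome_set = [ranking[0]]
    next_idx = 1
    unresolved = False
    while True:
        stats, _ = _map_and_stats(reads, genome_set, config)
        call.iteration_log.append(
            {
                "genomes": [g.id for g in genome_set],
                "stats": dict(stats),
            }
        )
        offenders = [
            rid for rid, s in stats.items() if s.het_per_kb > config.het_max_per_kb
        ]
        if not offenders:
            break
        if next_idx >= len(ranking):
            unresolved = True
            call.flags.append("unresolved_coinfection")
            break
        genome_set.append(ranking[next_idx])
        next_idx += 1

    if len(genome_set) >= 3 and not unresolved:
        shortcut = [genome_set[0], genome_set[-1]]
        sc_stats, _ = _map_and_stats(reads, shortcut, config)
        call.iteration_log.append(
            {
                "genomes": [g.id for g in shortcut],
                "stats": dict(sc_stats),
                "shortcut": True,
            }
        )
        if all(s.het_per_kb <= config.het_max_per_kb for s in sc_stats.values()):
            genome_set = shortcut
            stats = sc_stats

    infected_ids = [
        g.id for g in genome_set if stats[g.id].breadth > config.breadth_infected
    ]
    if unresolved:
        call.status = "infected"
        call.strain_ids = infected_ids
    elif infected_ids:
        call.status = "infected"
        call.strain_ids = infected_ids
    else:
        call.status = "uninfected"
        call.strain_ids = []
    return call


def call_consensus(
    pile: Pileup, ref_id: str, config: DetectionConfig | None = None
) -> str:
    """Majority-allele consensus, falling back to the reference base at
    positions below consensus_min_depth.  Ties go to the alphabetically
    first base for determinism."""
    config = config or DetectionConfig()
    counts = pile.counts[ref_id]
    ref_codes = _seq_to_codes(pile.refs[ref_id].sequence)
    depth = counts.sum(axis=1)
    if depth.sum() == 0:
        logger.warning("no coverage on %s: consensus equals reference", ref_id)
    majority = counts.argmax(axis=1)  # argmax takes first max -> A<C<G<T tie-break
    use_ref = depth < config.consensus_min_depth
    out = np.where(use_ref, ref_codes, majority).astype(np.int8)
    from wolbshift.simdata import _codes_to_seq

    return _codes_to_seq(out)


def write_sam(
    path,
    alignments: Sequence[ReadAlignment],
    reads: Sequence[SimRead],
    references: Sequence[StrainGenome],
) -> None:
    """Export competitive alignments as SAM for interoperability.

    Internal coordinates are 0-based half-open; pysam converts to SAM's
    1-based convention on write.  Alignments are written as ungapped
    matches (the mapper's substitution-only contract).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": r.length} for r in references],
    }
    ref_index = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            read = reads[aln.read_index]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.id
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "I" * len(read.sequence)
            )
            if aln.mapped:
                seg.reference_id = ref_index[aln.ref_id]
                seg.reference_start = aln.ref_start
                seg.cigarstring = f"{len(read.sequence)}M"
                seg.mapping_quality = 60
                seg.set_tag("NM", aln.edit_distance)
            else:
                seg.is_unmapped = True
            out.write(seg)


def detect(
    reads: Sequence[SimRead],
    panel: Sequence[StrainGenome],
    config: DetectionConfig | None = None,
    sample_id: str = "sample",
) -> InfectionCall:
    """Full per-sample decision: screen, then iterate if not uninfected."""
    config = config or DetectionConfig()
    screen = screen_sample(reads, panel, config)
    if screen.preliminary_uninfected:
        return InfectionCall(
            sample_id=sample_id,
            status="uninfected",
            strain_ids=[],
            iteration_log=[{"screen_ranking": screen.ranking}],
        )
    by_id = {g.id: g for g in panel}
    ranked = [by_id[rid] for rid in screen.ranking]
    call = iterate_strains(reads, ranked, config, sample_id=sample_id)
    call.iteration_log.insert(0, {"screen_ranking": screen.ranking})
    return call
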