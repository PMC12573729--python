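"""Fragment-based average nucleotide identity and greedy genome dereplication.

ANI between a query and a reference genome is estimated FastANI-style: the
query is cut into consecutive non-overlapping fragments (terminal partial
fragment dropped), each fragment is placed at its best location in the
reference by shared-k-mer seed anchoring followed by bounded-error
alignment (edlib), and a fragment counts as aligned when its identity
reaches the per-fragment identity floor.  ANI is the mean identity over
aligned fragments (percent); the aligned fraction (MAF) is the share of
fragments that aligned.  ANI is asymmetric: both directions are computed
where it matters.

Dereplication greedily clusters genomes (processed longest-first) with an
existing representative when ANI exceeds the threshold in *both* directions
and the smaller of the two aligned fractions reaches the MAF threshold;
defaults are ANI > 99% over MAF >= 0.90.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from wolbshift.simdata import StrainGenome


@dataclass(frozen=True)
class AniResult:
    """Directed ANI between a query and a reference.

    ani is in percent and only defined (non-NaN) when aligned_fraction > 0.
    """

    query_id: str
    ref_id: str
    ani: float
    aligned_fraction: float
    n_fragments: int


@dataclass(frozen=True)
class DerepConfig:
    ani_threshold: float = 99.0
    maf_threshold: float = 0.90
    fragment_length: int = 1000
    seed_kmer: int = 15
    fragment_identity_floor: float = 80.0

    def __post_init__(self) -> None:
        if not 50 <= self.ani_threshold <= 100:
            raise ValueError("ani_threshold must be in [50, 100]")
        if not 0 < self.maf_threshold <= 1:
            raise ValueError("maf_threshold must be in (0, 1]")
        if self.fragment_length < 2 * self.seed_kmer:
            raise ValueError("fragment_length too short for seeding")


@dataclass
class ClusterSet:
    """Partition of genomes into ANI clusters with a representative each."""

    clusters: list[tuple[str, list[str]]]

    def representative_of(self, genome_id: str) -> str:
        for rep, members in self.clusters:
            if genome_id in members:
                return rep
        raise KeyError(genome_id)

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


# Diagonal bucket width and window margin for seed-anchored placement; both
# only need to exceed the plausible indel drift within one fragment.
_DIAG_BUCKET = 64
_WINDOW_MARGIN = 96
_MAX_CANDIDATE_BUCKETS = 4


def _best_fragment_identity(
    frag: str,
    ref: str,
    ref_index: dict[str, list[int]],
    config: DerepConfig,
) -> float | None:
    """Identity of the best seed-anchored placement of frag in ref, or None
    when no shared seed exists."""
    k = config.seed_kmer
    votes: dict[int, int] = defaultdict(int)
    for off in range(0, len(frag) - k + 1, k):
        for ref_pos in ref_index.get(frag[off : off + k], ()):
            votes[(ref_pos - off) // _DIAG_BUCKET] += 1
    if not votes:
        return None
    buckets = sorted(votes, key=lambda b: (-votes[b], b))[:_MAX_CANDIDATE_BUCKETS]
    max_edits = int(len(frag) * (1 - config.fragment_identity_floor / 100.0))
    best_ed = None
    for bucket in buckets:
        diag = bucket * _DIAG_BUCKET
        lo = max(0, diag - _WINDOW_MARGIN)
        hi = min(len(ref), diag + len(frag) + _DIAG_BUCKET + _WINDOW_MARGIN)
        res = edlib.align(frag, ref[lo:hi], mode="HW", task="distance", k=max_edits)
        ed = res["editDistance"]
        if ed >= 0 and (best_ed is None or ed < best_ed):
            best_ed = ed
            if best_ed == 0:
                break
    if best_ed is None:
        return None
    return 100.0 * (1.0 - best_ed / len(frag))


def fragment_ani(
    query: StrainGenome,
    ref: StrainGenome,
    config: DerepConfig | None = None,
    _ref_index: dict[str, list[int]] | None = None,
) -> AniResult:
    """Directed fragment-based ANI of query against ref."""
    config = config or DerepConfig()
    if not query.sequence or not ref.sequence:
        raise ValueError("sequences must be non-empty")
    flen = config.fragment_length
    n_fragments = len(query.sequence) // flen
    if n_fragments == 0:
        raise ValueError("query too short: no complete fragment")
    index = _ref_index if _ref_index is not None else _kmer_index(ref.sequence, config.seed_kmer)
    identities = []
    for i in range(n_fragments):
        frag = query.sequence[i * flen : (i + 1) * flen]
        ident = _best_fragment_identity(frag, ref.sequence, index, config)
        if ident is not None and ident >= config.fragment_identity_floor:
            identities.append(ident)
    aligned_fraction = len(identities) / n_fragments
    ani = float(np.mean(identities)) if identities else float("nan")
    return AniResult(query.id, ref.id, ani, aligned_fraction, n_fragments)


def _mutual_match(
    a: StrainGenome,
    b: StrainGenome,
    config: DerepConfig,
    indexes: dict[str, dict[str, list[int]]],
) -> bool:
    r_ab = fragment_ani(a, b, config, _ref_index=indexes[b.id])
    if r_ab.aligned_fraction < config.maf_threshold or not r_ab.ani > config.ani_threshold:
        return False
    r_ba = fragment_ani(b, a, config, _ref_index=indexes[a.id])
    return (
        r_ba.aligned_fraction >= config.maf_threshold
        and r_ba.ani > config.ani_threshold
    )


def dereplicate(
    genomes: list[StrainGenome], config: DerepConfig | None = None
) -> ClusterSet:
    """Greedy centroid clustering at ANI > threshold and MAF >= threshold.

    Genomes are processed longest-first (id ascending as tie-break), so each
    cluster's founder — and hence its representative — is its longest
    member.  The result is therefore invariant to the input order.
    """
    config = config or DerepConfig()
    if not genomes:
        raise ValueError("need at least one genome")
    ordered = sorted(genomes, key=lambda g: (-g.length, g.id))
    indexes = {g.id: _kmer_index(g.sequence, config.seed_kmer) for g in ordered}
    reps: list[StrainGenome] = []
    members: dict[str, list[str]] = {}
    for g in ordered:
        placed = False
        for rep in reps:
            if _mutual_match(g, rep, config, indexes):
                members[rep.id].append(g.id)
                placed = True
                break
        if not placed:
            reps.append(g)
            members[g.id] = [g.id]
    return ClusterSet(clusters=[(rep.id, members[rep.id]) for rep in reps])


def pairwise_ani_matrix(
    genomes: list[StrainGenome], config: DerepConfig | None = None
) -> pd.DataFrame:
    """Directed ANI for every ordered pair (long-format DataFrame).

    Columns: query, ref, ani, aligned_fraction.  The diagonal is 100 / 1.0
    by definition.
    """
    config = config or DerepConfig()
    indexes = {g.id: _kmer_index(g.sequence, config.seed_kmer) for g in genomes}
    rows = []
    for q in genomes:
        for r in genomes:
            if q.id == r.id:
                rows.append(
                    {"query": q.id, "ref": r.id, "ani": 100.0, "aligned_fraction": 1.0}
                )
            else:
                res = fragment_ani(q, r, config, _ref_index=indexes[r.id])
                rows.append(
                    {
                        "query": q.id,
                        "ref": r.id,
                        "ani": res.ani,
                        "aligned_fraction": res.aligned_fraction,
                    }
                )
    return pd.DataFrame(rows)


def ani_lookup(matrix: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Directed (query, ref) -> ani dict from a pairwise_ani_matrix frame."""
    return {
        (row.query, row.ref): row.ani for row in matrix.itertuples(index=False)
    }
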