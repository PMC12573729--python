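"""Screen symbiont genomes for cytoplasmic-incompatibility (cifA/cifB) and
male-killing (wmk) candidate loci.

The screen is a filter pipeline over standard homology-hit tables (BLAST
tabular, 12 standard columns plus qcovs) and gene annotations (GFF3-style
features):

1. keep hits with e-value < 1e-20 AND query coverage > 60% (both strict);
2. confirm each surviving hit by a reciprocal search: its top reciprocal
   hit must belong to the same locus family that produced it;
3. require concordance with the structural annotation: an annotated gene on
   the same contig and strand must overlap at least half of the hit span;
4. for the cif toxin-antidote system, count consecutive (adjacent gene,
   same strand, no intervening gene) cifA+cifB pairs as operons; remaining
   cif assignments are orphans.

Query ids carry their locus family as a prefix tag (e.g. ``cifA|cidA_wPip``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

FAMILIES = ("cifA", "cifB", "wmk")

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qcovs",
]


@dataclass(frozen=True)
class ScreenConfig:
    e_value_max: float = 1e-20
    query_coverage_min: float = 60.0  # percent
    gene_overlap_min: float = 0.5  # fraction of the hit span

    def __post_init__(self) -> None:
        if self.e_value_max <= 0:
            raise ValueError("e_value_max must be positive")
        if not 0 <= self.query_coverage_min <= 100:
            raise ValueError("query_coverage_min must be a percent")


@dataclass(frozen=True)
class LocusCall:
    """Per-genome counts of cif operons, orphan cifA/cifB and wmk copies."""

    genome_id: str
    n_cif_operons: int
    n_orphan_cifA: int
    n_orphan_cifB: int
    n_wmk: int


def locus_family(query_id: str) -> str:
    """Locus family from a family-tagged query id (prefix before '|')."""
    fam = query_id.split("|", 1)[0]
    if fam not in FAMILIES:
        raise ValueError(f"query id {query_id!r} carries no known family tag")
    return fam


def read_blast_tab(path, with_hit_id: bool = False) -> pd.DataFrame:
    """Read a 13-column BLAST tabular file (std 12 + qcovs)."""
    cols = (["hit_id"] if with_hit_id else []) + BLAST_COLUMNS
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    _validate_hits(df)
    return df


def _validate_hits(hits: pd.DataFrame) -> None:
    for i, row in enumerate(hits.itertuples(index=False)):
        if row.evalue < 0:
            raise ValueError(f"malformed hit row {i + 1}: negative e-value")
        if not 0 <= row.qcovs <= 100:
            raise ValueError(
                f"malformed hit row {i + 1}: query coverage {row.qcovs} not in [0, 100]"
            )


def filter_hits(hits: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Keep hits with e-value and query-coverage passing strict thresholds."""
    config = config or ScreenConfig()
    _validate_hits(hits)
    keep = (hits["evalue"] < config.e_value_max) & (
        hits["qcovs"] > config.query_coverage_min
    )
    return hits[keep].reset_index(drop=True)


def reciprocal_confirm(
    candidate_family: str,
    reciprocal_hits: pd.DataFrame,
    family_map: dict[str, str],
) -> bool:
    """Confirm a candidate by its top reciprocal hit.

    The top hit is the lowest e-value, ties broken by highest bit score,
    then lexicographic subject id; a candidate with no reciprocal hits is
    unconfirmed.
    """
    if reciprocal_hits.empty:
        return False
    top = reciprocal_hits.sort_values(
        ["evalue", "bitscore", "sseqid"], ascending=[True, False, True]
    ).iloc[0]
    return family_map.get(top["sseqid"]) == candidate_family


def hit_span(row) -> tuple[int, int, str]:
    """1-based inclusive subject span and strand of a hit row.

    sstart > send encodes the minus strand.
    """
    s, e = int(row["sstart"]), int(row["send"])
    if s <= e:
        return s, e, "+"
    return e, s, "-"


def annotation_concordance(
    hit_row,
    features: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> tuple[bool, str | None]:
    """Check whether an annotated gene supports the hit.

    Kept iff some gene on the same contig and strand overlaps at least
    gene_overlap_min of the hit span; returns (kept, feature_id).
    """
    config = config or ScreenConfig()
    start, end, strand = hit_span(hit_row)
    span = end - start + 1
    cands = features[
        (features["contig"] == hit_row["sseqid"]) & (features["strand"] == strand)
    ]
    best_id, best_olap = None, 0
    for feat in cands.itertuples(index=False):
        olap = min(end, feat.end) - max(start, feat.start) + 1
        if olap > best_olap:
            best_olap, best_id = olap, feat.feature_id
    if best_olap >= config.gene_overlap_min * span:
        return True, best_id
    return False, None


def detect_operons(
    cif_assignments: Sequence[tuple[str, str]],
    features: pd.DataFrame,
) -> tuple[int, dict[str, int]]:
    """Count cifA+cifB operons among confirmed gene assignments.

    ``cif_assignments`` maps feature_id -> family ('cifA'/'cifB').  A cifA
    gene and a cifB gene form one operon iff their features are adjacent in
    genomic order on the same contig and strand with no intervening
    predicted gene; pairing is greedy left-to-right and each gene joins at
    most one operon.  Returns (n_operons, orphan counts per family).
    """
    fam_of = dict(cif_assignments)
    ordered = features.sort_values(["contig", "start"]).reset_index(drop=True)
    used: set[str] = set()
    n_operons = 0
    for i in range(len(ordered) - 1):
        g1, g2 = ordered.iloc[i], ordered.iloc[i + 1]
        if g1["contig"] != g2["contig"] or g1["strand"] != g2["strand"]:
            continue
        f1, f2 = fam_of.get(g1["feature_id"]), fam_of.get(g2["feature_id"])
        if g1["feature_id"] in used or g2["feature_id"] in used:
            continue
        if {f1, f2} == {"cifA", "cifB"}:
            n_operons += 1
            used.update([g1["feature_id"], g2["feature_id"]])
    orphans = {"cifA": 0, "cifB": 0}
    for fid, fam in fam_of.items():
        if fid not in used:
            orphans[fam] += 1
    return n_operons, orphans


def screen_genome(
    genome_id: str,
    hits: pd.DataFrame,
    reciprocal: pd.DataFrame,
    features: pd.DataFrame,
    family_map: dict[str, str],
    config: ScreenConfig | None = None,
) -> LocusCall:
    """Run the full filter chain for one genome and count loci.

    ``hits`` must carry a ``hit_id`` column; ``reciprocal`` holds the
    reciprocal-search rows indexed by the same hit_id.
    """
    config = config or ScreenConfig()
    kept = filter_hits(hits, config)
    cif_assignments: list[tuple[str, str]] = []
    n_wmk = 0
    for row in kept.itertuples(index=False):
        fam = locus_family(row.qseqid)
        recip = reciprocal[reciprocal["hit_id"] == row.hit_id]
        if not reciprocal_confirm(fam, recip, family_map):
            continue
        ok, feature_id = annotation_concordance(
            kept.loc[kept["hit_id"] == row.hit_id].iloc[0], features, config
        )
        if not ok:
            continue
        if fam == "wmk":
            n_wmk += 1
        else:
            cif_assignments.append((feature_id, fam))
    n_operons, orphans = detect_operons(cif_assignments, features)
    return LocusCall(
        genome_id=genome_id,
        n_cif_operons=n_operons,
        n_orphan_cifA=orphans["cifA"],
        n_orphan_cifB=orphans["cifB"],
        n_wmk=n_wmk,
    )


def tabulate(calls: Sequence[LocusCall]) -> pd.DataFrame:
    """One row per genome: consecutive cifA+cifB, non-consecutive cifA,
    non-consecutive cifB, wmk."""
    return pd.DataFrame(
        [
            {
                "genome": c.genome_id,
                "consecutive_cifA_cifB": c.n_cif_operons,
                "non_consecutive_cifA": c.n_orphan_cifA,
                "non_consecutive_cifB": c.n_orphan_cifB,
                "wmk": c.n_wmk,
            }
            for c in calls
        ]
    )
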