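"""Synthetic data with known ground truth for every pipeline stage.

Four generators cover the pipeline's inputs:

* ``evolve_strains`` — symbiont genomes radiating from a common ancestor
  with controlled pairwise divergence.  Mutations are placed uniformly with
  replacement (multiple hits allowed), matching the Jukes-Cantor correction
  applied downstream, so realized p-distances fall slightly below targets.
* ``simulate_reads`` — single-end read sets from strain mixtures with a
  substitution-only error model and per-read truth labels.
* ``simulate_host_system`` — host sister-species pair histories under
  co-divergence / horizontal transfer / introgressive transfer / loss /
  uninfected scenarios, with symbiont and mitochondrial sequences evolved
  under configured clocks, a specimen-count occurrence matrix, and the true
  scenario recorded per pair.
* ``simulate_hit_tables`` — homology hit tables (BLAST tabular dialect),
  reciprocal-search tables and gene annotations with planted cif operons,
  orphan cifA/cifB, wmk copies, and decoys that each violate exactly one
  screening criterion.

Genomes are linear; reads are single-end; errors are substitutions only.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = {c: i for i, c in enumerate("ACGT")}


def _seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.empty(arr.size, dtype=np.int8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _codes_to_seq(codes: np.ndarray) -> str:
    return ALPHABET[codes].tobytes().decode()


@dataclass(frozen=True)
class StrainGenome:
    """A reference symbiont genome sequence with identity metadata."""

    id: str
    sequence: str
    source_host: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimStrainConfig:
    """Controls the symbiont genome radiation.

    target_distances is a symmetric matrix of expected substitutions/site
    between strain pairs; entries above 0.70 are rejected because the JC
    correction applied downstream approaches saturation there.
    """

    seed: int
    genome_length: int = 20_000
    n_strains: int = 2
    target_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.target_distances is None:
            self.target_distances = np.full(
                (self.n_strains, self.n_strains), 0.02
            )
            np.fill_diagonal(self.target_distances, 0.0)
        d = np.asarray(self.target_distances, dtype=float)
        if d.shape != (self.n_strains, self.n_strains):
            raise ValueError("target_distances shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("target_distances must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("target_distances diagonal must be zero")
        if np.any(d < 0) or np.any(d > 0.70):
            raise ValueError("pairwise distances must lie in [0, 0.70]")
        self.target_distances = d


@dataclass
class SimReadConfig:
    """Controls read simulation from a strain mixture."""

    mixture: list[tuple[str, float]]
    coverage: float = 25.0
    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        weights = [w for _, w in self.mixture]
        if not weights or any(w <= 0 for w in weights):
            raise ValueError("mixture weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


@dataclass
class HostSystemConfig:
    """Controls host sister-pair history simulation.

    wolb_rate is substitutions/site/host generation per lineage;
    mito_rate is percent uncorrected pairwise distance per My (a pairwise
    clock, so each lineage accrues half).  Genome lengths default to a
    20 kb symbiont and 15 kb mitogenome working scale.
    """

    n_pairs: int = 6
    split_time_range: tuple[float, float] = (2e5, 8e6)  # host generations
    sympatry_range: tuple[float, float] = (0.0, 1.0)
    scenario_weights: dict[str, float] = field(
        default_factory=lambda: {
            "codivergence": 0.2,
            "horizontal": 0.3,
            "introgressive": 0.15,
            "loss": 0.2,
            "uninfected": 0.15,
        }
    )
    wolb_rate: float = 6.4e-10
    mito_rate: float = 1.9
    generations_per_year: float = 2.0
    wolb_genome_length: int = 20_000
    mito_genome_length: int = 15_000
    n_specimens: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.scenario_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("scenario_weights must sum to 1")
        unknown = set(self.scenario_weights) - {
            "codivergence",
            "horizontal",
            "introgressive",
            "loss",
            "uninfected",
        }
        if unknown:
            raise ValueError(f"unknown scenarios: {unknown}")
        if self.wolb_rate <= 0 or self.mito_rate <= 0:
            raise ValueError("rates must be strictly positive")
        if not 1 <= self.generations_per_year <= 3:
            raise ValueError("generations_per_year must be in [1, 3]")


def _mutate(codes: np.ndarray, n_events: int, rng: np.random.Generator) -> np.ndarray:
    """Apply n substitution events at uniform positions with replacement."""
    out = codes.copy()
    if n_events == 0:
        return out
    positions = rng.integers(0, codes.size, size=n_events)
    shifts = rng.integers(1, 4, size=n_events)
    for pos, shift in zip(positions, shifts):
        out[pos] = (out[pos] + shift) % 4
    return out


def _star_branch_lengths(d: np.ndarray) -> np.ndarray:
    """Non-negative per-lineage branch lengths b with b_i + b_j ~ d_ij."""
    n = d.shape[0]
    if n == 1:
        return np.zeros(1)
    if n == 2:
        return np.array([d[0, 1] / 2.0, d[0, 1] / 2.0])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    a = np.zeros((len(pairs), n))
    rhs = np.zeros(len(pairs))
    for k, (i, j) in enumerate(pairs):
        a[k, i] = a[k, j] = 1.0
        rhs[k] = d[i, j]
    b, _ = nnls(a, rhs)
    return b


def evolve_strains(
    config: SimStrainConfig,
) -> tuple[list[StrainGenome], pd.DataFrame]:
    """Radiate n strains from a random ancestor on a star topology.

    Per-lineage branch lengths are fit (non-negative least squares) so that
    expected pairwise divergence matches ``target_distances``; each lineage
    then receives Poisson(branch_length x L) substitution events at uniform
    positions with replacement.  Returns the genomes and a truth table of
    realized (Hamming) pairwise p-distances.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    root = rng.integers(0, 4, size=L, dtype=np.int8)
    branches = _star_branch_lengths(config.target_distances)
    genomes: list[StrainGenome] = []
    code_arrays: list[np.ndarray] = []
    for i in range(config.n_strains):
        n_events = rng.poisson(branches[i] * L)
        codes = _mutate(root, n_events, rng)
        code_arrays.append(codes)
        genomes.append(StrainGenome(id=f"strain_{i:02d}", sequence=_codes_to_seq(codes)))
    ids = [g.id for g in genomes]
    realized = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(config.n_strains):
        for j in range(i + 1, config.n_strains):
            p = float(np.mean(code_arrays[i] != code_arrays[j]))
            realized.iloc[i, j] = realized.iloc[j, i] = p
    return genomes, realized


@dataclass(frozen=True)
class SimRead:
    """A simulated read with its truth label."""

    id: str
    sequence: str
    source_strain: str
    position: int


def simulate_reads(
    genomes: Sequence[StrainGenome], config: SimReadConfig
) -> list[SimRead]:
    """Draw single-end reads from a weighted strain mixture.

    Expected read count per strain is weight x coverage x L / read_length
    (rounded); start positions are uniform on [0, L - read_length]; errors
    are per-base substitutions at ``error_rate``.
    """
    by_id = {g.id: g for g in genomes}
    for sid, _ in config.mixture:
        if sid not in by_id:
            raise KeyError(f"mixture strain {sid!r} not among provided genomes")
    rng = np.random.default_rng(config.seed)
    reads: list[SimRead] = []
    for sid, weight in config.mixture:
        genome = by_id[sid]
        L = genome.length
        if config.read_length > L:
            raise ValueError("read_length exceeds genome_length")
        n_reads = int(round(weight * config.coverage * L / config.read_length))
        codes = _seq_to_codes(genome.sequence)
        starts = rng.integers(0, L - config.read_length + 1, size=n_reads)
        for k, start in enumerate(starts):
            frag = codes[start : start + config.read_length].copy()
            if config.error_rate > 0:
                err_mask = rng.random(config.read_length) < config.error_rate
                n_err = int(err_mask.sum())
                if n_err:
                    frag[err_mask] = (
                        frag[err_mask] + rng.integers(1, 4, size=n_err)
                    ) % 4
            reads.append(
                SimRead(
                    id=f"{sid}_r{k:06d}",
                    sequence=_codes_to_seq(frag),
                    source_strain=sid,
                    position=int(start),
                )
            )
    return reads


SCENARIOS = ("codivergence", "horizontal", "introgressive", "loss", "uninfected")

# Two isolates count as the same strain when their expected divergence stays
# below the 99%-ANI dereplication threshold (distance 0.01).
SAME_STRAIN_DISTANCE = 0.01


@dataclass
class HostSystem:
    """Output of simulate_host_system: pair table, occurrence matrix and
    per-species symbiont / mitochondrial consensus sequences."""

    pair_table: pd.DataFrame
    occurrence: pd.DataFrame  # species x strain specimen counts
    n_specimens: pd.Series
    wolb_seqs: dict[str, str]  # species -> symbiont isolate consensus
    mito_seqs: dict[str, str]  # species -> mitochondrial sequence
    strain_sets: dict[str, frozenset]  # species -> true strain ids


def simulate_host_system(config: HostSystemConfig) -> HostSystem:
    """Simulate sister-pair histories with known transfer scenarios.

    Co-divergence: symbiont split equals the host split.  Horizontal: the
    symbiont split is drawn independently of the host split (older or
    younger).  Introgressive: symbiont and mitochondrial splits are equal
    and younger than the host nuclear split.  Loss: one species has lost the
    infection.  Uninfected: neither species carries the symbiont.
    """
    rng = np.random.default_rng(config.seed)
    gpy = config.generations_per_year
    names = list(config.scenario_weights)
    probs = np.array([config.scenario_weights[k] for k in names])
    rows = []
    occurrence: dict[str, dict[str, int]] = {}
    wolb_seqs: dict[str, str] = {}
    mito_seqs: dict[str, str] = {}
    strain_sets: dict[str, frozenset] = {}
    n_spec = {}
    strain_counter = 0

    for p in range(config.n_pairs):
        sp_a, sp_b = f"sp{p:02d}a", f"sp{p:02d}b"
        split_gen = float(rng.uniform(*config.split_time_range))
        split_my = split_gen / (gpy * 1e6)
        sympatry = float(rng.uniform(*config.sympatry_range))
        scenario = names[rng.choice(len(names), p=probs)]

        # mitochondrial split (in My): equals the host split except under
        # introgression, where the mitogenome hitchhikes with the symbiont.
        t_wolb_gen = np.nan
        if scenario == "codivergence" or scenario == "loss":
            t_wolb_gen = split_gen
            t_mito_my = split_my
        elif scenario == "horizontal":
            t_wolb_gen = float(split_gen * rng.uniform(0.1, 4.0))
            t_mito_my = split_my
        elif scenario == "introgressive":
            t_wolb_gen = float(split_gen * rng.uniform(0.05, 0.8))
            t_mito_my = t_wolb_gen / (gpy * 1e6)
        else:  # uninfected
            t_mito_my = split_my

        # mitochondrial sequences (pairwise clock: half per lineage)
        mito_root = rng.integers(0, 4, size=config.mito_genome_length, dtype=np.int8)
        d_mito_lineage = (config.mito_rate / 100.0) * t_mito_my / 2.0
        for sp in (sp_a, sp_b):
            n_ev = rng.poisson(d_mito_lineage * config.mito_genome_length)
            mito_seqs[sp] = _codes_to_seq(_mutate(mito_root, n_ev, rng))

        # symbiont sequences and strain identities
        infected = {sp_a: scenario in ("codivergence", "horizontal", "introgressive"),
                    sp_b: scenario in ("codivergence", "horizontal", "introgressive")}
        if scenario == "loss":
            infected[sp_a] = True  # species b lost the infection
        if any(infected.values()):
            wolb_root = rng.integers(
                0, 4, size=config.wolb_genome_length, dtype=np.int8
            )
            d_wolb_lineage = config.wolb_rate * t_wolb_gen
            expected_pair_distance = 2 * d_wolb_lineage
            shared = expected_pair_distance < SAME_STRAIN_DISTANCE
            if shared:
                strain_ids = {sp_a: f"wstr_{strain_counter:03d}",
                              sp_b: f"wstr_{strain_counter:03d}"}
                strain_counter += 1
            else:
                strain_ids = {sp_a: f"wstr_{strain_counter:03d}",
                              sp_b: f"wstr_{strain_counter + 1:03d}"}
                strain_counter += 2
            for sp in (sp_a, sp_b):
                if not infected[sp]:
                    continue
                n_ev = rng.poisson(d_wolb_lineage * config.wolb_genome_length)
                wolb_seqs[sp] = _codes_to_seq(_mutate(wolb_root, n_ev, rng))
                strain_sets[sp] = frozenset([strain_ids[sp]])
        for sp in (sp_a, sp_b):
            if sp not in strain_sets:
                strain_sets[sp] = frozenset()

        # occurrence counts: specimens carrying the strain per species
        for sp in (sp_a, sp_b):
            n_spec[sp] = config.n_specimens
            occurrence[sp] = {}
            if infected[sp]:
                prevalence = rng.uniform(0.3, 1.0)
                count = 1 + rng.binomial(config.n_specimens - 1, prevalence)
                (strain,) = strain_sets[sp]
                occurrence[sp][strain] = int(count)

        rows.append(
            {
                "pair_id": f"pair{p:02d}",
                "species_a": sp_a,
                "species_b": sp_b,
                "split_gen": split_gen,
                "split_my": split_my,
                "sympatry": sympatry,
                "scenario": scenario,
                "wolb_split_gen": t_wolb_gen,
                "mito_split_my": t_mito_my,
                "shares_strain": bool(strain_sets[sp_a] & strain_sets[sp_b]),
            }
        )

    all_strains = sorted({s for ss in strain_sets.values() for s in ss})
    occ = pd.DataFrame(0, index=sorted(occurrence), columns=all_strains, dtype=int)
    for sp, counts in occurrence.items():
        for strain, c in counts.items():
            occ.loc[sp, strain] = c
    return HostSystem(
        pair_table=pd.DataFrame(rows),
        occurrence=occ,
        n_specimens=pd.Series(n_spec),
        wolb_seqs=wolb_seqs,
        mito_seqs=mito_seqs,
        strain_sets=strain_sets,
    )


# ---------------------------------------------------------------------------
# Hit-table / annotation fixtures for the CI/MK locus screen
# ---------------------------------------------------------------------------

FAMILIES = ("cifA", "cifB", "wmk")
DECOY_KINDS = ("evalue", "qcov", "reciprocal", "annotation")

_QUERY_NAMES = {"cifA": "cifA|cidA_wPip", "cifB": "cifB|cidB_wPip", "wmk": "wmk|wmk_wMel"}
_PROTEOME_IDS = {"cifA": "prot_cidA", "cifB": "prot_cidB", "wmk": "prot_wmk"}
_QUERY_LENGTHS = {"cifA": 475, "cifB": 1174, "wmk": 309}


@dataclass
class HitTablePlan:
    """Planted loci and decoys for one genome's screen fixture."""

    genome_id: str
    n_operons: int = 1
    n_orphan_cifA: int = 0
    n_orphan_cifB: int = 0
    n_wmk: int = 0
    decoys: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.decoys) - set(DECOY_KINDS)
        if bad:
            raise ValueError(f"unknown decoy kinds: {bad}")


@dataclass
class HitTableFixture:
    """Simulated screen inputs plus the truth bookkeeping."""

    hits: pd.DataFrame
    reciprocal: pd.DataFrame
    features: pd.DataFrame
    family_map: dict[str, str]
    truth: pd.DataFrame


def simulate_hit_tables(plan: HitTablePlan, seed: int = 0) -> HitTableFixture:
    """Build hit / reciprocal / annotation tables with known truth.

    True planted loci receive e-values < 1e-20, query coverage > 60%, a
    concordant top reciprocal hit and an overlapping same-strand gene
    feature.  Each decoy violates exactly one criterion: a weak e-value
    (1e-10), low query coverage (50%), a discordant reciprocal top hit, or a
    placement with no overlapping annotated gene.
    """
    rng = np.random.default_rng(seed)
    contig = f"{plan.genome_id}_contig1"
    gene_len = 900
    gap = 300
    slots: list[tuple[str, str | None, str | None]] = []  # (kind, family, decoy_kind)
    for _ in range(plan.n_operons):
        slots.append(("locus", "cifA", None))
        slots.append(("locus", "cifB", None))
        slots.append(("filler", None, None))
    for fam, n in (("cifA", plan.n_orphan_cifA), ("cifB", plan.n_orphan_cifB),
                   ("wmk", plan.n_wmk)):
        for _ in range(n):
            slots.append(("locus", fam, None))
            slots.append(("filler", None, None))
    for kind in plan.decoys:
        fam = FAMILIES[rng.choice(len(FAMILIES))]
        slots.append(("decoy", fam, kind))
        slots.append(("filler", None, None))

    features = []
    hit_rows = []
    recip_rows = []
    truth_rows = []
    pos = 1
    gene_idx = 0
    hit_idx = 0
    for kind, fam, decoy_kind in slots:
        start, end = pos, pos + gene_len - 1
        pos = end + 1 + gap
        strand = "+"
        has_gene = True
        if kind == "decoy" and decoy_kind == "annotation":
            has_gene = False  # hit falls in an intergenic region
        if has_gene:
            feature_id = f"{plan.genome_id}_gene{gene_idx:04d}"
            gene_idx += 1
            product = "hypothetical protein" if kind == "filler" else f"{fam} candidate"
            features.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "feature_id": feature_id,
                    "product": product,
                }
            )
        if kind == "filler":
            continue
        qlen = _QUERY_LENGTHS[fam]
        evalue = 10.0 ** rng.uniform(-60, -25)
        qcov = float(rng.uniform(70, 100))
        recip_ok = True
        if kind == "decoy":
            if decoy_kind == "evalue":
                evalue = 1e-10
            elif decoy_kind == "qcov":
                qcov = 50.0
            elif decoy_kind == "reciprocal":
                recip_ok = False
        hit_id = f"{plan.genome_id}_hit{hit_idx:04d}"
        hit_idx += 1
        align_len = int(qlen * qcov / 100)
        hit_rows.append(
            {
                "hit_id": hit_id,
                "qseqid": _QUERY_NAMES[fam],
                "sseqid": contig,
                "pident": float(rng.uniform(40, 95)),
                "length": align_len,
                "mismatch": int(align_len * 0.2),
                "gapopen": 0,
                "qstart": 1,
                "qend": align_len,
                "sstart": start,
                "send": end,
                "evalue": evalue,
                "bitscore": float(rng.uniform(200, 900)),
                "qcovs": qcov,
            }
        )
        # reciprocal search for this candidate region
        same_prot = _PROTEOME_IDS[fam]
        other_fams = [f for f in FAMILIES if f != fam]
        wrong_prot = _PROTEOME_IDS[other_fams[rng.choice(len(other_fams))]]
        top, second = (same_prot, wrong_prot) if recip_ok else (wrong_prot, same_prot)
        recip_rows.append(
            {"hit_id": hit_id, "sseqid": top, "evalue": 1e-50, "bitscore": 800.0}
        )
        recip_rows.append(
            {"hit_id": hit_id, "sseqid": second, "evalue": 1e-30, "bitscore": 400.0}
        )
        truth_rows.append(
            {
                "hit_id": hit_id,
                "family": fam,
                "kind": kind,
                "decoy_kind": decoy_kind,
                "in_operon": kind == "locus" and fam in ("cifA", "cifB")
                and False,  # filled below
            }
        )

    truth = pd.DataFrame(truth_rows)
    # first 2*n_operons true cif loci are the planted adjacent pairs
    if len(truth):
        operon_hits = truth.index[
            (truth.kind == "locus") & truth.family.isin(["cifA", "cifB"])
        ][: 2 * plan.n_operons]
        truth.loc[operon_hits, "in_operon"] = True

    family_map = {v: k for k, v in _PROTEOME_IDS.items()}
    return HitTableFixture(
        hits=pd.DataFrame(hit_rows),
        reciprocal=pd.DataFrame(recip_rows),
        features=pd.DataFrame(features),
        family_map=family_map,
        truth=truth,
    )
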