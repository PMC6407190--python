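"""Synthetic post-tetraploidy grass genomes with ground truth.

The generator emulates the study system: a proto-genome of single-copy
chromosomes, a whole-genome duplication producing homoeologous pairs,
stochastic fractionation of duplicated gene copies, and a trajectory of
telomere-centric rearrangements sampled from the event algebra.  Similarity
scores between genomes are drawn per homology layer, with ortholog E-values
stochastically dominating (smaller than) outparalog E-values, so the
downstream filter/chain/paint/infer pipeline can be exercised and benchmarked
against the retained true event log without any external data.

Defaults mirror the study conditions: 7 proto-chromosomes (14 after
duplication, i.e. 7 homoeologous pairs), an NCF-dominated event mix (11 NCFs,
1 EEJ and 1 reciprocal translocation across the two studied lineages), and a
0.7 duplicate-retention rate typical of fractionating paleopolyploids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    Chromosome,
    EventType,
    FusionEvent,
    GeneLocus,
    Genome,
    INTERGENE_GAP_BP,
    apply_eej,
    apply_ncf,
    apply_reciprocal_translocation,
    apply_inversion,
    drop_satellites,
    pericentromeric_window,
    relayout,
    telomere_window,
)

__all__ = [
    "SimulationConfig",
    "SimilarityHit",
    "SimulationExhaustedError",
    "make_proto_genome",
    "apply_wgd",
    "fractionate",
    "random_trajectory",
    "emit_similarity",
]

#: log10 E-value floor: best observable similarity (also the self-hit value)
LOG10_EVALUE_FLOOR = -180.0


class SimulationExhaustedError(RuntimeError):
    """No valid participants remain for the requested event."""


@dataclass
class SimulationConfig:
    """Knobs of the generator.

    ``evalue_layers`` maps homology layer to the (mean, sd) of a truncated
    normal over log10 E; only the relative ordering of layers matters
    downstream.  ``event_mix`` weights are unnormalized.
    """

    n_proto: int = 7
    genes_per_chrom: int = 200
    retention_rate: float = 0.7
    event_mix: dict[str, float] = field(default_factory=lambda: {
        EventType.NCF: 11.0,
        EventType.EEJ: 1.0,
        EventType.RECIPROCAL_TRANSLOCATION: 1.0,
        EventType.INVERSION: 0.0,
    })
    n_events: int = 7
    seed: int = 0
    evalue_layers: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "ortholog": (-80.0, 10.0),
        "outparalog": (-30.0, 10.0),
        "noise": (-8.0, 2.0),
    })
    noise_rate: float = 0.0
    gene_length_bp: int = 2_000
    intergene_gap_bp: int = INTERGENE_GAP_BP
    pericentromere_frac: float = 0.05
    telomere_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.retention_rate <= 1.0):
            raise ValueError("retention_rate must be in (0, 1]")
        if any(w < 0 for w in self.event_mix.values()) or not any(
            w > 0 for w in self.event_mix.values()
        ):
            raise ValueError("event_mix weights must be nonnegative and not all zero")


@dataclass
class SimilarityHit:
    """One directed similarity hit (query -> subject)."""

    query_id: str
    subject_id: str
    log10_evalue: float
    rank: int = 0
    layer: str = "ortholog"


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def make_proto_genome(config: SimulationConfig, *, prefix: str = "A",
                      genome_id: str | None = None) -> Genome:
    """Proto-genome of ``n_proto`` single-origin chromosomes.

    Every gene is the sole member of its own family; centromeres sit at the
    gene-count midpoint; ``origin_label`` is the gene's own chromosome.
    """
    if config.n_proto < 1:
        raise ValueError("n_proto must be >= 1")
    chroms = []
    for ci in range(1, config.n_proto + 1):
        chrom_id = f"{prefix}{ci}"
        loci = []
        for gi in range(config.genes_per_chrom):
            gid = f"{chrom_id}g{gi:04d}"
            loci.append(GeneLocus(
                gene_id=gid, family_id=gid, chrom_id=chrom_id, index=gi,
                start_bp=0, end_bp=config.gene_length_bp - 1,
                strand="+", origin_label=chrom_id, copy=0,
            ))
        chrom = Chromosome(chrom_id=chrom_id, loci=loci,
                           centromere_index=config.genes_per_chrom // 2)
        relayout(chrom, config.intergene_gap_bp)
        chroms.append(chrom)
    return Genome(genome_id=genome_id or f"{prefix}-proto", chromosomes=chroms)


def apply_wgd(genome: Genome, *, suffix: str = "x") -> Genome:
    """Whole-genome duplication: every chromosome is copied with its id and
    gene ids suffixed; duplicated genes join their progenitor's family; the
    duplicate pairs populate ``homoeolog_pairs``."""
    if any(e.event_type == EventType.WGD for e in genome.event_log):
        raise RuntimeError("genome has already undergone a WGD")
    g = genome.copy()
    new_chroms = []
    for chrom in g.chromosomes:
        dup_id = f"{chrom.chrom_id}{suffix}"
        loci = [
            GeneLocus(
                gene_id=f"{loc.gene_id}{suffix}", family_id=loc.family_id,
                chrom_id=dup_id, index=loc.index, start_bp=loc.start_bp,
                end_bp=loc.end_bp, strand=loc.strand, origin_label=dup_id,
                copy=1,
            )
            for loc in chrom.loci
        ]
        new_chroms.append(Chromosome(
            chrom_id=dup_id, loci=loci, centromere_index=chrom.centromere_index,
        ))
        g.homoeolog_pairs.add(frozenset((chrom.chrom_id, dup_id)))
    g.chromosomes.extend(new_chroms)
    g.event_log.append(FusionEvent(
        event_type=EventType.WGD,
        products=[c.chrom_id for c in new_chroms],
    ))
    return g


def fractionate(genome: Genome, retention_rate: float, seed: int,
                *, unbiased: bool = False,
                gap_bp: int = INTERGENE_GAP_BP) -> Genome:
    """Post-WGD gene loss: each duplicated copy survives with probability
    ``retention_rate``.

    By default the duplicate (``copy == 1``) member is the one at risk,
    keeping one complete lineage as a clean reference; ``unbiased=True``
    deletes a random member of each two-member family instead.  Survivors
    keep their relative order.
    """
    if not any(e.event_type == EventType.WGD for e in genome.event_log):
        raise RuntimeError("fractionation requires a prior WGD")
    g = genome.copy()
    rng = np.random.default_rng(seed)

    members: dict[str, list[GeneLocus]] = {}
    for loc in g.loci():
        members.setdefault(loc.family_id, []).append(loc)

    doomed: set[str] = set()
    for family, locs in sorted(members.items()):
        if len(locs) != 2:
            continue
        if rng.random() < retention_rate:
            continue
        if unbiased:
            victim = locs[int(rng.integers(0, 2))]
        else:
            victim = next(l for l in locs if l.copy == 1)
        doomed.add(victim.gene_id)

    for chrom in g.chromosomes:
        chrom.loci = [l for l in chrom.loci if l.gene_id not in doomed]
        chrom.centromere_index = min(chrom.centromere_index, len(chrom.loci))
        relayout(chrom, gap_bp)
    g.event_log.append(FusionEvent(
        event_type=EventType.FRACTIONATION,
        details={"n_lost": len(doomed), "retention_rate": retention_rate},
    ))
    return g


# ---------------------------------------------------------------------------
# random trajectories
# ---------------------------------------------------------------------------

_MIN_CHROM_GENES = 20  # chromosomes smaller than this are not event-eligible

#: breakpoints are kept this many genes away from origin-run boundaries, so
#: every origin run the event creates is wide enough to be detectable
#: downstream (paint segments need a handful of supporting anchors); a
#: breakpoint closer to a boundary leaves the event underdetermined from the
#: final paint no matter how good the block detection is
_MIN_RUN_FLANK = 5


def _eligible(genome: Genome) -> list[Chromosome]:
    return [c for c in genome.chromosomes
            if not c.is_satellite and len(c) >= _MIN_CHROM_GENES]


def _uniform_run(chrom: Chromosome, point: int, *, right: bool,
                 width: int = _MIN_RUN_FLANK) -> bool:
    """True when the ``width`` loci on one side of split point ``point``
    (to the right when ``right`` else to the left) exist and share one
    origin label."""
    n = len(chrom)
    lo, hi = (point, point + width) if right else (point - width, point)
    if lo < 0 or hi > n:
        return False
    return len({chrom.loci[i].origin_label for i in range(lo, hi)}) == 1


def _run_flanked(chrom: Chromosome, point: int, width: int = _MIN_RUN_FLANK) -> bool:
    """True when the ``width`` loci on each side of split point ``point``
    exist and each side is origin-uniform (the split does not shave an
    origin run below detectability)."""
    n = len(chrom)
    if point - width < 0 or point + width > n:
        return False
    left = {chrom.loci[i].origin_label for i in range(point - width, point)}
    right = {chrom.loci[i].origin_label for i in range(point, point + width)}
    return len(left) == 1 and len(right) == 1


def _ncf_insertion_candidates(chrom: Chromosome, frac: float) -> list[int]:
    """Pericentromeric insertion points whose flanking loci share one origin
    label, with at least ``_MIN_RUN_FLANK`` same-label genes on each side.
    Run-boundary insertions are excluded so that the true event is
    recoverable from the final paint (a boundary insertion leaves the invaded
    label genuinely underdetermined)."""
    lo, hi = pericentromeric_window(chrom, frac)
    return [
        p for p in range(lo, hi + 1)
        if 0 < p < len(chrom)
        and chrom.loci[p - 1].origin_label == chrom.loci[p].origin_label
        and _run_flanked(chrom, p)
    ]


def random_trajectory(genome: Genome, config: SimulationConfig,
                      *, seed: int | None = None,
                      drop_satellites_at_end: bool = True) -> Genome:
    """Sample ``config.n_events`` rearrangements from ``event_mix`` with
    uniformly drawn valid participants and breakpoints, then (by default)
    drop all satellites.  The returned genome's event log is the ground
    truth, reproducible from (config, seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = genome.copy()
    types = sorted(k for k, w in config.event_mix.items() if w > 0)
    weights = np.array([config.event_mix[t] for t in types], dtype=float)
    weights = weights / weights.sum()

    for _ in range(config.n_events):
        placed = False
        for _attempt in range(200):
            etype = types[int(rng.choice(len(types), p=weights))]
            pool = _eligible(g)
            if len(pool) < (1 if etype == EventType.INVERSION else 2):
                break
            if etype == EventType.NCF:
                donor, recipient = (pool[i] for i in rng.choice(len(pool), 2, replace=False))
                w_d = telomere_window(donor, config.telomere_frac)
                left = int(rng.integers(1, w_d + 1))
                right = int(rng.integers(len(donor) - w_d, len(donor)))
                if not (left < right and left <= donor.centromere_index <= right):
                    continue
                seg = donor.loci[left:right]
                if seg[0].origin_label != seg[-1].origin_label:
                    continue  # EEJ products make unparseable donors
                if not (_uniform_run(donor, left, right=True)
                        and _uniform_run(donor, right, right=False)):
                    continue  # cut would shave an origin run below detectability
                points = _ncf_insertion_candidates(recipient, config.pericentromere_frac)
                if not points:
                    continue
                p = int(points[int(rng.integers(0, len(points)))])
                g = apply_ncf(g, donor.chrom_id, recipient.chrom_id, left, right, p,
                              enforce_windows=True,
                              pericentromere_frac=config.pericentromere_frac,
                              gap_bp=config.intergene_gap_bp)
                placed = True
                break
            if etype == EventType.EEJ:
                a, b = (pool[i] for i in rng.choice(len(pool), 2, replace=False))
                w_a = telomere_window(a, config.telomere_frac)
                w_b = telomere_window(b, config.telomere_frac)
                cut_a = int(rng.integers(len(a) - w_a, len(a)))
                cut_b = int(rng.integers(1, w_b + 1))
                if not (_uniform_run(a, cut_a, right=False)
                        and _uniform_run(b, cut_b, right=True)):
                    continue  # junction run too short to detect
                g = apply_eej(g, a.chrom_id, b.chrom_id, cut_a, cut_b,
                              enforce_windows=True,
                              telomere_frac=config.telomere_frac,
                              gap_bp=config.intergene_gap_bp)
                placed = True
                break
            if etype == EventType.RECIPROCAL_TRANSLOCATION:
                a, b = (pool[i] for i in rng.choice(len(pool), 2, replace=False))
                # keep detectable runs on each side of each cut and avoid
                # origin-run boundaries so the exchange is recoverable
                cand_a = [p for p in range(a.centromere_index, len(a))
                          if _run_flanked(a, p)]
                cand_b = [p for p in range(b.centromere_index, len(b))
                          if _run_flanked(b, p)]
                if not cand_a or not cand_b:
                    continue
                cut_a = int(cand_a[int(rng.integers(0, len(cand_a)))])
                cut_b = int(cand_b[int(rng.integers(0, len(cand_b)))])
                g = apply_reciprocal_translocation(g, a.chrom_id, b.chrom_id,
                                                   cut_a, cut_b,
                                                   gap_bp=config.intergene_gap_bp)
                placed = True
                break
            if etype == EventType.INVERSION:
                c = pool[int(rng.integers(0, len(pool)))]
                i = int(rng.integers(0, len(c) - 1))
                j = int(rng.integers(i + 1, len(c) + 1))
                g = apply_inversion(g, c.chrom_id, i, j,
                                    gap_bp=config.intergene_gap_bp)
                placed = True
                break
        if not placed:
            raise SimulationExhaustedError(
                "no valid participants/breakpoints for the requested event mix"
            )
    if drop_satellites_at_end:
        g = drop_satellites(g)
    return g


# ---------------------------------------------------------------------------
# similarity emission
# ---------------------------------------------------------------------------

def _draw_log10e(rng: np.random.Generator, mu: float, sd: float) -> float:
    return float(np.clip(rng.normal(mu, sd), LOG10_EVALUE_FLOOR, 0.0))


def emit_similarity(genome_a: Genome, genome_b: Genome,
                    config: SimulationConfig, seed: int) -> list[SimilarityHit]:
    """Synthetic all-vs-all similarity from genome_a queries to genome_b.

    Per query gene: a hit to every same-family subject, with log10 E drawn
    from the ortholog layer when the two genes are the same post-WGD copy
    lineage and from the outparalog layer otherwise, plus (optionally)
    uniform noise hits at ``noise_rate`` per query.  When the two genomes are
    the same object or share an id, each gene's rank-1 hit is itself at the
    E-value floor.  Ranks are assigned per query, rank 1 = lowest E-value.
    """
    rng = np.random.default_rng(seed)
    self_comparison = genome_a is genome_b or genome_a.genome_id == genome_b.genome_id
    mu_o, sd_o = config.evalue_layers["ortholog"]
    mu_p, sd_p = config.evalue_layers["outparalog"]
    mu_n, sd_n = config.evalue_layers.get("noise", (-8.0, 2.0))

    by_family: dict[str, list[GeneLocus]] = {}
    subjects: list[GeneLocus] = []
    for loc in genome_b.loci():
        by_family.setdefault(loc.family_id, []).append(loc)
        subjects.append(loc)

    hits: list[SimilarityHit] = []
    for q in genome_a.loci():
        q_hits: list[SimilarityHit] = []
        for s in by_family.get(q.family_id, []):
            if s.gene_id == q.gene_id and self_comparison:
                q_hits.append(SimilarityHit(q.gene_id, s.gene_id,
                                            LOG10_EVALUE_FLOOR, layer="self"))
                continue
            # within a family the post-WGD copy number identifies the lineage
            if s.copy == q.copy:
                q_hits.append(SimilarityHit(
                    q.gene_id, s.gene_id, _draw_log10e(rng, mu_o, sd_o),
                    layer="ortholog"))
            else:
                q_hits.append(SimilarityHit(
                    q.gene_id, s.gene_id, _draw_log10e(rng, mu_p, sd_p),
                    layer="outparalog"))
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            s = subjects[int(rng.integers(0, len(subjects)))]
            if s.gene_id != q.gene_id:
                q_hits.append(SimilarityHit(
                    q.gene_id, s.gene_id, _draw_log10e(rng, mu_n, sd_n),
                    layer="noise"))
        q_hits.sort(key=lambda h: (h.log10_evalue, h.subject_id))
        for r, h in enumerate(q_hits, start=1):
            h.rank = r
        hits.extend(q_hits)
    return hits
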