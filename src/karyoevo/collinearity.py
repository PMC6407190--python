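"""Collinear-block detection by sparse dynamic-programming chaining.

Homologous gene pairs are chained per chromosome pair and orientation under
the classical synteny scoring scheme: each anchor contributes
``min(-log10 E, match_cap)``; consecutive anchors pay one gap penalty unit
per 10 kb of physical distance, summed over both chromosomes; and no more
than ``mg`` intervening genes may separate consecutive anchors on either
chromosome.  Chains are extracted greedily best-first with deterministic
tie-breaking, filtered by a minimum anchor count and a block significance
E-value, and finally classified as primary (orthologous: best in its region)
or secondary (paralogous, from the ancestral polyploidy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .homology import HomologPair
from .model import Genome

__all__ = [
    "ChainingParams",
    "Anchor",
    "CollinearBlock",
    "Background",
    "PositionIndex",
    "chain_blocks",
    "block_significance",
    "classify_homology_layer",
]


@dataclass
class ChainingParams:
    """Scoring and filtering knobs for the chainer.

    ``mg`` is the maximum number of intervening genes between consecutive
    anchors on either chromosome; ``match_cap`` caps the per-anchor score;
    the gap penalty is per 10 kb of inter-anchor distance summed over both
    chromosomes (a per-chromosome-maximum alternative is selectable).
    """

    mg: int = 40
    match_cap: float = 50.0
    gap_penalty_per_10kb: float = 1.0
    block_evalue_threshold: float = 1e-10
    min_anchors: int = 5
    significance_method: str = "analytic"  # or "permutation"
    permutation_reps: int = 1000
    permutation_seed: int = 0
    gap_distance_mode: str = "sum"  # or "per_chromosome_max"

    def __post_init__(self) -> None:
        if self.mg < 1:
            raise ValueError("mg must be >= 1")
        if self.match_cap <= 0:
            raise ValueError("match_cap must be positive")

    def anchor_weight(self, log10_evalue: float) -> float:
        """min(-log10 E, match_cap); E = 0 counts as the cap."""
        if log10_evalue == float("-inf"):
            return self.match_cap
        return min(-log10_evalue, self.match_cap)


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    ord_a: int
    ord_b: int
    bp_a: int
    bp_b: int
    end_bp_a: int
    end_bp_b: int
    weight: float


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[Anchor]
    orientation: str  # "forward" | "reverse"
    score: float
    evalue: float = 1.0
    homology_class: str | None = None  # "primary" | "secondary"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def start_a_bp(self) -> int:
        return min(a.bp_a for a in self.anchors)

    @property
    def end_a_bp(self) -> int:
        return max(a.end_bp_a for a in self.anchors)

    @property
    def start_b_bp(self) -> int:
        return min(a.bp_b for a in self.anchors)

    @property
    def end_b_bp(self) -> int:
        return max(a.end_bp_b for a in self.anchors)

    @property
    def ord_span_a(self) -> tuple[int, int]:
        return (min(a.ord_a for a in self.anchors), max(a.ord_a for a in self.anchors))

    @property
    def ord_span_b(self) -> tuple[int, int]:
        return (min(a.ord_b for a in self.anchors), max(a.ord_b for a in self.anchors))


@dataclass
class Background:
    """Per-chromosome-pair null model inputs for block significance."""

    n_pairs: int
    n_genes_a: int
    n_genes_b: int
    anchors: list[Anchor] = field(default_factory=list)


class PositionIndex:
    """gene_id -> (chrom_id, ordinal, start_bp, end_bp) over one or more
    genomes, plus per-chromosome gene counts."""

    def __init__(self) -> None:
        self._pos: dict[str, tuple[str, int, int, int]] = {}
        self.chrom_sizes: dict[str, int] = {}
        self.genome_of_chrom: dict[str, str] = {}

    @classmethod
    def from_genomes(cls, *genomes: Genome) -> "PositionIndex":
        idx = cls()
        for g in genomes:
            for chrom in g.chromosomes:
                idx.chrom_sizes[chrom.chrom_id] = len(chrom)
                idx.genome_of_chrom[chrom.chrom_id] = g.genome_id
                for loc in chrom.loci:
                    idx._pos[loc.gene_id] = (
                        chrom.chrom_id, loc.index, loc.start_bp, loc.end_bp
                    )
        return idx

    def __getitem__(self, gene_id: str) -> tuple[str, int, int, int]:
        try:
            return self._pos[gene_id]
        except KeyError as exc:
            raise KeyError(f"gene {gene_id!r} has no position") from exc

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._pos


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def _gap_penalty(a: Anchor, b: Anchor, params: ChainingParams) -> float:
    da = abs(b.bp_a - a.bp_a)
    db = abs(b.bp_b - a.bp_b)
    dist = max(da, db) if params.gap_distance_mode == "per_chromosome_max" else da + db
    return params.gap_penalty_per_10kb * dist / 10_000.0


def _best_chain(anchors: Sequence[Anchor], params: ChainingParams,
                orientation: str) -> tuple[float, list[int]]:
    """Highest-scoring chain among ``anchors`` for one orientation.

    Returns (score, anchor indices into ``anchors`` in chain order); an empty
    list when there are no anchors.  Ties break toward the earlier-sorted
    chain end, making extraction deterministic.
    """
    if not anchors:
        return 0.0, []
    sign = 1 if orientation == "forward" else -1
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].ord_a, sign * anchors[i].ord_b, anchors[i].gene_b),
    )
    dp = [0.0] * len(order)
    parent = [-1] * len(order)
    for pi, i in enumerate(order):
        ai = anchors[i]
        best = 0.0
        best_j = -1
        for pj in range(pi - 1, -1, -1):
            aj = anchors[order[pj]]
            if ai.ord_a - aj.ord_a - 1 > params.mg:
                break  # sorted by ord_a: everything further is out of range
            if aj.ord_a >= ai.ord_a:
                continue
            if sign * (ai.ord_b - aj.ord_b) <= 0:
                continue
            if abs(ai.ord_b - aj.ord_b) - 1 > params.mg:
                continue
            cand = dp[pj] - _gap_penalty(aj, ai, params)
            if cand > best:
                best = cand
                best_j = pj
        dp[pi] = ai.weight + best
        parent[pi] = best_j
    end = max(range(len(order)), key=lambda pi: (dp[pi], -pi))
    score = dp[end]
    chain_positions = []
    while end >= 0:
        chain_positions.append(order[end])
        end = parent[end]
    chain_positions.reverse()
    return score, chain_positions


def _pair_anchors(pairs: Iterable[HomologPair], positions: PositionIndex,
                  params: ChainingParams,
                  genome_a_chroms: set[str] | None) -> dict[tuple[str, str], list[Anchor]]:
    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for p in pairs:
        ca, orda, bpa, enda = positions[p.gene_a]
        cb, ordb, bpb, endb = positions[p.gene_b]
        if ca == cb:
            continue  # within-chromosome (tandem) pairs are not chained
        ga, gb = p.gene_a, p.gene_b
        if genome_a_chroms is not None:
            if cb in genome_a_chroms and ca not in genome_a_chroms:
                ca, orda, bpa, enda, cb, ordb, bpb, endb, ga, gb = (
                    cb, ordb, bpb, endb, ca, orda, bpa, enda, gb, ga
                )
        elif (cb, ca) < (ca, cb):
            ca, orda, bpa, enda, cb, ordb, bpb, endb, ga, gb = (
                cb, ordb, bpb, endb, ca, orda, bpa, enda, gb, ga
            )
        grouped.setdefault((ca, cb), []).append(Anchor(
            gene_a=ga, gene_b=gb, ord_a=orda, ord_b=ordb,
            bp_a=bpa, bp_b=bpb, end_bp_a=enda, end_bp_b=endb,
            weight=params.anchor_weight(p.log10_evalue),
        ))
    return grouped


def chain_blocks(
    pairs: Iterable[HomologPair],
    positions: PositionIndex,
    params: ChainingParams | None = None,
    *,
    genome_a_chroms: set[str] | None = None,
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks.

    Per chromosome pair, the best-scoring chain over both orientations is
    extracted, its anchors removed, and the search repeated until no chain
    reaches ``min_anchors``; each surviving chain is kept if its significance
    E-value passes ``block_evalue_threshold``.  Each anchor therefore appears
    in at most one reported block.  When ``genome_a_chroms`` is given, blocks
    are oriented with those chromosomes on the ``chrom_a`` side; otherwise
    sides are ordered lexicographically.
    """
    params = params or ChainingParams()
    grouped = _pair_anchors(pairs, positions, params, genome_a_chroms)

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(grouped):
        pool = grouped[(ca, cb)]
        background = Background(
            n_pairs=len(pool),
            n_genes_a=positions.chrom_sizes[ca],
            n_genes_b=positions.chrom_sizes[cb],
            anchors=list(pool),
        )
        while pool:
            sf, chain_f = _best_chain(pool, params, "forward")
            sr, chain_r = _best_chain(pool, params, "reverse")
            # prefer the higher score; ties: more anchors, then forward
            if (sr, len(chain_r)) > (sf, len(chain_f)):
                score, chain, orientation = sr, chain_r, "reverse"
            else:
                score, chain, orientation = sf, chain_f, "forward"
            if len(chain) < params.min_anchors:
                break
            chain_anchors = [pool[i] for i in chain]
            block = CollinearBlock(
                chrom_a=ca, chrom_b=cb, anchors=chain_anchors,
                orientation=orientation, score=score,
            )
            block.evalue = block_significance(block, background, params)
            taken = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in taken]
            if block.evalue <= params.block_evalue_threshold:
                blocks.append(block)

    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.start_a_bp, b.orientation))
    return blocks


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _analytic_evalue(m: int, span_a: int, span_b: int,
                     background: Background) -> float:
    """Expected count of chains as compact as the observed block, under
    uniform random placement of the N background pairs.

    A monotone chain of k anchors confined to an ``l1 x l2`` gene window can
    start at ~na*nb positions and distribute its k-1 positive ordinal
    increments in C(l1-2, k-2) * C(l2-2, k-2) ways, so the expected number
    of such chains among N uniform pairs is

        C(N, k) * k! * na * nb * C(l1-2, k-2) * C(l2-2, k-2) / (na*nb)^k.

    Tightness is what carries the signal: a gap-free k-run has a single
    increment configuration, while a diffuse chance chain pays the full
    combinatorial factor.  The reported E-value is the minimum over
    sub-sizes k <= m within the same window (a block containing strong
    k-anchor evidence is at least that significant), which also makes it
    monotone non-increasing in anchor count at fixed background and spans.
    """
    n, na, nb = background.n_pairs, background.n_genes_a, background.n_genes_b
    if m <= 0 or n <= 0:
        return 1.0
    l1 = max(span_a, m)
    l2 = max(span_b, m)
    log_na_nb = math.log(na) + math.log(nb)
    best = math.log(max(n, 1))  # k = 1: any single pair is expected ~N times
    for k in range(2, min(m, n) + 1):
        log_e = (
            _log_choose(n, k) + math.lgamma(k + 1) + log_na_nb
            + _log_choose(max(l1 - 2, 0), k - 2)
            + _log_choose(max(l2 - 2, 0), k - 2)
            - k * log_na_nb
        )
        best = min(best, log_e)
    return float(math.exp(min(best, 700.0)))


def _permutation_evalue(block: CollinearBlock, background: Background,
                        params: ChainingParams) -> float:
    """Permutation null: shuffle the subject chromosome's gene labels (each
    anchored subject gene is relocated uniformly over all its chromosome's
    gene positions), re-run the chainer, and fit a right Gumbel tail to the
    max chain scores; the E-value is the fitted exceedance probability of
    the observed score (per chromosome pair tested)."""
    from scipy import stats

    rng = np.random.default_rng(params.permutation_seed)
    anchors = background.anchors
    if not anchors:
        return 1.0
    nb = background.n_genes_b
    ords_b = np.array([a.ord_b for a in anchors])
    # bp per ordinal on the subject side, estimated from the anchors
    spacing = max(
        (max(a.bp_b for a in anchors) - min(a.bp_b for a in anchors))
        / max(ords_b.max() - ords_b.min(), 1),
        1.0,
    )
    maxima = np.empty(params.permutation_reps)
    for rep in range(params.permutation_reps):
        relabel = rng.permutation(nb)
        shuffled = [
            Anchor(
                gene_a=a.gene_a, gene_b=a.gene_b, ord_a=a.ord_a,
                ord_b=int(relabel[a.ord_b]), bp_a=a.bp_a,
                bp_b=int(1 + relabel[a.ord_b] * spacing), end_bp_a=a.end_bp_a,
                end_bp_b=int(1 + relabel[a.ord_b] * spacing), weight=a.weight,
            )
            for a in anchors
        ]
        sf, _ = _best_chain(shuffled, params, "forward")
        sr, _ = _best_chain(shuffled, params, "reverse")
        maxima[rep] = max(sf, sr)
    if np.allclose(maxima, maxima[0]):
        # degenerate null (e.g. single anchor): fall back to the empirical tail
        exceed = int(np.sum(maxima >= block.score))
        return (exceed + 1) / (params.permutation_reps + 1)
    loc, scale = stats.gumbel_r.fit(maxima)
    return float(stats.gumbel_r.sf(block.score, loc=loc, scale=scale))


def block_significance(block: CollinearBlock, background: Background,
                       params: ChainingParams | None = None,
                       method: str | None = None) -> float:
    """E-value of a collinear block against its chromosome-pair background.

    A block with no anchors has E-value 1 by convention (no evidence).  The
    analytic method is a closed-form expected-count bound, monotone
    non-increasing in anchor count at fixed background; the permutation
    method shuffles the background and fits a Gumbel tail (the slower,
    assumption-free oracle).
    """
    params = params or ChainingParams()
    method = method or params.significance_method
    if block.n_anchors == 0:
        return 1.0
    if background.n_genes_a <= 0 or background.n_genes_b <= 0:
        raise ValueError("background chromosome gene counts must be positive")
    if method == "analytic":
        sa = block.ord_span_a
        sb = block.ord_span_b
        return _analytic_evalue(
            block.n_anchors, sa[1] - sa[0] + 1, sb[1] - sb[0] + 1, background
        )
    if method == "permutation":
        return _permutation_evalue(block, background, params)
    raise ValueError(f"unknown significance method {method!r}")


# ---------------------------------------------------------------------------
# primary / secondary classification
# ---------------------------------------------------------------------------

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_homology_layer(
    blocks: Sequence[CollinearBlock],
    *,
    self_comparison: bool = False,
    overlap_frac: float = 0.5,
) -> list[CollinearBlock]:
    """Label blocks primary (orthologous) or secondary (paralogous).

    Within each ``chrom_a`` region the best-scoring block is primary; any
    lower-scoring block whose footprint overlaps already-primary territory by
    at least ``overlap_frac`` of its own ordinal span is secondary.  Blocks
    from a within-genome self-comparison are always secondary (paralogy from
    the ancestral polyploidy).  Ties break by anchor count, then lower
    subject chromosome id, then leftmost start — deterministic.
    """
    ranked = sorted(
        blocks,
        key=lambda b: (-b.score, -b.n_anchors, b.chrom_b, b.start_a_bp, b.orientation),
    )
    claimed: dict[str, list[tuple[int, int]]] = {}
    for b in ranked:
        if self_comparison:
            b.homology_class = "secondary"
            continue
        span = b.ord_span_a
        span_len = span[1] - span[0] + 1
        covered = sum(_overlap(span, c) for c in claimed.get(b.chrom_a, []))
        if covered >= overlap_frac * span_len:
            b.homology_class = "secondary"
        else:
            b.homology_class = "primary"
            claimed.setdefault(b.chrom_a, []).append(span)
    return list(blocks)
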