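"""Filtering raw similarity hits into the homologous-pair set.

Per query, only the best ``top_k`` non-self hits at or below the E-value
threshold are kept (the classical best-five-at-1e-5 protocol); pairs are then
stored canonically (lexicographic) and deduplicated, and pairs touching
families with too many members on a single chromosome are removed, since
large tandem clusters confound collinearity detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import SimilarityHit

__all__ = [
    "HomologPair",
    "filter_hits",
    "remove_large_families",
    "families_from_pairs",
    "pairs_to_table",
    "pairs_from_table",
]

DEFAULT_EVALUE_THRESHOLD = 1e-5
DEFAULT_TOP_K = 5
DEFAULT_MAX_FAMILY_SIZE = 30


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair, stored canonically."""

    gene_a: str
    gene_b: str
    log10_evalue: float
    is_self: bool = False

    @staticmethod
    def make(g1: str, g2: str, log10_evalue: float) -> "HomologPair":
        a, b = sorted((g1, g2))
        return HomologPair(a, b, log10_evalue, is_self=(g1 == g2))


def filter_hits(
    hits: Iterable[SimilarityHit],
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
    *,
    subject_genome_of: Mapping[str, str] | None = None,
    per_subject_genome: bool = True,
) -> list[HomologPair]:
    """Retain, per query, at most ``top_k`` non-self hits with
    E <= ``evalue_threshold``; dedup canonically keeping the best E-value.

    When ``subject_genome_of`` is given and ``per_subject_genome`` is true,
    the top-k budget applies per query against each subject genome (so a
    strong self-genome paralog cannot crowd out cross-genome orthologs);
    otherwise it applies per query overall.
    """
    log_thresh = math.log10(evalue_threshold)
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue  # self-hits are never homolog pairs
        if h.log10_evalue > log_thresh:
            continue
        by_query.setdefault(h.query_id, []).append(h)

    best: dict[tuple[str, str], float] = {}
    for query in sorted(by_query):
        q_hits = sorted(by_query[query], key=lambda h: (h.log10_evalue, h.subject_id))
        if subject_genome_of is not None and per_subject_genome:
            taken: dict[str, int] = {}
            kept = []
            for h in q_hits:
                gkey = subject_genome_of.get(h.subject_id, "?")
                if taken.get(gkey, 0) < top_k:
                    kept.append(h)
                    taken[gkey] = taken.get(gkey, 0) + 1
        else:
            kept = q_hits[:top_k]
        for h in kept:
            key = tuple(sorted((h.query_id, h.subject_id)))
            if key not in best or h.log10_evalue < best[key]:
                best[key] = h.log10_evalue

    return [HomologPair(a, b, e) for (a, b), e in sorted(best.items())]


def remove_large_families(
    pairs: Sequence[HomologPair],
    families: Mapping[str, str],
    chrom_of: Mapping[str, str],
    max_family_size: int = DEFAULT_MAX_FAMILY_SIZE,
) -> list[HomologPair]:
    """Drop every pair touching a family with >= ``max_family_size`` members
    on any single chromosome.

    ``families`` maps each gene to its family over the full gene roster (not
    just the genes in ``pairs``) and ``chrom_of`` maps genes to chromosomes;
    a gene missing from either raises a mapping error.
    """
    counts: dict[tuple[str, str], int] = {}
    for gene, fam in families.items():
        try:
            chrom = chrom_of[gene]
        except KeyError as exc:
            raise KeyError(f"gene {gene!r} missing from chromosome map") from exc
        key = (fam, chrom)
        counts[key] = counts.get(key, 0) + 1

    oversized = {fam for (fam, _), n in counts.items() if n >= max_family_size}

    out = []
    for p in pairs:
        try:
            fa, fb = families[p.gene_a], families[p.gene_b]
        except KeyError as exc:
            raise KeyError(f"gene missing from family map: {exc}") from exc
        if fa in oversized or fb in oversized:
            continue
        out.append(p)
    return out


def families_from_pairs(pairs: Iterable[HomologPair]) -> dict[str, str]:
    """Single-linkage gene families (connected components over the retained
    pairs), used when no family table accompanies the input.  Each component
    is named after its lexicographically smallest member."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for p in pairs:
        ra, rb = find(p.gene_a), find(p.gene_b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo
    return {gene: find(gene) for gene in parent}


def pairs_to_table(pairs: Sequence[HomologPair], path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [(p.gene_a, p.gene_b, p.log10_evalue) for p in pairs],
        columns=["gene_a", "gene_b", "log10_evalue"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def pairs_from_table(path) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        HomologPair.make(r.gene_a, r.gene_b, float(r.log10_evalue))
        for r in df.itertuples(index=False)
    ]
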