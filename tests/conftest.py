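"""Shared fixtures: hand-built genomes and the replayed lineage analyses."""

from __future__ import annotations

import pytest

from karyoevo import io as kio
from karyoevo.model import Chromosome, GeneLocus, Genome, relayout
from karyoevo.pipeline import analyze, replay_fixture


def make_chromosome(
    chrom_id: str,
    labels,
    centromere_index: int | None = None,
    gene_len: int = 2_000,
    gap: int = 10_000,
) -> Chromosome:
    """Chromosome from a list of origin labels (or a gene count)."""
    if isinstance(labels, int):
        labels = [chrom_id] * labels
    loci = [
        GeneLocus(
            gene_id=f"{chrom_id}g{i:04d}", family_id=f"{chrom_id}g{i:04d}",
            chrom_id=chrom_id, index=i, start_bp=0, end_bp=gene_len - 1,
            strand="+", origin_label=lab,
        )
        for i, lab in enumerate(labels)
    ]
    chrom = Chromosome(
        chrom_id=chrom_id, loci=loci,
        centromere_index=len(loci) // 2 if centromere_index is None else centromere_index,
    )
    relayout(chrom, gap)
    return chrom


def make_genome(spec: dict, genome_id: str = "g", homoeolog_pairs=()) -> Genome:
    """Genome from {chrom_id: gene count | label list | (labels, centromere)}."""
    chroms = []
    for cid, val in spec.items():
        if isinstance(val, tuple):
            chroms.append(make_chromosome(cid, val[0], centromere_index=val[1]))
        else:
            chroms.append(make_chromosome(cid, val))
    return Genome(genome_id=genome_id, chromosomes=chroms,
                  homoeolog_pairs={frozenset(p) for p in homoeolog_pairs})


@pytest.fixture(scope="session")
def homoeolog_pair_map():
    return kio.load_homoeolog_pairs()


@pytest.fixture(scope="session")
def triticeae_analysis(homoeolog_pair_map):
    reference, derived = replay_fixture("triticeae")
    return analyze(derived, reference, pair_map=homoeolog_pair_map)


@pytest.fixture(scope="session")
def brachypodium_analysis(homoeolog_pair_map):
    reference, derived = replay_fixture("brachypodium")
    return analyze(derived, reference, pair_map=homoeolog_pair_map)
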