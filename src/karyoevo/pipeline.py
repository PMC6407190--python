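"""End-to-end orchestration: simulate/replay -> homology -> collinearity ->
painting -> inference -> statistics.

This module wires the stages together for the two standard workflows:

* replaying the bundled lineage event scripts (the 12 -> 7 Triticeae and
  12 -> 5 Brachypodium trajectories) against a fresh 12-chromosome
  reference genome and re-inferring the events from the paints, and
* benchmark runs on random trajectories, where the inferred event multiset
  is scored against the simulator's retained ground truth.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as kio
from .collinearity import ChainingParams, CollinearBlock, PositionIndex, chain_blocks, classify_homology_layer
from .homology import filter_hits
from .inference import Trajectory, assemble_trajectory
from .model import EventType, Genome, replay_script
from .painting import Karyogram, build_karyogram, project_to_ancestral
from .simulate import (
    SimulationConfig,
    apply_wgd,
    emit_similarity,
    fractionate,
    make_proto_genome,
    random_trajectory,
)
from .stats import FusionNullParams, homoeologous_fusion_pvalue, monte_carlo_fusion_null

__all__ = [
    "AnalysisResult",
    "make_reference_genome",
    "replay_fixture",
    "analyze",
    "truth_event_multiset",
    "inferred_event_multiset",
    "recovery_run",
    "run_full",
]

DEFAULT_REFERENCE_CHROMS = 12
DEFAULT_GENES_PER_CHROM = 100


def tag_gene_ids(genome: Genome, tag: str, *, tag_chroms: bool = False) -> Genome:
    """Copy of ``genome`` with every gene id prefixed ``tag|``.

    A rearranged genome and the reference it derives from carry the same
    gene and (for untouched chromosomes) chromosome ids; tagging keeps ids
    globally unique across the two genomes (as real accessions are), so
    identical ids are never mistaken for self-hits, position indices stay
    collision-free, and block orientation is unambiguous.  Families and
    origin labels are untouched.
    """
    g = genome.copy()
    for chrom in g.chromosomes:
        if tag_chroms:
            chrom.chrom_id = f"{tag}|{chrom.chrom_id}"
        for loc in chrom.loci:
            loc.gene_id = f"{tag}|{loc.gene_id}"
            if tag_chroms:
                loc.chrom_id = chrom.chrom_id
    if tag_chroms:
        g.homoeolog_pairs = {
            frozenset(f"{tag}|{c}" for c in pair) for pair in g.homoeolog_pairs
        }
    return g


@dataclass
class AnalysisResult:
    reference: Genome
    extant: Genome
    blocks: list[CollinearBlock]
    karyogram: Karyogram
    trajectory: Trajectory
    karyogram_ancestral: Karyogram | None = None


def make_reference_genome(
    genes_per_chrom: int = DEFAULT_GENES_PER_CHROM,
    n_chrom: int = DEFAULT_REFERENCE_CHROMS,
    prefix: str = "Os",
    genome_id: str = "reference",
    with_homoeolog_pairs: bool = True,
) -> Genome:
    """A rice-like reference karyotype: ``n_chrom`` single-origin
    chromosomes carrying the shipped homoeolog-pair map."""
    cfg = SimulationConfig(n_proto=n_chrom, genes_per_chrom=genes_per_chrom)
    g = make_proto_genome(cfg, prefix=prefix, genome_id=genome_id)
    if with_homoeolog_pairs and prefix == "Os" and n_chrom == DEFAULT_REFERENCE_CHROMS:
        g.homoeolog_pairs = kio.load_homoeolog_pairs()
    return g


def replay_fixture(
    name: str,
    genes_per_chrom: int = DEFAULT_GENES_PER_CHROM,
) -> tuple[Genome, Genome]:
    """Replay a bundled lineage script; returns (reference, derived)."""
    script = kio.load_fixture_script(name)
    reference = make_reference_genome(genes_per_chrom)
    derived = tag_gene_ids(replay_script(reference, script),
                           name.replace("_script.json", ""))
    derived.genome_id = name.replace("_script.json", "")
    return reference, derived


def analyze(
    extant: Genome,
    reference: Genome,
    *,
    sim_config: SimulationConfig | None = None,
    chain_params: ChainingParams | None = None,
    pair_map: set[frozenset[str]] | None = None,
    min_segment_anchors: int = 5,
    ref_to_proto: dict[str, str] | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """The full inference pipeline on an extant/reference genome pair.

    Similarity is synthesized per homology layer, filtered to homolog pairs,
    chained into collinear blocks, classified primary/secondary, painted,
    and parsed into a fusion trajectory.  ``pair_map`` (label-level
    homoeolog pairs) defaults to the extant genome's own pair set.
    """
    sim_config = sim_config or SimulationConfig()
    chain_params = chain_params or ChainingParams()
    shared = ({c.chrom_id for c in extant.chromosomes}
              & {c.chrom_id for c in reference.chromosomes})
    if shared:
        raise ValueError(
            f"extant and reference genomes share chromosome ids {sorted(shared)}; "
            "tag one side (see tag_gene_ids) so block orientation is unambiguous"
        )
    if pair_map is None:
        pair_map = extant.homoeolog_pairs or reference.homoeolog_pairs

    hits = emit_similarity(extant, reference, sim_config, seed)
    pairs = filter_hits(hits)
    positions = PositionIndex.from_genomes(extant, reference)
    blocks = chain_blocks(
        pairs, positions, chain_params,
        genome_a_chroms={c.chrom_id for c in extant.chromosomes},
    )
    classify_homology_layer(blocks)
    # painting sees every block: anchor-level weight priority keeps the
    # orthologous (primary) signal on top wherever layers overlap
    karyo = build_karyogram(blocks, extant, min_segment_anchors)
    trajectory = assemble_trajectory(karyo, pair_map)
    karyo7 = None
    if ref_to_proto is not None:
        karyo7 = project_to_ancestral(karyo, ref_to_proto)
    return AnalysisResult(
        reference=reference, extant=extant, blocks=blocks,
        karyogram=karyo, trajectory=trajectory, karyogram_ancestral=karyo7,
    )


# ---------------------------------------------------------------------------
# ground-truth benchmarking
# ---------------------------------------------------------------------------

def truth_event_multiset(genome: Genome) -> Counter:
    """Canonical multiset of the genome's logged fusion events:
    (type, invading origin, invaded origin) for NCF — direction matters —
    and unordered label pairs for EEJ and reciprocal translocation."""
    out: Counter = Counter()
    for e in genome.event_log:
        if e.event_type == EventType.NCF:
            out[("NCF", e.donor_origin, e.recipient_origin)] += 1
        elif e.event_type == EventType.EEJ:
            out[("EEJ",) + tuple(sorted((e.donor_origin or "", e.recipient_origin or "")))] += 1
        elif e.event_type == EventType.RECIPROCAL_TRANSLOCATION:
            out[("RECIPROCAL_TRANSLOCATION",) + tuple(
                sorted((e.donor_origin or "", e.recipient_origin or "")))] += 1
    return out


def inferred_event_multiset(trajectory: Trajectory) -> Counter:
    out: Counter = Counter()
    for e in trajectory.events:
        if e.event_type in ("NONE", "AMBIGUOUS"):
            continue
        out[e.key()] += 1
    return out


def recovery_run(
    seed: int,
    *,
    retention_rate: float = 1.0,
    genes_per_chrom: int = DEFAULT_GENES_PER_CHROM,
    n_events: int | None = None,
    event_mix: dict[str, float] | None = None,
) -> tuple[Counter, Counter]:
    """One benchmark run: simulate a post-WGD genome, rearrange it, and
    re-infer the events through the full pipeline.

    Returns (truth multiset, inferred multiset).  The reference snapshot is
    the post-WGD genome before fractionation, so lowering ``retention_rate``
    thins the ortholog anchors the pipeline has to chain.
    """
    rng = np.random.default_rng(seed)
    if n_events is None:
        n_events = int(rng.integers(2, 7))
    cfg = SimulationConfig(
        genes_per_chrom=genes_per_chrom,
        retention_rate=retention_rate,
        event_mix=event_mix or {EventType.NCF: 0.8, EventType.EEJ: 0.2},
        n_events=n_events,
        noise_rate=0.0,
    )
    proto = make_proto_genome(cfg, genome_id="proto")
    post = apply_wgd(proto)
    reference = post.copy()
    reference.genome_id = "reference"

    derived = post.copy()
    derived.genome_id = "derived"
    if retention_rate < 1.0:
        derived = fractionate(derived, retention_rate, int(rng.integers(2**31)))
    derived = random_trajectory(derived, cfg, seed=int(rng.integers(2**31)))
    derived = tag_gene_ids(derived, "d", tag_chroms=True)

    truth = truth_event_multiset(derived)
    result = analyze(derived, reference, sim_config=cfg,
                     pair_map=post.homoeolog_pairs,
                     seed=int(rng.integers(2**31)))
    return truth, inferred_event_multiset(result.trajectory)


# ---------------------------------------------------------------------------
# full run with artifacts on disk
# ---------------------------------------------------------------------------

def run_full(
    outdir,
    *,
    script: str | dict | None = "brachypodium",
    genes_per_chrom: int = DEFAULT_GENES_PER_CHROM,
    seed: int = 0,
    chain_params: ChainingParams | None = None,
    render: bool = True,
) -> dict:
    """Replay a lineage script (bundled name, path, or dict), run the full
    inference pipeline, write the intermediate artifacts, and return (and
    write) a JSON summary with event counts and the fusion-null statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(script, str):
        p = Path(script)
        if p.exists():
            with open(p) as fh:
                script_obj = json.load(fh)
            name = p.stem
        else:
            script_obj = kio.load_fixture_script(script)
            name = script
    elif isinstance(script, dict):
        script_obj, name = script, "custom"
    else:
        script_obj, name = {"events": []}, "unrearranged"

    reference = make_reference_genome(genes_per_chrom)
    derived = tag_gene_ids(replay_script(reference, script_obj), name)
    derived.genome_id = name
    # untouched chromosomes keep the reference's ids; disambiguate them
    ref_ids = {c.chrom_id for c in reference.chromosomes}
    for chrom in derived.chromosomes:
        if chrom.chrom_id in ref_ids:
            chrom.chrom_id = f"{name}.{chrom.chrom_id}"
            for loc in chrom.loci:
                loc.chrom_id = chrom.chrom_id

    pair_map = kio.load_homoeolog_pairs()
    ref_to_proto = kio.load_os_to_proto()
    result = analyze(derived, reference, chain_params=chain_params,
                     pair_map=pair_map, ref_to_proto=ref_to_proto, seed=seed)
    traj = result.trajectory

    # artifacts
    kio.write_gff3(derived, outdir / f"{name}.gff3")
    kio.write_family_table(derived, outdir / f"{name}.families.tsv")
    derived.to_json(outdir / f"{name}.genome.json")
    kio.write_block_table(result.blocks, outdir / f"{name}.blocks.tsv",
                          outdir / f"{name}.anchors.tsv")
    kio.write_karyogram_bed(result.karyogram, outdir / f"{name}.paint.bed")
    kio.karyogram_to_json(result.karyogram, outdir / f"{name}.paint.json")
    with open(outdir / f"{name}.trajectory.json", "w") as fh:
        json.dump(traj.to_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / f"{name}.report.txt", "w") as fh:
        fh.write(traj.report() + "\n")

    n_ncf = traj.count("NCF")
    n_hom_ncf = sum(1 for e in traj.events
                    if e.event_type == "NCF" and e.is_homoeologous)
    # the null lives on the ancestral post-duplication karyotype (7 pairs,
    # 14 chromosomes): merged chromosomes count as independent ancestral
    # segments, so more fusions can occur than the extant pair map lists
    n_ancestral_pairs = 7
    params = FusionNullParams(
        n_pairs=n_ancestral_pairs,
        k_homoeologous=min(n_hom_ncf, n_ancestral_pairs),
        n_fusions_total=min(max(n_ncf, n_hom_ncf), n_ancestral_pairs),
        reps=20_000, seed=seed,
    ) if n_ncf else None
    stats_summary = None
    if params is not None:
        mc = monte_carlo_fusion_null(params)
        stats_summary = {
            "n_pairs": params.n_pairs,
            "k_homoeologous": params.k_homoeologous,
            "n_fusions_total": params.n_fusions_total,
            "closed_form": homoeologous_fusion_pvalue(params),
            "mc_first_k": mc.p_first_k,
            "mc_first_k_se": mc.se_first_k,
            "mc_at_least_k": mc.p_at_least_k,
            "mc_at_least_k_se": mc.se_at_least_k,
        }

    if render:
        from .viz import ColorScheme, render_karyogram
        scheme = ColorScheme.default()
        if result.karyogram_ancestral is not None:
            render_karyogram(result.karyogram_ancestral, result.karyogram,
                             scheme, outdir / f"{name}.karyogram.svg",
                             title=name)

    summary = {
        "name": name,
        "seed": seed,
        "n_chromosomes": derived.n_chromosomes,
        "events": {
            "NCF": n_ncf,
            "EEJ": traj.count("EEJ"),
            "RECIPROCAL_TRANSLOCATION": traj.count("RECIPROCAL_TRANSLOCATION"),
            "NCF_homoeologous": n_hom_ncf,
        },
        "n_satellites_implied": traj.n_satellites_implied,
        "chrom_count_initial": traj.chrom_count_initial,
        "chrom_count_final": traj.chrom_count_final,
        "fusion_null": stats_summary,
    }
    with open(outdir / f"{name}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
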