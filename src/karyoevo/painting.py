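"""Ancestral-origin painting of extant chromosomes.

Primary collinear blocks against a reference genome are projected onto each
extant chromosome as an ordered sequence of paint segments, one reference
label per segment.  Painting is anchor-resolved: every anchor is assigned to
its best overlapping block, anchors are scanned in chromosome order, and
maximal same-label runs become segments; adjacent same-label segments merge
and sub-threshold fragments are absorbed into identical flanks or dropped.
A karyogram can be expressed in the extant-vs-reference scheme (12 reference
chromosomes) or projected onto the 7 proto-chromosome alphabet of the
ancestral karyotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .collinearity import CollinearBlock
from .model import Genome

__all__ = [
    "PaintSegment",
    "Karyogram",
    "paint_chromosome",
    "build_karyogram",
    "truth_karyogram",
    "project_to_ancestral",
]

DEFAULT_MIN_SEGMENT_ANCHORS = 5


@dataclass
class PaintSegment:
    """Maximal run of one extant chromosome assigned to one reference label."""

    chrom_id: str
    start_bp: int
    end_bp: int
    ref_label: str
    n_anchors: int
    orientation: str = "forward"


@dataclass
class Karyogram:
    genome_id: str
    paints: dict[str, list[PaintSegment]] = field(default_factory=dict)
    scheme: str = "reference12"

    def labels(self, chrom_id: str) -> list[str]:
        """The reduced label sequence of one chromosome's paint."""
        labels = [s.ref_label for s in self.paints.get(chrom_id, [])]
        reduced: list[str] = []
        for lab in labels:
            if not reduced or reduced[-1] != lab:
                reduced.append(lab)
        return reduced


def _block_sort_key(b: CollinearBlock):
    return (-b.score, -b.n_anchors, b.chrom_b, b.start_a_bp, b.orientation)


def paint_chromosome(
    blocks: Sequence[CollinearBlock],
    chrom: str,
    min_segment_anchors: int = DEFAULT_MIN_SEGMENT_ANCHORS,
) -> list[PaintSegment]:
    """Ordered ancestral-origin paint of one extant chromosome.

    ``blocks`` carry the extant chromosome on the ``chrom_a`` side and the
    reference on ``chrom_b``; the reference chromosome id becomes the
    segment label.  Each anchor position goes to the strongest local
    evidence: the highest per-anchor similarity weight, ties resolved by
    block score, then anchor count, then lexicographic reference label
    (so orthologous anchors outrank paralogous ones wherever both cover a
    position, which is what makes the paint primary).  Runs shorter than
    ``min_segment_anchors`` are absorbed into identical flanking labels or
    dropped.
    """
    mine = [b for b in blocks if b.chrom_a == chrom]
    if not mine:
        return []

    # anchor-level assignment: strongest local similarity wins the position
    assignment: dict[int, tuple[float, int, str, str, int, int]] = {}
    for rank, b in enumerate(sorted(mine, key=_block_sort_key)):
        for a in b.anchors:
            cur = assignment.get(a.ord_a)
            if cur is None or (-a.weight, rank) < (cur[0], cur[1]):
                assignment[a.ord_a] = (
                    -a.weight, rank, b.chrom_b, b.orientation, a.bp_a, a.end_bp_a
                )

    runs: list[PaintSegment] = []
    for ord_a in sorted(assignment):
        _, _, label, orientation, bp, end_bp = assignment[ord_a]
        if runs and runs[-1].ref_label == label:
            runs[-1].end_bp = max(runs[-1].end_bp, end_bp)
            runs[-1].n_anchors += 1
        else:
            runs.append(PaintSegment(
                chrom_id=chrom, start_bp=bp, end_bp=end_bp,
                ref_label=label, n_anchors=1, orientation=orientation,
            ))

    return _smooth(runs, min_segment_anchors)


def _merge_adjacent(segments: list[PaintSegment]) -> list[PaintSegment]:
    out: list[PaintSegment] = []
    for seg in segments:
        if out and out[-1].ref_label == seg.ref_label:
            out[-1].end_bp = max(out[-1].end_bp, seg.end_bp)
            out[-1].n_anchors += seg.n_anchors
        else:
            out.append(seg)
    return out


def _smooth(segments: list[PaintSegment], min_anchors: int) -> list[PaintSegment]:
    """Absorb or drop sub-threshold fragments until stable."""
    segments = _merge_adjacent(segments)
    changed = True
    while changed:
        changed = False
        for i, seg in enumerate(segments):
            if seg.n_anchors >= min_anchors:
                continue
            left = segments[i - 1] if i > 0 else None
            right = segments[i + 1] if i < len(segments) - 1 else None
            if left is not None and right is not None and left.ref_label == right.ref_label:
                # island flanked by one label on both sides: absorbed
                left.end_bp = right.end_bp
                left.n_anchors += seg.n_anchors + right.n_anchors
                del segments[i:i + 2]
            else:
                del segments[i]
            changed = True
            break
        segments = _merge_adjacent(segments)
    return segments


def build_karyogram(
    blocks: Sequence[CollinearBlock],
    genome: Genome,
    min_segment_anchors: int = DEFAULT_MIN_SEGMENT_ANCHORS,
    scheme: str = "reference12",
) -> Karyogram:
    """Paint every non-satellite chromosome of ``genome`` from ``blocks``."""
    karyo = Karyogram(genome_id=genome.genome_id, scheme=scheme)
    chrom_ids = {c.chrom_id for c in genome.chromosomes}
    for b in blocks:
        if b.chrom_a not in chrom_ids and b.chrom_b not in chrom_ids:
            raise KeyError(
                f"block {b.chrom_a}~{b.chrom_b} references no chromosome of "
                f"genome {genome.genome_id}"
            )
    for chrom in genome.chromosomes:
        if chrom.is_satellite:
            continue
        karyo.paints[chrom.chrom_id] = paint_chromosome(
            blocks, chrom.chrom_id, min_segment_anchors
        )
    return karyo


def truth_karyogram(genome: Genome, scheme: str = "reference12") -> Karyogram:
    """Paint from the loci's own origin labels (simulation ground truth)."""
    karyo = Karyogram(genome_id=genome.genome_id, scheme=scheme)
    for chrom in genome.chromosomes:
        if chrom.is_satellite:
            continue
        segs = []
        for label, start, stop in chrom.origin_runs():
            segs.append(PaintSegment(
                chrom_id=chrom.chrom_id,
                start_bp=chrom.loci[start].start_bp,
                end_bp=chrom.loci[stop - 1].end_bp,
                ref_label=label,
                n_anchors=stop - start,
            ))
        karyo.paints[chrom.chrom_id] = _merge_adjacent(segs)
    return karyo


def project_to_ancestral(karyogram: Karyogram,
                         ref_to_proto: Mapping[str, str]) -> Karyogram:
    """Relabel a reference-scheme karyogram into the proto-chromosome
    alphabet; adjacent segments that become same-label merge, so the
    projection never increases the segment count."""
    out = Karyogram(genome_id=karyogram.genome_id, scheme="ancestral7")
    for chrom_id, segs in karyogram.paints.items():
        projected = []
        for s in segs:
            try:
                label = ref_to_proto[s.ref_label]
            except KeyError as exc:
                raise KeyError(
                    f"no proto-chromosome mapping for label {s.ref_label!r}"
                ) from exc
            projected.append(PaintSegment(
                chrom_id=s.chrom_id, start_bp=s.start_bp, end_bp=s.end_bp,
                ref_label=label, n_anchors=s.n_anchors,
                orientation=s.orientation,
            ))
        out.paints[chrom_id] = _merge_adjacent(projected)
    return out
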