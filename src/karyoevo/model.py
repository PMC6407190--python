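"""Domain types and the telomere-centric rearrangement algebra.

Chromosome-number reduction in grasses proceeds, under the telomere-centric
model, by removal of telomere-proximal fragments followed by fusion of the
freed ends: a nested chromosome fusion (NCF) inserts the centromere-bearing
interior of a donor chromosome into the pericentromeric region of a recipient,
an end-end joining (EEJ) concatenates the major parts of two chromosomes, and
in either case the removed distal fragments form a small satellite chromosome
whose subsequent loss lowers the chromosome count.  Reciprocal translocations
exchange distal arms without producing a satellite; inversions reverse a run
of genes in place.

All operations are pure: they deep-copy the genome, apply the event, append a
:class:`FusionEvent` record to the genome's event log and return the new
genome.  Genes are atomic units; physical coordinates are recomputed after
every event by laying the loci end-to-end with their original lengths and a
fixed inter-gene gap, so downstream gap penalties remain well defined.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneLocus",
    "Chromosome",
    "Genome",
    "FusionEvent",
    "BreakpointError",
    "InvalidParticipantError",
    "ScriptError",
    "EventType",
    "INTERGENE_GAP_BP",
    "apply_ncf",
    "apply_eej",
    "apply_reciprocal_translocation",
    "apply_inversion",
    "drop_satellites",
    "replay_script",
    "pericentromeric_window",
    "telomere_window",
]

#: default spacing inserted between consecutive genes when coordinates are
#: recomputed after a rearrangement (bp)
INTERGENE_GAP_BP = 10_000


class BreakpointError(ValueError):
    """A cut ordinal or insertion point is outside its admissible range."""


class InvalidParticipantError(ValueError):
    """An event names a chromosome that cannot take part in it."""


class ScriptError(ValueError):
    """An event script failed at a given step; carries the step index."""

    def __init__(self, step: int, message: str):
        self.step = step
        super().__init__(f"script step {step}: {message}")


class EventType:
    NCF = "NCF"
    EEJ = "EEJ"
    RECIPROCAL_TRANSLOCATION = "RECIPROCAL_TRANSLOCATION"
    INVERSION = "INVERSION"
    SATELLITE_LOSS = "SATELLITE_LOSS"
    WGD = "WGD"
    FRACTIONATION = "FRACTIONATION"


@dataclass
class GeneLocus:
    """One gene on a chromosome.

    ``origin_label`` tags the ancestral/reference chromosome the gene descends
    from and is what karyotype painting recovers; ``copy`` distinguishes the
    two post-WGD copy lineages of a family (0 = progenitor, 1 = duplicate).
    """

    gene_id: str
    family_id: str
    chrom_id: str
    index: int
    start_bp: int
    end_bp: int
    strand: str = "+"
    origin_label: str = ""
    copy: int = 0

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class Chromosome:
    """An ordered list of gene loci with one (possibly inactive) centromere.

    ``centromere_index`` is a split point in ``0..n``: the centromere sits
    between loci ``centromere_index - 1`` and ``centromere_index``.  Fusions
    leave the losing centromere in place but flagged inactive; its positions
    are kept in ``inactive_centromeres`` so painting retains the information.
    """

    chrom_id: str
    loci: list[GeneLocus] = field(default_factory=list)
    centromere_index: int = 0
    is_satellite: bool = False
    active_centromere: bool = True
    inactive_centromeres: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def n_genes(self) -> int:
        return len(self.loci)

    @property
    def length_bp(self) -> int:
        return self.loci[-1].end_bp if self.loci else 0

    def origin_runs(self) -> list[tuple[str, int, int]]:
        """Maximal runs of identical ``origin_label``: (label, start, stop)."""
        runs: list[tuple[str, int, int]] = []
        for i, loc in enumerate(self.loci):
            if runs and runs[-1][0] == loc.origin_label:
                runs[-1] = (runs[-1][0], runs[-1][1], i + 1)
            else:
                runs.append((loc.origin_label, i, i + 1))
        return runs


@dataclass
class FusionEvent:
    """Record of one rearrangement.

    For NCF the donor is the 'invading' chromosome and the recipient the
    'invaded' one.  ``donor_origin`` / ``recipient_origin`` hold the ancestral
    labels at the participating breakpoints when they are well defined, which
    is what trajectory inference is benchmarked against.
    """

    event_type: str
    donor_id: str = ""
    recipient_id: str = ""
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    is_homoeologous: bool = False
    donor_origin: str | None = None
    recipient_origin: str | None = None
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["breakpoints"] = [list(bp) for bp in self.breakpoints]
        return d


@dataclass
class Genome:
    genome_id: str
    chromosomes: list[Chromosome] = field(default_factory=list)
    homoeolog_pairs: set[frozenset[str]] = field(default_factory=set)
    event_log: list[FusionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_unique_ids()

    def _check_unique_ids(self) -> None:
        ids = [c.chrom_id for c in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chromosome ids in genome {self.genome_id}")

    def get(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(f"no chromosome {chrom_id!r} in genome {self.genome_id}")

    def __contains__(self, chrom_id: str) -> bool:
        return any(c.chrom_id == chrom_id for c in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def gene_ids(self) -> list[str]:
        return [loc.gene_id for c in self.chromosomes for loc in c.loci]

    def loci(self) -> Iterable[GeneLocus]:
        for c in self.chromosomes:
            yield from c.loci

    def copy(self) -> "Genome":
        return copy.deepcopy(self)

    def is_homoeologous_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.homoeolog_pairs

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "homoeolog_pairs": sorted(sorted(p) for p in self.homoeolog_pairs),
            "chromosomes": [
                {
                    "chrom_id": c.chrom_id,
                    "centromere_index": c.centromere_index,
                    "is_satellite": c.is_satellite,
                    "active_centromere": c.active_centromere,
                    "inactive_centromeres": list(c.inactive_centromeres),
                    "loci": [asdict(l) for l in c.loci],
                }
                for c in self.chromosomes
            ],
            "event_log": [e.to_dict() for e in self.event_log],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        chroms = []
        for cd in d["chromosomes"]:
            loci = [GeneLocus(**ld) for ld in cd["loci"]]
            chroms.append(
                Chromosome(
                    chrom_id=cd["chrom_id"],
                    loci=loci,
                    centromere_index=cd["centromere_index"],
                    is_satellite=cd["is_satellite"],
                    active_centromere=cd["active_centromere"],
                    inactive_centromeres=list(cd.get("inactive_centromeres", [])),
                )
            )
        g = cls(
            genome_id=d["genome_id"],
            chromosomes=chroms,
            homoeolog_pairs={frozenset(p) for p in d.get("homoeolog_pairs", [])},
        )
        for ed in d.get("event_log", []):
            ed = dict(ed)
            ed["breakpoints"] = [tuple(bp) for bp in ed.get("breakpoints", [])]
            g.event_log.append(FusionEvent(**ed))
        return g

    @classmethod
    def from_json(cls, text_or_path) -> "Genome":
        try:
            d = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def relayout(chrom: Chromosome, gap_bp: int = INTERGENE_GAP_BP) -> None:
    """Recompute indices and physical coordinates after a rearrangement.

    Gene lengths are preserved; loci are laid end-to-end separated by
    ``gap_bp``.
    """
    pos = 1
    for i, loc in enumerate(chrom.loci):
        length = loc.length_bp
        loc.index = i
        loc.chrom_id = chrom.chrom_id
        loc.start_bp = pos
        loc.end_bp = pos + length - 1
        pos = loc.end_bp + gap_bp + 1


def pericentromeric_window(chrom: Chromosome, frac: float = 0.05) -> tuple[int, int]:
    """Admissible NCF insertion ordinals: centromere +/- ceil(frac * n)."""
    half = max(1, math.ceil(frac * len(chrom)))
    lo = max(1, chrom.centromere_index - half)
    hi = min(len(chrom) - 1, chrom.centromere_index + half)
    return lo, hi


def telomere_window(chrom: Chromosome, frac: float = 0.10) -> int:
    """Number of ordinals counted as telomere-proximal on each arm."""
    return max(1, math.ceil(frac * len(chrom)))


def _outer_origin(loci: Sequence[GeneLocus]) -> str | None:
    """Shared origin label of the two ends of a run of loci, if any."""
    if not loci:
        return None
    if loci[0].origin_label == loci[-1].origin_label:
        return loci[0].origin_label
    return None


def _flank_origin(loci: Sequence[GeneLocus], point: int) -> str | None:
    """Origin label shared by the loci flanking a split point.

    Falls back to the chromosome's outer label when the flanks disagree
    (insertion exactly at a run boundary) so that homoeology flags stay
    comparable with paint-level inference, which sees only the outer label.
    """
    left = loci[point - 1].origin_label if point > 0 else None
    right = loci[point].origin_label if point < len(loci) else None
    if left is not None and right is not None:
        if left == right:
            return left
        return _outer_origin(loci)
    return left if left is not None else right


def _shift_inactive(positions: Iterable[int], point: int, offset: int) -> list[int]:
    return [p + offset if p >= point else p for p in positions]


def _flag_homoeologous(genome: Genome, a: str, b: str,
                       label_a: str | None, label_b: str | None) -> bool:
    if genome.is_homoeologous_pair(a, b):
        return True
    if label_a and label_b and genome.is_homoeologous_pair(label_a, label_b):
        return True
    return False


# ---------------------------------------------------------------------------
# event operations
# ---------------------------------------------------------------------------

def apply_ncf(
    genome: Genome,
    donor: str,
    recipient: str,
    donor_left_cut: int,
    donor_right_cut: int,
    insertion_point: int,
    *,
    invert: bool = False,
    product_id: str | None = None,
    satellite_id: str | None = None,
    enforce_windows: bool = True,
    pericentromere_frac: float = 0.05,
    gap_bp: int = INTERGENE_GAP_BP,
) -> Genome:
    """Nested chromosome fusion: insert the donor's centromere-bearing
    interior ``[donor_left_cut, donor_right_cut)`` at ``insertion_point`` of
    the recipient; the donor's two distal fragments form one satellite.

    The recipient's centromere stays active; the donor's is flagged inactive.
    The total gene count and the chromosome count are both conserved (the
    donor disappears as a standalone chromosome, the satellite appears).
    """
    if donor == recipient:
        raise InvalidParticipantError("NCF donor and recipient must differ")
    g = genome.copy()
    d = g.get(donor)
    r = g.get(recipient)
    if d.is_satellite or r.is_satellite:
        raise InvalidParticipantError("satellite chromosomes cannot take part in an NCF")
    n_d, n_r = len(d), len(r)
    if not (0 < donor_left_cut < donor_right_cut < n_d):
        raise BreakpointError(
            f"NCF donor cuts ({donor_left_cut}, {donor_right_cut}) out of range for "
            f"{donor} with {n_d} genes"
        )
    if not (donor_left_cut <= d.centromere_index <= donor_right_cut):
        raise BreakpointError(
            f"NCF donor interior [{donor_left_cut}, {donor_right_cut}) must carry the "
            f"centromere of {donor} (at {d.centromere_index})"
        )
    if not (0 <= insertion_point <= n_r):
        raise BreakpointError(f"insertion point {insertion_point} out of range for {recipient}")
    if enforce_windows:
        lo, hi = pericentromeric_window(r, pericentromere_frac)
        if not (lo <= insertion_point <= hi):
            raise BreakpointError(
                f"insertion point {insertion_point} outside pericentromeric window "
                f"[{lo}, {hi}] of {recipient}"
            )

    donor_origin = _outer_origin(d.loci[donor_left_cut:donor_right_cut])
    recipient_origin = _flank_origin(r.loci, insertion_point)

    segment = d.loci[donor_left_cut:donor_right_cut]
    seg_inactive = [c - donor_left_cut for c in ([d.centromere_index] + d.inactive_centromeres)
                    if donor_left_cut <= c <= donor_right_cut]
    if invert:
        segment = list(reversed(segment))
        for loc in segment:
            loc.strand = "-" if loc.strand == "+" else "+"
        seg_inactive = [len(segment) - c for c in seg_inactive]
    seg_len = len(segment)

    fused_id = product_id or f"{donor}/{recipient}"
    sat_id = satellite_id or _fresh_id(g, f"{donor}.sat")

    fused = Chromosome(
        chrom_id=fused_id,
        loci=r.loci[:insertion_point] + segment + r.loci[insertion_point:],
        centromere_index=(r.centromere_index + seg_len
                          if insertion_point < r.centromere_index else r.centromere_index),
        inactive_centromeres=(
            _shift_inactive(r.inactive_centromeres, insertion_point, seg_len)
            + [insertion_point + c for c in seg_inactive]
        ),
    )
    satellite = Chromosome(
        chrom_id=sat_id,
        loci=d.loci[:donor_left_cut] + d.loci[donor_right_cut:],
        centromere_index=0,
        is_satellite=True,
        active_centromere=False,
    )
    relayout(fused, gap_bp)
    relayout(satellite, gap_bp)

    _replace(g, recipient, fused)
    _remove(g, donor)
    g.chromosomes.append(satellite)

    g.event_log.append(FusionEvent(
        event_type=EventType.NCF,
        donor_id=donor,
        recipient_id=recipient,
        breakpoints=[(donor, donor_left_cut), (donor, donor_right_cut),
                     (recipient, insertion_point)],
        products=[fused_id, sat_id],
        is_homoeologous=_flag_homoeologous(genome, donor, recipient,
                                           donor_origin, recipient_origin),
        donor_origin=donor_origin,
        recipient_origin=recipient_origin,
        details={"invert": invert},
    ))
    return g


def apply_eej(
    genome: Genome,
    chrom_a: str,
    chrom_b: str,
    cut_a: int,
    cut_b: int,
    *,
    product_id: str | None = None,
    satellite_id: str | None = None,
    enforce_windows: bool = True,
    telomere_frac: float = 0.10,
    gap_bp: int = INTERGENE_GAP_BP,
) -> Genome:
    """End-end joining: ``a[:cut_a]`` and ``b[cut_b:]`` fuse into one
    chromosome (junction at the cut ends); the distal fragments ``a[cut_a:]``
    and ``b[:cut_b]`` form one satellite.  ``a``'s centromere stays active.
    """
    if chrom_a == chrom_b:
        raise InvalidParticipantError("EEJ participants must differ")
    g = genome.copy()
    a = g.get(chrom_a)
    b = g.get(chrom_b)
    if a.is_satellite or b.is_satellite:
        raise InvalidParticipantError("satellite chromosomes cannot take part in an EEJ")
    n_a, n_b = len(a), len(b)
    if not (0 <= cut_a <= n_a and 0 <= cut_b <= n_b):
        raise BreakpointError(f"EEJ cuts ({cut_a}, {cut_b}) out of range")
    if enforce_windows:
        if n_a - cut_a > telomere_window(a, telomere_frac):
            raise BreakpointError(
                f"cut {cut_a} of {chrom_a} not telomere-proximal (right arm)")
        if cut_b > telomere_window(b, telomere_frac):
            raise BreakpointError(
                f"cut {cut_b} of {chrom_b} not telomere-proximal (left arm)")
    if not (a.centromere_index <= cut_a and cut_b <= b.centromere_index):
        raise BreakpointError("EEJ cuts must not strand a centromere on the satellite")

    label_a = a.loci[cut_a - 1].origin_label if cut_a > 0 else None
    label_b = b.loci[cut_b].origin_label if cut_b < n_b else None

    merged_id = product_id or f"{chrom_a}/{chrom_b}"
    sat_id = satellite_id or _fresh_id(g, f"{chrom_a}-{chrom_b}.sat")

    merged = Chromosome(
        chrom_id=merged_id,
        loci=a.loci[:cut_a] + b.loci[cut_b:],
        centromere_index=a.centromere_index,
        inactive_centromeres=(
            [c for c in a.inactive_centromeres if c <= cut_a]
            + [cut_a + (b.centromere_index - cut_b)]
            + [cut_a + (c - cut_b) for c in b.inactive_centromeres if c >= cut_b]
        ),
    )
    satellite = Chromosome(
        chrom_id=sat_id,
        loci=a.loci[cut_a:] + b.loci[:cut_b],
        centromere_index=0,
        is_satellite=True,
        active_centromere=False,
    )
    relayout(merged, gap_bp)
    relayout(satellite, gap_bp)

    _replace(g, chrom_a, merged)
    _remove(g, chrom_b)
    g.chromosomes.append(satellite)

    g.event_log.append(FusionEvent(
        event_type=EventType.EEJ,
        donor_id=chrom_a,
        recipient_id=chrom_b,
        breakpoints=[(chrom_a, cut_a), (chrom_b, cut_b)],
        products=[merged_id, sat_id],
        is_homoeologous=_flag_homoeologous(genome, chrom_a, chrom_b, label_a, label_b),
        donor_origin=label_a,
        recipient_origin=label_b,
    ))
    return g


def apply_reciprocal_translocation(
    genome: Genome,
    chrom_a: str,
    chrom_b: str,
    cut_a: int,
    cut_b: int,
    *,
    product_ids: tuple[str, str] | None = None,
    gap_bp: int = INTERGENE_GAP_BP,
) -> Genome:
    """Exchange the arms distal to the cuts; no satellite is produced.

    Both cuts must lie at or beyond the active centromere so each product
    retains exactly one active centromere.
    """
    if chrom_a == chrom_b:
        raise InvalidParticipantError("translocation participants must differ")
    g = genome.copy()
    a = g.get(chrom_a)
    b = g.get(chrom_b)
    if a.is_satellite or b.is_satellite:
        raise InvalidParticipantError("satellite chromosomes cannot take part in a translocation")
    if not (0 <= cut_a <= len(a) and 0 <= cut_b <= len(b)):
        raise BreakpointError(f"translocation cuts ({cut_a}, {cut_b}) out of range")
    if cut_a < a.centromere_index or cut_b < b.centromere_index:
        raise BreakpointError("translocation cuts must lie distal to the active centromeres")

    # origin labels of the exchanged tails, for comparison with paint-level
    # inference (which sees the translocation as reciprocal terminal labels)
    tail_a = a.loci[cut_a].origin_label if cut_a < len(a) else None
    tail_b = b.loci[cut_b].origin_label if cut_b < len(b) else None

    id_a, id_b = product_ids or (chrom_a, chrom_b)
    new_a = Chromosome(
        chrom_id=id_a,
        loci=a.loci[:cut_a] + b.loci[cut_b:],
        centromere_index=a.centromere_index,
        inactive_centromeres=(
            [c for c in a.inactive_centromeres if c <= cut_a]
            + [cut_a + (c - cut_b) for c in b.inactive_centromeres if c >= cut_b]
        ),
    )
    new_b = Chromosome(
        chrom_id=id_b,
        loci=b.loci[:cut_b] + a.loci[cut_a:],
        centromere_index=b.centromere_index,
        inactive_centromeres=(
            [c for c in b.inactive_centromeres if c <= cut_b]
            + [cut_b + (c - cut_a) for c in a.inactive_centromeres if c >= cut_a]
        ),
    )
    relayout(new_a, gap_bp)
    relayout(new_b, gap_bp)
    _replace(g, chrom_a, new_a)
    _replace(g, chrom_b, new_b)

    g.event_log.append(FusionEvent(
        event_type=EventType.RECIPROCAL_TRANSLOCATION,
        donor_id=chrom_a,
        recipient_id=chrom_b,
        breakpoints=[(chrom_a, cut_a), (chrom_b, cut_b)],
        products=[id_a, id_b],
        is_homoeologous=genome.is_homoeologous_pair(chrom_a, chrom_b),
        donor_origin=tail_a,
        recipient_origin=tail_b,
    ))
    return g


def apply_inversion(
    genome: Genome,
    chrom: str,
    start: int,
    stop: int,
    *,
    gap_bp: int = INTERGENE_GAP_BP,
) -> Genome:
    """Reverse the loci in ``[start, stop)`` and flip their strands."""
    g = genome.copy()
    c = g.get(chrom)
    if not (0 <= start < stop <= len(c)):
        raise BreakpointError(f"inversion range [{start}, {stop}) out of range for {chrom}")
    segment = list(reversed(c.loci[start:stop]))
    for loc in segment:
        loc.strand = "-" if loc.strand == "+" else "+"
    c.loci[start:stop] = segment
    if start < c.centromere_index < stop:
        c.centromere_index = start + stop - c.centromere_index
    c.inactive_centromeres = [
        start + stop - p if start < p < stop else p for p in c.inactive_centromeres
    ]
    relayout(c, gap_bp)
    g.event_log.append(FusionEvent(
        event_type=EventType.INVERSION,
        donor_id=chrom,
        recipient_id=chrom,
        breakpoints=[(chrom, start), (chrom, stop)],
        products=[chrom],
    ))
    return g


def drop_satellites(genome: Genome) -> Genome:
    """Remove every satellite chromosome, logging one loss event each."""
    g = genome.copy()
    sats = [c for c in g.chromosomes if c.is_satellite]
    g.chromosomes = [c for c in g.chromosomes if not c.is_satellite]
    for sat in sats:
        g.event_log.append(FusionEvent(
            event_type=EventType.SATELLITE_LOSS,
            donor_id=sat.chrom_id,
            products=[],
            details={"n_genes_lost": len(sat)},
        ))
    return g


# ---------------------------------------------------------------------------
# scripted replay
# ---------------------------------------------------------------------------

def _resolve_ordinal(value, chrom: Chromosome) -> int:
    """Resolve a script position: int ordinal, float fraction of the current
    gene count, or the keyword ``"centromere"``."""
    if value == "centromere":
        return chrom.centromere_index
    if isinstance(value, bool):
        raise ValueError("boolean is not a position")
    if isinstance(value, int):
        return value
    if isinstance(value, float):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"fractional position {value} outside [0, 1]")
        return round(value * len(chrom))
    raise ValueError(f"cannot interpret position {value!r}")


def replay_script(genome: Genome, script) -> Genome:
    """Apply a JSON-style event script in order.

    ``script`` is either a list of event dicts or a mapping with keys
    ``events`` (the list) and optional ``final_names`` (chrom_id renames
    applied at the end) and ``homoeolog_pairs`` (seed for the genome's pair
    set).  Positions may be integer ordinals, fractions of the chromosome's
    current gene count, or ``"centromere"``.  The first invalid step aborts
    with its index.
    """
    if isinstance(script, Mapping):
        events = script.get("events", [])
        final_names = script.get("final_names", {})
        pairs = script.get("homoeolog_pairs", [])
    else:
        events, final_names, pairs = script, {}, []

    g = genome.copy()
    for p in pairs:
        g.homoeolog_pairs.add(frozenset(p))

    for step, ev in enumerate(events):
        etype = ev.get("type", "").upper().replace("-", "_")
        try:
            if etype == EventType.NCF:
                donor = g.get(ev["donor"])
                recipient = g.get(ev["recipient"])
                cuts = ev.get("donor_cuts", [0.1, 0.9])
                g = apply_ncf(
                    g, ev["donor"], ev["recipient"],
                    _resolve_ordinal(cuts[0], donor),
                    _resolve_ordinal(cuts[1], donor),
                    _resolve_ordinal(ev.get("insertion_point", "centromere"), recipient),
                    invert=bool(ev.get("invert", False)),
                    product_id=ev.get("product"),
                    satellite_id=ev.get("satellite"),
                )
            elif etype == EventType.EEJ:
                a = g.get(ev["a"])
                b = g.get(ev["b"])
                g = apply_eej(
                    g, ev["a"], ev["b"],
                    _resolve_ordinal(ev.get("cut_a", 0.9), a),
                    _resolve_ordinal(ev.get("cut_b", 0.1), b),
                    product_id=ev.get("product"),
                    satellite_id=ev.get("satellite"),
                )
            elif etype == EventType.RECIPROCAL_TRANSLOCATION:
                a = g.get(ev["a"])
                b = g.get(ev["b"])
                products = ev.get("products")
                g = apply_reciprocal_translocation(
                    g, ev["a"], ev["b"],
                    _resolve_ordinal(ev["cut_a"], a),
                    _resolve_ordinal(ev["cut_b"], b),
                    product_ids=tuple(products) if products else None,
                )
            elif etype == EventType.INVERSION:
                c = g.get(ev["chrom"])
                g = apply_inversion(
                    g, ev["chrom"],
                    _resolve_ordinal(ev["from"], c),
                    _resolve_ordinal(ev["to"], c),
                )
            elif etype in ("SATELLITE_LOSS", "DROP_SATELLITES"):
                g = drop_satellites(g)
            else:
                raise ValueError(f"unknown event type {ev.get('type')!r}")
        except (KeyError, ValueError) as exc:
            raise ScriptError(step, str(exc)) from exc

    for old, new in final_names.items():
        if old in g:
            chrom = g.get(old)
            chrom.chrom_id = new
            for loc in chrom.loci:
                loc.chrom_id = new
    return g


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _replace(genome: Genome, chrom_id: str, new_chrom: Chromosome) -> None:
    for i, c in enumerate(genome.chromosomes):
        if c.chrom_id == chrom_id:
            genome.chromosomes[i] = new_chrom
            return
    raise KeyError(chrom_id)


def _remove(genome: Genome, chrom_id: str) -> None:
    genome.chromosomes = [c for c in genome.chromosomes if c.chrom_id != chrom_id]


def _fresh_id(genome: Genome, base: str) -> str:
    if base not in genome:
        return base
    k = 2
    while f"{base}{k}" in genome:
        k += 1
    return f"{base}{k}"
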