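"""Inferring the fusion-event trajectory from a chromosome paint.

Under the telomere-centric model every extant chromosome's ordered sequence
of ancestral-origin labels is generated by a small grammar: a chromosome is a
concatenation of *units*, where a unit is a host label X optionally carrying
nested units strictly inside its span (each insertion of a donor interior
into X's pericentromere splits X's run).  Parsing that grammar back out
yields the event list: every nested unit is one nested chromosome fusion
(NCF, invading = child root, invaded = host root), every junction between
consecutive top-level units is one end-end joining (EEJ), and a pair of
chromosomes whose terminal units carry reciprocally exchanged labels is one
reciprocal translocation.  A label sequence that does not fit the grammar
(e.g. X,Y,X,Y) is surfaced as AMBIGUOUS rather than guessed.

Inversions do not change origin labels and are therefore not event-called
from paints; the temporal order of independent events is likewise not
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .painting import Karyogram, PaintSegment

__all__ = [
    "InferredEvent",
    "Trajectory",
    "AmbiguousPaintError",
    "NoCallError",
    "PaintUnit",
    "parse_units",
    "infer_chromosome_events",
    "infer_translocations",
    "assemble_trajectory",
    "compare_trajectories",
]


class NoCallError(ValueError):
    """An empty paint admits no event call."""


class AmbiguousPaintError(ValueError):
    """The label sequence cannot be parsed as a nest/concat combination."""


@dataclass
class PaintUnit:
    """One unit of the paint grammar: host label with nested children."""

    root: str
    children: list["PaintUnit"] = field(default_factory=list)


@dataclass(frozen=True)
class InferredEvent:
    event_type: str  # NCF | EEJ | RECIPROCAL_TRANSLOCATION | NONE | AMBIGUOUS
    carrier: str = ""
    invading_label: str | None = None
    invaded_label: str | None = None
    left_label: str | None = None
    right_label: str | None = None
    partner: str | None = None
    is_homoeologous: bool = False

    def key(self) -> tuple:
        """Canonical identity for cross-trajectory comparison.

        NCF direction matters (invading vs invaded); EEJ and translocation
        are unordered, so reversing a chromosome's paint leaves the key
        unchanged.
        """
        if self.event_type == "NCF":
            return ("NCF", self.invading_label, self.invaded_label)
        if self.event_type == "EEJ":
            return ("EEJ",) + tuple(sorted((self.left_label, self.right_label)))
        if self.event_type == "RECIPROCAL_TRANSLOCATION":
            return ("RECIPROCAL_TRANSLOCATION",) + tuple(
                sorted((self.left_label or "", self.right_label or ""))
            )
        return (self.event_type,)


@dataclass
class Trajectory:
    genome_id: str
    events: list[InferredEvent] = field(default_factory=list)
    n_satellites_implied: int = 0
    chrom_count_initial: int = 0
    chrom_count_final: int = 0
    ambiguous_chroms: list[str] = field(default_factory=list)

    def count(self, event_type: str) -> int:
        return sum(1 for e in self.events if e.event_type == event_type)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "events": [
                {
                    "event_type": e.event_type,
                    "carrier": e.carrier,
                    "invading_label": e.invading_label,
                    "invaded_label": e.invaded_label,
                    "left_label": e.left_label,
                    "right_label": e.right_label,
                    "partner": e.partner,
                    "is_homoeologous": e.is_homoeologous,
                }
                for e in self.events
            ],
            "n_satellites_implied": self.n_satellites_implied,
            "chrom_count_initial": self.chrom_count_initial,
            "chrom_count_final": self.chrom_count_final,
            "ambiguous_chroms": list(self.ambiguous_chroms),
        }

    def report(self) -> str:
        """Human-readable event table."""
        lines = [
            f"Trajectory of {self.genome_id}: "
            f"{self.chrom_count_initial} -> {self.chrom_count_final} chromosomes, "
            f"{self.n_satellites_implied} satellites implied",
            f"{'carrier':<12}{'event':<26}{'labels':<18}{'homoeologous'}",
        ]
        for e in self.events:
            if e.event_type == "NCF":
                labels = f"{e.invading_label} -> {e.invaded_label}"
            elif e.event_type == "EEJ":
                labels = f"{e.left_label} | {e.right_label}"
            elif e.event_type == "RECIPROCAL_TRANSLOCATION":
                labels = f"{e.left_label} <-> {e.right_label}"
            else:
                labels = "-"
            lines.append(
                f"{e.carrier:<12}{e.event_type:<26}{labels:<18}"
                f"{'yes' if e.is_homoeologous else 'no'}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# grammar parsing
# ---------------------------------------------------------------------------

def _reduce(labels: Sequence[str]) -> list[str]:
    out: list[str] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def parse_units(labels: Sequence[str]) -> list[PaintUnit]:
    """Parse a reduced label sequence into top-level paint units.

    Each unit spans from the first to the last occurrence of its root label;
    labels strictly inside that span must not recur outside it, otherwise
    the history is underdetermined and :class:`AmbiguousPaintError` raises.
    Runs between occurrences of the root parse recursively as its children
    (innermost-first is implicit: deeper nests become deeper children).
    """
    labels = _reduce(labels)
    units: list[PaintUnit] = []
    i = 0
    while i < len(labels):
        root = labels[i]
        j = max(k for k, lab in enumerate(labels) if lab == root)
        inside = labels[i + 1:j]
        outside = labels[:i] + labels[j + 1:]
        if set(inside) & set(outside):
            raise AmbiguousPaintError(
                f"label sequence {list(labels)!r} is not a nest/concat history"
            )
        children: list[PaintUnit] = []
        run: list[str] = []
        for lab in inside:
            if lab == root:
                children.extend(parse_units(run))
                run = []
            else:
                run.append(lab)
        children.extend(parse_units(run))
        units.append(PaintUnit(root=root, children=children))
        i = j + 1
    return units


def _ncf_events(unit: PaintUnit, carrier: str,
                pair_map: set[frozenset[str]] | None) -> list[InferredEvent]:
    events = []
    for child in unit.children:
        events.append(InferredEvent(
            event_type="NCF", carrier=carrier,
            invading_label=child.root, invaded_label=unit.root,
            is_homoeologous=_is_pair(pair_map, child.root, unit.root),
        ))
        events.extend(_ncf_events(child, carrier, pair_map))
    return events


def _is_pair(pair_map: set[frozenset[str]] | None, a: str | None, b: str | None) -> bool:
    if pair_map is None or a is None or b is None:
        return False
    return frozenset((a, b)) in pair_map


def infer_chromosome_events(
    paint: Sequence[PaintSegment],
    pair_map: set[frozenset[str]] | None = None,
    carrier: str | None = None,
) -> list[InferredEvent]:
    """Events recorded in one chromosome's paint.

    Pattern X..Y..X is an NCF of Y into X (recursively, innermost-first);
    a junction between consecutive top-level units is an EEJ; a single
    single-label unit yields one NONE event.  An unparseable sequence yields
    one AMBIGUOUS event instead of raising.
    """
    if not paint:
        raise NoCallError("empty paint: no events can be called")
    chrom = carrier or paint[0].chrom_id
    labels = _reduce([s.ref_label for s in paint])
    try:
        units = parse_units(labels)
    except AmbiguousPaintError:
        return [InferredEvent(event_type="AMBIGUOUS", carrier=chrom)]

    events: list[InferredEvent] = []
    for unit in units:
        events.extend(_ncf_events(unit, chrom, pair_map))
    for left, right in zip(units, units[1:]):
        events.append(InferredEvent(
            event_type="EEJ", carrier=chrom,
            left_label=left.root, right_label=right.root,
            is_homoeologous=_is_pair(pair_map, left.root, right.root),
        ))
    if not events:
        events.append(InferredEvent(event_type="NONE", carrier=chrom))
    return events


# ---------------------------------------------------------------------------
# translocations and whole-genome assembly
# ---------------------------------------------------------------------------

def _unit_labels(unit: PaintUnit) -> set[str]:
    labels = {unit.root}
    for c in unit.children:
        labels |= _unit_labels(c)
    return labels


def _terminal_match(units_p: list[PaintUnit], end_p: int,
                    units_q: list[PaintUnit], end_q: int) -> bool:
    """True when P's terminal unit at ``end_p`` (0 = left, -1 = right) and
    Q's at ``end_q`` carry reciprocally exchanged labels."""
    tp, tq = units_p[end_p], units_q[end_q]
    if tp.root == tq.root:
        return False
    others_q = set().union(*(
        _unit_labels(u) for k, u in enumerate(units_q)
        if k != (end_q % len(units_q))
    )) if len(units_q) > 1 else set()
    others_p = set().union(*(
        _unit_labels(u) for k, u in enumerate(units_p)
        if k != (end_p % len(units_p))
    )) if len(units_p) > 1 else set()
    return tp.root in others_q and tq.root in others_p


def infer_translocations(
    karyogram: Karyogram,
    pair_map: set[frozenset[str]] | None = None,
) -> list[InferredEvent]:
    """Reciprocal translocations: chromosome pairs whose terminal paint
    units carry each other's native labels."""
    events, _ = _translocations_with_consumed(karyogram, pair_map)
    return events


def _translocations_with_consumed(
    karyogram: Karyogram,
    pair_map: set[frozenset[str]] | None,
) -> tuple[list[InferredEvent], dict[str, set[int]]]:
    parsed: dict[str, list[PaintUnit]] = {}
    for chrom_id in sorted(karyogram.paints):
        labels = karyogram.labels(chrom_id)
        if not labels:
            continue
        try:
            parsed[chrom_id] = parse_units(labels)
        except AmbiguousPaintError:
            continue

    events: list[InferredEvent] = []
    consumed: dict[str, set[int]] = {}
    seen: set[tuple] = set()
    chroms = sorted(parsed)
    for i, p in enumerate(chroms):
        for q in chroms[i + 1:]:
            up, uq = parsed[p], parsed[q]
            for end_p in (0, -1):
                for end_q in (0, -1):
                    ip = end_p % len(up)
                    iq = end_q % len(uq)
                    if ip in consumed.get(p, set()) or iq in consumed.get(q, set()):
                        continue
                    if _terminal_match(up, end_p, uq, end_q):
                        lp, lq = up[ip].root, uq[iq].root
                        consumed.setdefault(p, set()).add(ip)
                        consumed.setdefault(q, set()).add(iq)
                        # a clean two-chromosome exchange matches at both
                        # end pairs; that is one event, not two
                        key = (p, q, frozenset((lp, lq)))
                        if key in seen:
                            continue
                        seen.add(key)
                        events.append(InferredEvent(
                            event_type="RECIPROCAL_TRANSLOCATION",
                            carrier=p, partner=q,
                            left_label=lp, right_label=lq,
                            is_homoeologous=_is_pair(pair_map, lp, lq),
                        ))
    return events, consumed


def assemble_trajectory(
    karyogram: Karyogram,
    pair_map: set[frozenset[str]] | None = None,
) -> Trajectory:
    """Aggregate the whole genome's inferred events into a trajectory.

    The implied satellite count is #NCF + #EEJ (each such fusion sheds
    exactly one satellite), so the initial chromosome count is the final
    count plus the implied satellites.  Junctions explained by a reciprocal
    translocation are not double-counted as EEJs.  Chromosomes with
    unparseable paints are reported but excluded from the counts.
    """
    traj = Trajectory(genome_id=karyogram.genome_id)
    rt_events, consumed = _translocations_with_consumed(karyogram, pair_map)

    for chrom_id in sorted(karyogram.paints):
        labels = karyogram.labels(chrom_id)
        if not labels:
            continue
        try:
            units = parse_units(labels)
        except AmbiguousPaintError:
            traj.ambiguous_chroms.append(chrom_id)
            traj.events.append(InferredEvent(event_type="AMBIGUOUS", carrier=chrom_id))
            continue
        for unit in units:
            traj.events.extend(_ncf_events(unit, chrom_id, pair_map))
        used = consumed.get(chrom_id, set())
        for k in range(len(units) - 1):
            # junction between units k and k+1; a terminal unit carried in by
            # a translocation explains its junction, which is then no EEJ
            if k in used or (k + 1) in used:
                continue
            traj.events.append(InferredEvent(
                event_type="EEJ", carrier=chrom_id,
                left_label=units[k].root, right_label=units[k + 1].root,
                is_homoeologous=_is_pair(pair_map, units[k].root, units[k + 1].root),
            ))

    traj.events.extend(rt_events)
    n_ncf = traj.count("NCF")
    n_eej = traj.count("EEJ")
    traj.n_satellites_implied = n_ncf + n_eej
    traj.chrom_count_final = sum(1 for c in karyogram.paints.values() if c)
    traj.chrom_count_initial = traj.chrom_count_final + traj.n_satellites_implied
    return traj


def compare_trajectories(t1: Trajectory, t2: Trajectory) -> list[tuple]:
    """Events shared between two trajectories, matched on canonical keys
    (type plus label pair; NCF direction matters)."""
    labels1 = {lab for e in t1.events for lab in
               (e.invading_label, e.invaded_label, e.left_label, e.right_label) if lab}
    labels2 = {lab for e in t2.events for lab in
               (e.invading_label, e.invaded_label, e.left_label, e.right_label) if lab}
    if labels1 and labels2 and not (labels1 & labels2):
        raise ValueError("trajectories use disjoint reference alphabets")

    keys1 = [e.key() for e in t1.events if e.event_type not in ("NONE", "AMBIGUOUS")]
    keys2 = [e.key() for e in t2.events if e.event_type not in ("NONE", "AMBIGUOUS")]
    shared = []
    pool = list(keys2)
    for k in keys1:
        if k in pool:
            shared.append(k)
            pool.remove(k)
    return shared
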