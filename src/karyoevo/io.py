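"""Readers and writers for the standard interchange formats.

Genomes are exported as GFF3 (gene features, 1-based inclusive) plus a gene
family TSV (gene_id, family_id, origin_label); similarity hits travel as
12-column BLAST tabular (outfmt 6); collinear blocks and paints as TSV/BED.
Only the columns the pipeline consumes are interpreted on input; the rest are
carried or filled with neutral values.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .model import Chromosome, GeneLocus, Genome

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_data_json(name: str) -> dict:
    """Load a JSON file bundled under ``karyoevo/data``."""
    with resources.files("karyoevo.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_fixture_script(name: str) -> dict:
    """Load a bundled event script (``triticeae`` or ``brachypodium``)."""
    if not name.endswith(".json"):
        name = f"{name}_script.json"
    return load_data_json(name)


def load_homoeolog_pairs(path: str | None = None) -> set[frozenset[str]]:
    """The shipped (or a user-supplied) homoeolog-pair map as frozensets."""
    if path is None:
        d = load_data_json("rice_homoeolog_pairs.json")
    else:
        with open(path) as fh:
            d = json.load(fh)
    return {frozenset(p) for p in d["pairs"]}


def load_os_to_proto(path: str | None = None) -> dict[str, str]:
    if path is None:
        return dict(load_data_json("os_to_proto.json")["map"])
    with open(path) as fh:
        return dict(json.load(fh)["map"])


# ---------------------------------------------------------------------------
# genome round trip: GFF3 + family TSV
# ---------------------------------------------------------------------------

def write_gff3(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in genome.chromosomes:
            fh.write(f"##sequence-region {chrom.chrom_id} 1 {max(chrom.length_bp, 1)}\n")
        for chrom in genome.chromosomes:
            for loc in chrom.loci:
                attrs = (
                    f"ID={loc.gene_id};family={loc.family_id};"
                    f"origin={loc.origin_label};copy={loc.copy}"
                )
                fh.write(
                    f"{chrom.chrom_id}\tkaryoevo\tgene\t{loc.start_bp}\t{loc.end_bp}"
                    f"\t.\t{loc.strand}\t.\t{attrs}\n"
                )


def write_family_table(genome: Genome, path) -> None:
    rows = [
        (loc.gene_id, loc.family_id, loc.origin_label)
        for chrom in genome.chromosomes
        for loc in chrom.loci
    ]
    pd.DataFrame(rows, columns=["gene_id", "family_id", "origin_label"]).to_csv(
        path, sep="\t", index=False
    )


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        if "=" in piece:
            k, v = piece.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path, genome_id: str = "genome",
              family_table: str | None = None) -> Genome:
    """Build a :class:`Genome` from a GFF3 gene annotation.

    Gene features are taken in coordinate order per seqid; centromeres default
    to the gene-count midpoint.  Family and origin labels come from GFF
    attributes (``family=``, ``origin=``) or, if given, from a family TSV
    (gene_id, family_id[, origin_label]).
    """
    fam: dict[str, tuple[str, str]] = {}
    if family_table is not None:
        tab = pd.read_csv(family_table, sep="\t", dtype=str)
        for row in tab.itertuples(index=False):
            fam[row.gene_id] = (row.family_id, getattr(row, "origin_label", "") or "")

    per_chrom: dict[str, list[GeneLocus]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "mRNA"):
                continue
            seqid, _, _, start, end, _, strand, _, attr = parts[:9]
            attrs = _parse_gff_attributes(attr)
            gid = attrs.get("ID") or attrs.get("Name")
            if gid is None:
                raise ValueError(f"GFF3 feature without ID on {seqid}")
            family, origin = fam.get(
                gid, (attrs.get("family", gid), attrs.get("origin", seqid))
            )
            loc = GeneLocus(
                gene_id=gid, family_id=family, chrom_id=seqid, index=0,
                start_bp=int(start), end_bp=int(end),
                strand=strand if strand in "+-" else "+",
                origin_label=origin, copy=int(attrs.get("copy", 0)),
            )
            per_chrom.setdefault(seqid, []).append(loc)
            if seqid not in order:
                order.append(seqid)

    chroms = []
    for seqid in order:
        loci = sorted(per_chrom[seqid], key=lambda l: l.start_bp)
        for i, loc in enumerate(loci):
            loc.index = i
        chroms.append(Chromosome(chrom_id=seqid, loci=loci,
                                 centromere_index=len(loci) // 2))
    return Genome(genome_id=genome_id, chromosomes=chroms)


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

def write_blast_tabular(hits: Iterable, path) -> None:
    """Write similarity hits as 12-column BLAST tabular (outfmt 6)."""
    rows = []
    for h in hits:
        ev = 10.0 ** max(h.log10_evalue, -180.0)
        rows.append((
            h.query_id, h.subject_id, 95.0, 300, 10, 1, 1, 300, 1, 300,
            f"{ev:.3g}", 500.0,
        ))
    pd.DataFrame(rows, columns=BLAST6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_blast_tabular(path) -> pd.DataFrame:
    """Read BLAST outfmt-6; returns qseqid, sseqid, log10_evalue.

    Malformed rows raise with their 1-based line number.
    """
    import math

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 BLAST tabular columns, "
                    f"got {len(parts)}"
                )
            try:
                ev = float(parts[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad E-value {parts[10]!r}"
                ) from exc
            log10e = math.log10(ev) if ev > 0 else -180.0
            rows.append((parts[0], parts[1], log10e))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "log10_evalue"])


# ---------------------------------------------------------------------------
# blocks and paints
# ---------------------------------------------------------------------------

def write_block_table(blocks: Iterable, path, anchors_path=None) -> None:
    """Blocks as TSV (1-based inclusive bp) plus an optional anchors file."""
    rows, anchor_rows = [], []
    for bid, b in enumerate(blocks):
        rows.append((
            b.chrom_a, b.start_a_bp, b.end_a_bp, b.chrom_b, b.start_b_bp,
            b.end_b_bp, b.orientation, b.n_anchors, round(b.score, 3),
            f"{b.evalue:.3g}", b.homology_class or "",
        ))
        for a in b.anchors:
            anchor_rows.append((bid, a.gene_a, a.gene_b))
    pd.DataFrame(rows, columns=[
        "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
        "orientation", "n_anchors", "score", "evalue", "class",
    ]).to_csv(path, sep="\t", index=False)
    if anchors_path is not None:
        pd.DataFrame(anchor_rows, columns=["block_id", "gene_a", "gene_b"]).to_csv(
            anchors_path, sep="\t", index=False
        )


def write_karyogram_bed(karyogram, path) -> None:
    """Paint segments as BED (0-based half-open) with ref_label in name."""
    with open(path, "w") as fh:
        for chrom_id in sorted(karyogram.paints):
            for seg in karyogram.paints[chrom_id]:
                strand = "+" if seg.orientation == "forward" else "-"
                fh.write(
                    f"{chrom_id}\t{seg.start_bp - 1}\t{seg.end_bp}\t{seg.ref_label}"
                    f"\t{seg.n_anchors}\t{strand}\n"
                )


def karyogram_to_json(karyogram, path=None) -> str:
    d = {
        "genome_id": karyogram.genome_id,
        "scheme": karyogram.scheme,
        "paints": {
            chrom: [
                {
                    "start_bp": s.start_bp, "end_bp": s.end_bp,
                    "ref_label": s.ref_label, "n_anchors": s.n_anchors,
                    "orientation": s.orientation,
                }
                for s in segs
            ]
            for chrom, segs in karyogram.paints.items()
        },
    }
    text = json.dumps(d, sort_keys=True, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
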