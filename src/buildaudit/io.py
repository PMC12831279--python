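"""FASTA and GFF3 interchange.

FASTA goes through Biopython. The GFF3 writer/reader handles the controlled
subset this package emits (gene/mRNA/exon/CDS with ID/Parent attributes),
writing 1-based inclusive coordinates and reading them back into the 0-based
half-open internal convention.
"""
from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AnnotationGene, GeneModel

_SOURCE = "buildaudit"


def write_fasta(records: dict[str, str], path, wrap: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def _fmt_attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v not in (None, ""))


def _cds_phases(cds_spans, strand):
    spans = list(cds_spans) if strand == "+" else list(reversed(cds_spans))
    phases, cum = {}, 0
    for a, b in spans:
        phases[(a, b)] = (3 - cum % 3) % 3
        cum += b - a
    return phases


def gene_gff3_lines(gene, extra_attrs: dict | None = None) -> list[str]:
    """GFF3 lines for one gene (works for GeneModel and AnnotationGene)."""
    gid = gene.gene_id
    attrs = dict(extra_attrs or {})
    if isinstance(gene, GeneModel):
        attrs.setdefault("gene_class", gene.gene_class)
        if gene.sec_positions:
            attrs.setdefault("sec_positions", ",".join(map(str, gene.sec_positions)))
        attrs.setdefault("protein_length", gene.expected_protein_length)
        if gene.partner_id:
            attrs.setdefault("partner", gene.partner_id)
    lines = []

    def row(ftype, a, b, ident, parent=None, phase=".", extra=None):
        attr = _fmt_attrs(ID=ident, Parent=parent, **(extra or {}))
        lines.append("\t".join([
            gene.chrom, _SOURCE, ftype, str(a + 1), str(b), ".",
            gene.strand, str(phase), attr,
        ]))

    row("gene", gene.start, gene.end, gid, extra=attrs)
    row("mRNA", gene.start, gene.end, f"{gid}.t1", parent=gid)
    for i, (a, b) in enumerate(gene.exons, 1):
        row("exon", a, b, f"{gid}.e{i}", parent=f"{gid}.t1")
    phases = _cds_phases(gene.cds_spans, gene.strand)
    for i, (a, b) in enumerate(gene.cds_spans, 1):
        row("CDS", a, b, f"{gid}.c{i}", parent=f"{gid}.t1", phase=phases[(a, b)])
    return lines


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\n".join(gene_gff3_lines(g)) + "\n")


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def _read_features(path):
    """gene_id -> dict(chrom, strand, exons, cds, attrs)."""
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, a, b, _score, strand, _phase, attr = line.split("\t")
        attrs = _parse_attrs(attr)
        iv = (int(a) - 1, int(b))
        if ftype == "gene":
            gid = attrs["ID"]
            genes[gid] = dict(chrom=chrom, strand=strand, exons=[], cds=[],
                              attrs=attrs)
        elif ftype == "mRNA":
            parent_of[attrs["ID"]] = attrs["Parent"]
        elif ftype in ("exon", "CDS"):
            gid = parent_of.get(attrs["Parent"], attrs["Parent"])
            if gid not in genes:
                raise ValueError(f"GFF3 feature with unknown parent: {line}")
            genes[gid]["exons" if ftype == "exon" else "cds"].append(iv)
    for rec in genes.values():
        rec["exons"].sort()
        rec["cds"].sort()
    return genes


def read_gff3(path) -> list[AnnotationGene]:
    out = []
    for gid, rec in _read_features(path).items():
        out.append(AnnotationGene(gid, rec["chrom"], rec["strand"],
                                  rec["exons"], rec["cds"]))
    return out


def read_truth_gff3(path) -> list[GeneModel]:
    """Read a truth annotation written by this package back into GeneModels."""
    out = []
    for gid, rec in _read_features(path).items():
        attrs = rec["attrs"]
        sec = [int(x) for x in attrs.get("sec_positions", "").split(",") if x]
        out.append(GeneModel(
            gid, rec["chrom"], rec["strand"], rec["exons"], rec["cds"],
            attrs.get("gene_class", "multi_exon"), sec,
            int(attrs.get("protein_length", 0)), attrs.get("partner") or None,
        ))
    return out
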