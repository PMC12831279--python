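"""Core domain objects shared across the audit pipeline.

A :class:`GeneModel` is a truth-side gene: the unit being audited. A
:class:`GenomeBuild` is a (possibly corrupted) assembly + annotation under
audit. The :class:`ErrorLedger` records every corruption injected by the
simulator and serves as ground truth when benchmarking the classifier.

Coordinates are 0-based half-open internally; GFF3 emission converts to
1-based inclusive.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from ._util import revcomp

Interval = tuple[int, int]

GENE_CLASSES = (
    "multi_exon",
    "true_intronless",
    "cds_intronless",
    "selenoprotein",
    "readthrough_parent",
    "retroelement",
)

ERROR_KINDS = (
    "none",
    "indel",
    "missing_segment",
    "unannotated",
    "split_locus",
    "merged_locus",
    "premature_stop",
)


def _check_intervals(ivs: Iterable[Interval], label: str) -> None:
    prev_end = None
    for a, b in ivs:
        if not (0 <= a < b):
            raise ValueError(f"{label}: bad interval ({a},{b})")
        if prev_end is not None and a < prev_end:
            raise ValueError(f"{label}: intervals overlap or unsorted")
        prev_end = b


@dataclass
class GeneModel:
    """One reference gene: exon/CDS structure plus audit metadata."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_spans: list[Interval]
    gene_class: str
    sec_positions: list[int] = field(default_factory=list)
    expected_protein_length: int = 0
    partner_id: str | None = None  # readthrough partner, if any

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown gene_class {self.gene_class}")
        _check_intervals(self.exons, f"{self.gene_id} exons")
        _check_intervals(self.cds_spans, f"{self.gene_id} cds")
        if self.gene_class == "true_intronless" and len(self.exons) != 1:
            raise ValueError(f"{self.gene_id}: true_intronless needs exactly 1 exon")
        if self.gene_class == "cds_intronless":
            if len(self.exons) < 2:
                raise ValueError(f"{self.gene_id}: cds_intronless needs >1 exon")
            if not any(a <= self.cds_spans[0][0] and self.cds_spans[-1][1] <= b
                       for a, b in self.exons):
                raise ValueError(f"{self.gene_id}: cds_intronless CDS crosses exons")
        if self.gene_class == "selenoprotein" and not self.sec_positions:
            raise ValueError(f"{self.gene_id}: selenoprotein without sec_positions")

    # -- coordinate helpers -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def _plus_tx_pos(self, g: int) -> int:
        off = 0
        for a, b in self.exons:
            if a <= g < b:
                return off + (g - a)
            off += b - a
        raise ValueError(f"{self.gene_id}: position {g} not exonic")

    def cds_tx_interval(self) -> Interval:
        """CDS location within the spliced transcript (transcript coordinates)."""
        L = self.transcript_length
        s = self._plus_tx_pos(self.cds_spans[0][0])
        e = self._plus_tx_pos(self.cds_spans[-1][1] - 1) + 1
        if self.strand == "+":
            return s, e
        return L - e, L - s

    def spliced(self, chrom_seq: str) -> str:
        t = "".join(chrom_seq[a:b] for a, b in self.exons)
        return t if self.strand == "+" else revcomp(t)

    def cds_seq(self, chrom_seq: str) -> str:
        a, b = self.cds_tx_interval()
        return self.spliced(chrom_seq)[a:b]

    def shifted(self, delta: int) -> "GeneModel":
        return GeneModel(
            self.gene_id, self.chrom, self.strand,
            [(a + delta, b + delta) for a, b in self.exons],
            [(a + delta, b + delta) for a, b in self.cds_spans],
            self.gene_class, list(self.sec_positions),
            self.expected_protein_length, self.partner_id,
        )


@dataclass
class AnnotationGene:
    """A gene feature as a build's annotation presents it."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_spans: list[Interval]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GenomeBuild:
    """An assembly + annotation under audit."""

    build_id: str
    seqs: dict[str, str]
    genes: list[AnnotationGene]
    dialect: str = "truncate"  # how the build represents unresolved indels

    def __post_init__(self) -> None:
        if self.dialect not in ("n_fill", "truncate"):
            raise ValueError(f"unknown dialect {self.dialect}")


@dataclass
class ErrorProfile:
    """Corruption rates for :func:`buildaudit.syngen.inject_build_errors`.

    ``indel_spacing_bp`` is the mean distance between injected coding indels
    (homogeneous Poisson process along the coding sequence); ``None`` disables
    indel injection. The ``p_*`` fields are per-gene (per adjacent pair for
    merged loci) probabilities. ``dialect`` selects how the corrupted build
    represents an indel locus: ``n_fill`` masks a window with ambiguous
    nucleotides and keeps the annotated protein length, ``truncate`` edits the
    assembly sequence itself.
    """

    indel_spacing_bp: float | None = None
    p_missing_segment: float = 0.0
    p_unannotated: float = 0.0
    p_split_locus: float = 0.0
    p_merged_locus: float = 0.0
    p_premature_stop_seleno: float = 0.0
    dialect: str = "truncate"
    retroelement_copies: int = 0
    indel_lengths: tuple[int, ...] = (1, 2)
    n_fill_halfwidth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_missing_segment", "p_unannotated", "p_split_locus",
                     "p_merged_locus", "p_premature_stop_seleno"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.indel_spacing_bp is not None and self.indel_spacing_bp <= 0:
            raise ValueError("indel_spacing_bp must be > 0")
        if self.retroelement_copies < 0:
            raise ValueError("retroelement_copies must be >= 0")
        if self.dialect not in ("n_fill", "truncate"):
            raise ValueError(f"unknown dialect {self.dialect}")

    @property
    def is_zero(self) -> bool:
        return (self.indel_spacing_bp is None
                and self.p_missing_segment == 0 and self.p_unannotated == 0
                and self.p_split_locus == 0 and self.p_merged_locus == 0
                and self.p_premature_stop_seleno == 0)


@dataclass
class LedgerRecord:
    gene_id: str
    error: str
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.error not in ERROR_KINDS:
            raise ValueError(f"unknown error kind {self.error}")


@dataclass
class ErrorLedger:
    """Ground truth of injected corruptions: one record per truth gene,
    plus the genome-level list of indel positions in build coordinates."""

    records: list[LedgerRecord]
    indel_positions: list[tuple[str, int]] = field(default_factory=list)
    #: genomic positions of planted retroelement ORF copies (build coords)
    planted_copies: list[tuple[str, int]] = field(default_factory=list)

    def by_gene(self) -> dict[str, LedgerRecord]:
        return {r.gene_id: r for r in self.records}

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.error] = out.get(r.error, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.gene_id, r.error, json.dumps(r.detail, sort_keys=True))
             for r in self.records],
            columns=["gene_id", "error", "detail"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ErrorLedger":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("{}")
        recs = [LedgerRecord(r.gene_id, r.error, json.loads(r.detail))
                for r in df.itertuples()]
        return cls(recs)
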