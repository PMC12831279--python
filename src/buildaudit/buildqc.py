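"""Per-gene error classification of a genome build against a truth library.

The classifier follows a fixed decision order over the five audit categories
(plus ``correct``), mirroring a manual full-length-sequence search protocol:

(a) no locus covering >= ``c_present`` of the transcript -> sequence_not_present
(b) two or more loci jointly covering it, none individually >= ``c_single``
    -> split_multiple_loci
(c) the locus is annotated by a feature that hosts >= 2 distinct audited
    genes -> multiple_genes_one_locus
(d) no annotated gene feature overlaps the locus -> not_annotated
(e) annotated but the protein-length checksum fails, a premature stop or a
    frameshifting indel is found, or an N-filled window overlaps the CDS
    -> error_in_locus
(f) otherwise correct

Selenoprotein genes are translated Sec-aware (UGA at a flagged codon is
selenocysteine, not a stop), so correctly assembled selenoproteins are never
miscalled as premature-stop errors.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from scipy import stats

from ._util import percent, revcomp
from .align import (KmerIndex, LocusAlignment, MapParams,
                    detect_indels, map_transcript)
from .models import AnnotationGene, GeneModel, GenomeBuild

_STOPS = {"TAA", "TAG", "TGA"}

CATEGORIES = (
    "correct",
    "error_in_locus",
    "split_multiple_loci",
    "multiple_genes_one_locus",
    "not_annotated",
    "sequence_not_present",
)


# ---------------------------------------------------------------------------
# translation and checksum


def translate_cds(cds: str, sec_positions: list[int] | None = None
                  ) -> tuple[str, bool, int | None]:
    """Standard-code translation with selenocysteine recoding.

    TGA at a codon index listed in ``sec_positions`` translates to U and does
    not terminate. Any other in-frame stop before the final codon truncates
    and flags ``premature_stop``. Codons containing N translate to X. Returns
    (protein, premature_stop, index of the terminating stop codon or None).
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    cds = cds.upper()
    sec = set(sec_positions or ())
    n_codons = len(cds) // 3
    protein = []
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        if codon in _STOPS:
            if codon == "TGA" and i in sec:
                protein.append("U")
                continue
            return "".join(protein), i < n_codons - 1, i
        if "N" in codon:
            protein.append("X")
        else:
            protein.append(_CODON_TABLE[codon])
    return "".join(protein), False, None


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table
    return dict(standard_dna_table.forward_table)


_CODON_TABLE = _codon_table()


@dataclass
class ChecksumResult:
    predicted_length: int
    reference_length: int
    passed: bool
    ratio: float


def checksum_protein(predicted: str, reference: str) -> ChecksumResult:
    """Protein-length checksum: predicted vs reference length (stop excluded)."""
    p = predicted.rstrip("*")
    r = reference.rstrip("*")
    if not p or not r:
        raise ValueError("checksum requires non-empty proteins")
    return ChecksumResult(len(p), len(r), len(p) == len(r), len(p) / len(r))


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassifyParams:
    c_present: float = 0.30
    c_single: float = 0.90
    c_joint: float = 0.80


@dataclass
class Evidence:
    n_loci: int = 0
    checksum_pass: bool = False
    has_premature_stop: bool = False
    has_frameshift: bool = False
    n_filled: bool = False


@dataclass
class ErrorCall:
    gene_id: str
    build_id: str
    category: str
    evidence: Evidence = field(default_factory=Evidence)
    pseudogene_flag: bool = False


class _FeatureIndex:
    """Overlap queries over a build's annotated gene features."""

    def __init__(self, genes: list[AnnotationGene]):
        self.by_chrom: dict[str, list[AnnotationGene]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.starts = {}
        for c, gs in self.by_chrom.items():
            gs.sort(key=lambda g: g.start)
            self.starts[c] = [g.start for g in gs]

    def overlapping(self, chrom: str, a: int, b: int) -> list[AnnotationGene]:
        gs = self.by_chrom.get(chrom, [])
        out = []
        i = bisect_left(self.starts.get(chrom, []), b)
        for g in gs[:i]:
            if g.end > a:
                out.append(g)
        return out


def annotated_cds_seq(feature: AnnotationGene, chrom_seq: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in feature.cds_spans)
    return s if feature.strand == "+" else revcomp(s)


def _projected_cds(gene: GeneModel, aln: LocusAlignment, chrom_seq: str) -> str:
    """Build-side sequence under the truth CDS, read off the alignment blocks."""
    a, b = gene.cds_tx_interval()
    if aln.strand == "-":
        L = aln.transcript_length
        a, b = L - b, L - a
    parts = []
    for (t0, t1), (g0, _g1) in aln.blocks:
        lo, hi = max(t0, a), min(t1, b)
        if lo < hi:
            parts.append(chrom_seq[g0 + (lo - t0):g0 + (hi - t0)])
    seq = "".join(parts)
    return seq if aln.strand == "+" else revcomp(seq)


def classify_gene(gene: GeneModel, alignments: list[LocusAlignment],
                  build: GenomeBuild, feature_index: _FeatureIndex,
                  feature_gene_counts: dict[str, int] | None = None,
                  params: ClassifyParams = ClassifyParams()) -> ErrorCall:
    """Classify one gene against a build (decision order (a)-(f) above)."""
    present = [a for a in alignments if a.coverage >= params.c_present]
    ev = Evidence(n_loci=len(present))
    if not present:
        return ErrorCall(gene.gene_id, build.build_id, "sequence_not_present", ev)

    joint = min(sum(a.coverage for a in present), 1.0)
    if (len(present) >= 2 and joint >= params.c_joint
            and all(a.coverage < params.c_single for a in present)):
        return ErrorCall(gene.gene_id, build.build_id, "split_multiple_loci", ev)

    primary = present[0]
    feats = feature_index.overlapping(primary.chrom, primary.g_start,
                                      primary.g_end)
    if feats and feature_gene_counts:
        if any(feature_gene_counts.get(f.gene_id, 0) >= 2 for f in feats):
            return ErrorCall(gene.gene_id, build.build_id,
                             "multiple_genes_one_locus", ev)
    if not feats:
        return ErrorCall(gene.gene_id, build.build_id, "not_annotated", ev)

    feature = max(feats, key=lambda f: (min(f.end, primary.g_end)
                                        - max(f.start, primary.g_start)))
    chrom_seq = build.seqs[primary.chrom]
    cds = annotated_cds_seq(feature, chrom_seq)
    checksum = None
    if len(cds) >= 3:
        n_cod = len(cds) // 3
        sec = [p for p in gene.sec_positions if p < n_cod]
        protein, premature, _ = translate_cds(cds, sec)
        ev.has_premature_stop = premature
        if protein:
            checksum = checksum_protein(protein, "M" * gene.expected_protein_length)
            ev.checksum_pass = checksum.passed
        ev.n_filled = "N" in cds
    events = detect_indels(primary, gene.cds_tx_interval())
    ev.has_frameshift = any(e.frameshifting for e in events)

    pseudogene = False
    if ev.has_premature_stop:
        proj = _projected_cds(gene, primary, chrom_seq)
        if len(proj) >= 3:
            sec = [p for p in gene.sec_positions if p < len(proj) // 3]
            _p, prem2, idx2 = translate_cds(proj, sec)
            if prem2 and idx2 is not None:
                codon = proj[3 * idx2:3 * idx2 + 3]
                pseudogene = "N" not in codon

    if (not ev.checksum_pass or ev.has_premature_stop or ev.has_frameshift
            or ev.n_filled):
        return ErrorCall(gene.gene_id, build.build_id, "error_in_locus", ev,
                         pseudogene)
    return ErrorCall(gene.gene_id, build.build_id, "correct", ev)


def audit_build(truth, build: GenomeBuild,
                map_params: MapParams = MapParams(),
                params: ClassifyParams = ClassifyParams()) -> list[ErrorCall]:
    """Map every truth transcript to the build and classify every gene.

    ``truth`` is a :class:`~buildaudit.syngen.TruthSet` (or anything with
    ``models`` and ``transcripts``). The classifier never sees the ledger.
    """
    index = KmerIndex(build.seqs, map_params.k)
    fidx = _FeatureIndex(build.genes)
    aligned: dict[str, list[LocusAlignment]] = {}
    feature_gene_counts: dict[str, int] = {}
    for m in truth.models:
        alns = map_transcript(truth.transcripts[m.gene_id], index, map_params,
                              transcript_id=m.gene_id)
        aligned[m.gene_id] = alns
        present = [a for a in alns if a.coverage >= params.c_present]
        if present:
            p = present[0]
            for f in fidx.overlapping(p.chrom, p.g_start, p.g_end):
                feature_gene_counts[f.gene_id] = \
                    feature_gene_counts.get(f.gene_id, 0) + 1
    return [classify_gene(m, aligned[m.gene_id], build, fidx,
                          feature_gene_counts, params)
            for m in truth.models]


# ---------------------------------------------------------------------------
# summaries


@dataclass
class BuildSummary:
    build_id: str
    counts: dict[str, int]
    total: int
    percent_correct: float


def summarize_build(calls: list[ErrorCall]) -> BuildSummary:
    """Per-category counts and percent correct (half-up, 1 decimal)."""
    if not calls:
        raise ValueError("no error calls to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    total = len(calls)
    return BuildSummary(calls[0].build_id, counts, total,
                        percent(counts["correct"], total))


@dataclass
class IndelEstimate:
    n_events: int
    covered_bp: int
    bp_per_indel: float
    ci95: tuple[float, float]


def estimate_indel_rate(events, covered_bp: int) -> IndelEstimate:
    """Mean bp between coding indels with an exact 95% Poisson interval.

    ``events`` may be a list of :class:`IndelEvent` or an event count. With
    zero events the estimate is flagged infinite.
    """
    if covered_bp <= 0:
        raise ValueError("covered_bp must be positive")
    n = events if isinstance(events, int) else len(events)
    if n == 0:
        return IndelEstimate(0, covered_bp, float("inf"),
                             (2 * covered_bp / stats.chi2.ppf(0.975, 2), float("inf")))
    lam_lo = stats.chi2.ppf(0.025, 2 * n) / 2
    lam_hi = stats.chi2.ppf(0.975, 2 * n + 2) / 2
    return IndelEstimate(n, covered_bp, covered_bp / n,
                         (covered_bp / lam_hi, covered_bp / lam_lo))
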