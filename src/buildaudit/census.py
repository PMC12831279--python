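"""Feature-level censuses: domain architectures, intronless classes,
readthrough confidence, UTR/splice conservation, six-frame ORF homology.

Domain architectures are compared by (name, occurrence order) — the
formalization of comparing annotated domain tracks side by side — so a domain
instance is "shared" when all species carry an occurrence of that rank, and
otherwise falls in exactly one two-species or single-species pattern. The
six-frame ORF scan is the desk-scale analog of a translated search of a
protein against a genome, used to census retroelement ORF copies and
microprotein candidates; a hit with an internal stop or a frame break in an
otherwise matching copy is flagged pseudogenized.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._util import revcomp
from .align import global_identity, pairwise_protein_align
from .buildqc import _CODON_TABLE
from .models import AnnotationGene

# ---------------------------------------------------------------------------
# domain architectures


@dataclass
class DomainArchitecture:
    protein_id: str
    domains: list[tuple[str, int, int]]   # (name, start AA, end AA), ordered

    def __post_init__(self) -> None:
        starts = [s for _, s, _ in self.domains]
        if starts != sorted(starts):
            raise ValueError(f"{self.protein_id}: domains not ordered by start")

    def name_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, _s, _e in self.domains:
            out[name] = out.get(name, 0) + 1
        return out


PATTERNS = ("shared_all", "pig_human", "mouse_human", "pig_mouse",
            "pig_only", "mouse_only", "human_only")


@dataclass
class DomainDiff:
    gene_id: str
    instances: list[tuple[str, int, str]]   # (domain name, rank, pattern)

    def pattern_counts(self) -> dict[str, int]:
        out = {p: 0 for p in PATTERNS}
        for _n, _r, p in self.instances:
            out[p] += 1
        return out


def compare_architectures(arch_pig: DomainArchitecture,
                          arch_mouse: DomainArchitecture,
                          arch_human: DomainArchitecture,
                          gene_id: str = "") -> DomainDiff:
    """Assign every domain instance of an ortholog trio to a presence pattern."""
    counts = {"pig": arch_pig.name_counts(), "mouse": arch_mouse.name_counts(),
              "human": arch_human.name_counts()}
    names = sorted(set().union(*counts.values()))
    if not names:
        raise ValueError("all three architectures are empty")
    instances = []
    for name in names:
        for rank in range(max(c.get(name, 0) for c in counts.values())):
            present = frozenset(sp for sp, c in counts.items()
                                if c.get(name, 0) > rank)
            pattern = {
                frozenset({"pig", "mouse", "human"}): "shared_all",
                frozenset({"pig", "human"}): "pig_human",
                frozenset({"mouse", "human"}): "mouse_human",
                frozenset({"pig", "mouse"}): "pig_mouse",
                frozenset({"pig"}): "pig_only",
                frozenset({"mouse"}): "mouse_only",
                frozenset({"human"}): "human_only",
            }[present]
            instances.append((name, rank, pattern))
    return DomainDiff(gene_id, instances)


def domain_sharing_ratio(diffs: list[DomainDiff]) -> float | None:
    """count(pig_human) / count(mouse_human) over a gene set; None if undefined."""
    num = sum(d.pattern_counts()["pig_human"] for d in diffs)
    den = sum(d.pattern_counts()["mouse_human"] for d in diffs)
    return num / den if den > 0 else None


# ---------------------------------------------------------------------------
# intronless classification


def detect_intronless(gene: AnnotationGene) -> str:
    """true_intronless (1 exon), cds_intronless (CDS in one exon of several),
    or multi_exon."""
    if not gene.cds_spans:
        raise ValueError(f"{gene.gene_id}: no CDS")
    if len(gene.exons) == 1:
        return "true_intronless"
    cds_a, cds_b = gene.cds_spans[0][0], gene.cds_spans[-1][1]
    if any(a <= cds_a and cds_b <= b for a, b in gene.exons):
        return "cds_intronless"
    return "multi_exon"


# ---------------------------------------------------------------------------
# readthrough confidence


@dataclass
class ReadthroughEvidence:
    gene_pair_id: str
    transcript_predicted: bool
    n_other_species_with_transcript: int
    pig_transcription_evidence: bool

    def __post_init__(self) -> None:
        if self.n_other_species_with_transcript < 0:
            raise ValueError("n_other_species_with_transcript must be >= 0")


def score_readthrough(ev: ReadthroughEvidence) -> int:
    """Confidence 0-4 for a candidate readthrough (conjoined) gene.

    0 no transcript predicted; 1 predicted, no support elsewhere; 2 predicted
    with support in other species only; 3 predicted, limited outside support,
    transcription shown in pig; 4 predicted, support in >= 2 other species and
    transcription shown in pig.
    """
    if not ev.transcript_predicted:
        return 0
    if not ev.pig_transcription_evidence:
        return 1 if ev.n_other_species_with_transcript == 0 else 2
    return 3 if ev.n_other_species_with_transcript < 2 else 4


# ---------------------------------------------------------------------------
# UTR and splice-variant conservation


@dataclass
class UtrConservation:
    gene_id: str
    utr5_identity: float | None
    cds_identity: float | None
    utr3_identity: float | None
    low5: bool
    low3: bool


def utr_conservation(mrna_a: str, cds_a: tuple[int, int],
                     mrna_b: str, cds_b: tuple[int, int],
                     threshold5: float = 0.60, threshold3: float = 0.60,
                     gene_id: str = "") -> UtrConservation:
    """Global-alignment identity of the 5'UTR, CDS and 3'UTR separately.

    A zero-length UTR on either side leaves that identity undefined and the
    low flag unset.
    """
    for (a, b), L in ((cds_a, len(mrna_a)), (cds_b, len(mrna_b))):
        if not 0 <= a <= b <= L:
            raise ValueError("CDS boundaries outside mRNA")
    u5 = global_identity(mrna_a[:cds_a[0]], mrna_b[:cds_b[0]])
    cds = global_identity(mrna_a[cds_a[0]:cds_a[1]], mrna_b[cds_b[0]:cds_b[1]])
    u3 = global_identity(mrna_a[cds_a[1]:], mrna_b[cds_b[1]:])
    return UtrConservation(gene_id, u5, cds, u3,
                           u5 is not None and u5 < threshold5,
                           u3 is not None and u3 < threshold3)


def splice_conservation(exon_count_a: int, exon_count_b: int,
                        variant_table: dict[str, bool] | None = None
                        ) -> tuple[int, float | None]:
    """(exon-count delta a-b, conserved fraction of reference splice variants).

    ``variant_table`` maps reference variant id -> conserved in the other
    species; the fraction is None when no table is supplied.
    """
    if exon_count_a < 1 or exon_count_b < 1:
        raise ValueError("exon counts must be >= 1")
    frac = None
    if variant_table:
        frac = sum(variant_table.values()) / len(variant_table)
    return exon_count_a - exon_count_b, frac


# ---------------------------------------------------------------------------
# six-frame ORF homology search


@dataclass
class OrfHit:
    chrom: str
    start: int            # genomic, 0-based half-open, forward strand
    end: int
    strand: str
    frame: int            # 0..2 within strand
    identity: float
    score: float
    intact: bool
    pseudogenized: bool


def _frame_translation(seq: str, frame: int) -> str:
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in ("TAA", "TAG", "TGA"):
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


def _query_seeds(query: str, k: int = 5) -> set[str]:
    return {query[i:i + k] for i in range(len(query) - k + 1)}


def orf_homology_search(query: str, genome: dict[str, str],
                        min_identity: float = 0.80,
                        min_length_fraction: float = 0.80) -> list[OrfHit]:
    """Scan all six reading frames of a genome for copies of a protein.

    Windows of each frame translation sharing an exact 5-mer with the query
    are aligned locally; a hit is intact iff it covers the required fraction
    of the query at the identity floor within one frame and without internal
    stops. Overlapping hits are resolved greedily by score, then leftmost.
    """
    if len(query) < 30:
        raise ValueError("query must be at least 30 aa")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    seeds = _query_seeds(query)
    w = max(2 * len(query), 200)
    raw: list[OrfHit] = []
    for chrom, seq in genome.items():
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for frame in range(3):
                prot = _frame_translation(s, frame)
                for off in range(0, max(len(prot) - w // 2, 1), w // 2):
                    win = prot[off:off + w]
                    if not (seeds & _query_seeds(win)):
                        continue
                    res = pairwise_protein_align(query, win.replace("*", "X"))
                    if res.identity is None or res.identity < min_identity:
                        continue
                    if res.aligned_length < min_length_fraction * len(query):
                        continue
                    # map the aligned region (not the whole window) back to
                    # forward genomic coordinates
                    w0, w1 = res.target_span
                    aa0, aa1 = off + w0, off + w1
                    g0 = frame + 3 * aa0
                    g1 = frame + 3 * aa1
                    if strand == "-":
                        g0, g1 = len(seq) - g1, len(seq) - g0
                    has_stop = "*" in win[w0:w1]
                    raw.append(OrfHit(chrom, max(g0, 0), min(g1, len(seq)),
                                      strand, frame, res.identity, res.score,
                                      not has_stop, has_stop))
    # greedy non-overlap resolution, merging frame-broken copies
    raw.sort(key=lambda h: (-h.score, h.chrom, h.start))
    chosen: list[OrfHit] = []
    for h in raw:
        overlapping = [c for c in chosen
                       if c.chrom == h.chrom
                       and not (h.end <= c.start or c.end <= h.start)]
        if overlapping:
            for c in overlapping:
                if c.frame != h.frame or c.strand != h.strand:
                    c.intact = False
                    c.pseudogenized = True
            continue
        chosen.append(h)
    chosen.sort(key=lambda h: (h.chrom, h.start))
    return chosen


def readthrough_total(counts_by_category: dict[int, int]) -> int:
    """Sum of per-category candidate counts (reporting convenience)."""
    return sum(counts_by_category.values())
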