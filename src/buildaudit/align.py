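"""Spliced transcript-to-genome mapping, protein alignment, indel detection.

The mapper is a deterministic seed-and-chain aligner: exact k-mer anchors
against a sorted genome index, runs of co-diagonal anchors merged into
blocks, blocks chained co-linearly per candidate locus. Inter-block gaps are
classified as introns (transcript gap ~0, genome gap >= ``min_intron``,
preferably at GT..AG) or as indels when the two sides disagree in length.

Protein alignment is optimal local (Smith-Waterman) alignment under an
extended BLOSUM62 in which selenocysteine (U) scores as cysteine and X is
neutral; nucleotide and global variants are provided for the RNA orthology
tier and the UTR-conservation census.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._util import encode_seq, revcomp

# ---------------------------------------------------------------------------
# scoring

_PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZXU*"


def _extended_blosum62():
    base = substitution_matrices.load("BLOSUM62")
    m = substitution_matrices.Array(alphabet=_PROT_ALPHABET, dims=2)
    for a in _PROT_ALPHABET:
        for b in _PROT_ALPHABET:
            aa = "C" if a == "U" else a
            bb = "C" if b == "U" else b
            if a == "X" or b == "X":
                m[a, b] = 0.0
            elif aa in base.alphabet and bb in base.alphabet:
                m[a, b] = base[aa, bb]
            else:
                m[a, b] = -4.0
    return m


BLOSUM62_EXT = _extended_blosum62()


@dataclass(frozen=True)
class ProteinScoring:
    gap_open: float = -11.0
    gap_extend: float = -1.0


@dataclass
class AlignmentResult:
    score: float
    identity: float | None   # None when undefined (empty input)
    aligned_length: int
    #: aligned region on the second ("target") sequence, half-open
    target_span: tuple[int, int] | None = None


def _make_aligner(mode, matrix=None, match=None, mismatch=None,
                  gap_open=-11.0, gap_extend=-1.0):
    al = Align.PairwiseAligner()
    al.mode = mode
    if matrix is not None:
        al.substitution_matrix = matrix
    else:
        al.match_score = match
        al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _best_alignment_stats(aligner, a, b) -> AlignmentResult:
    try:
        aln = next(iter(aligner.align(a, b)))
    except StopIteration:   # local mode with no positively scoring alignment
        return AlignmentResult(0.0, None, 0)
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    ident = c.identities / cols if cols else None
    span = None
    blocks = aln.aligned[1]
    if len(blocks):
        span = (int(blocks[0][0]), int(blocks[-1][1]))
    return AlignmentResult(float(aln.score), ident, cols, span)


def pairwise_protein_align(seq_a: str, seq_b: str,
                           scoring: ProteinScoring = ProteinScoring()
                           ) -> AlignmentResult:
    """Optimal local protein alignment (score, identity, aligned columns).

    Empty input yields score 0 with identity flagged undefined (None).
    """
    if not seq_a or not seq_b:
        return AlignmentResult(0.0, None, 0)
    al = _make_aligner("local", matrix=BLOSUM62_EXT,
                       gap_open=scoring.gap_open, gap_extend=scoring.gap_extend)
    return _best_alignment_stats(al, seq_a, seq_b)


def pairwise_nucleotide_align(seq_a: str, seq_b: str) -> AlignmentResult:
    if not seq_a or not seq_b:
        return AlignmentResult(0.0, None, 0)
    al = _make_aligner("local", match=2.0, mismatch=-3.0,
                       gap_open=-5.0, gap_extend=-2.0)
    return _best_alignment_stats(al, seq_a, seq_b)


def global_identity(seq_a: str, seq_b: str) -> float | None:
    """Identity over the optimal global alignment; None for empty input."""
    if not seq_a or not seq_b:
        return None
    al = _make_aligner("global", match=2.0, mismatch=-1.0,
                       gap_open=-2.0, gap_extend=-0.5)
    return _best_alignment_stats(al, seq_a, seq_b).identity


# ---------------------------------------------------------------------------
# genome k-mer index

_CHROM_GUARD = 1_000_000  # global-coordinate padding between chromosomes


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every window; windows containing N are invalid."""
    n = enc.size
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, bool)
    enc64 = (enc & 3).astype(np.uint64)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | enc64[i:n - k + 1 + i]
    bad = np.concatenate([[0], np.cumsum(enc == 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


class KmerIndex:
    """Sorted exact k-mer index over a genome (dict of chromosome sequences)."""

    def __init__(self, seqs: dict[str, str], k: int = 16):
        if not seqs or all(len(s) == 0 for s in seqs.values()):
            raise ValueError("empty genome")
        self.k = k
        self.seqs = seqs
        self.chroms = list(seqs)
        self.offsets = {}
        codes_all, pos_all = [], []
        off = 0
        for c in self.chroms:
            self.offsets[c] = off
            codes, valid = _kmer_codes(encode_seq(seqs[c]), k)
            idx = np.flatnonzero(valid)
            codes_all.append(codes[idx])
            pos_all.append(idx.astype(np.int64) + off)
            off += len(seqs[c]) + _CHROM_GUARD
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]
        self._bounds = np.array([self.offsets[c] for c in self.chroms]
                                + [off], dtype=np.int64)

    def chrom_of(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        return self.chroms[i], int(gpos - self._bounds[i])

    def anchors(self, query: str, max_hits: int = 50
                ) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, global_genome_pos) exact k-mer matches."""
        codes, valid = _kmer_codes(encode_seq(query), self.k)
        qpos = np.flatnonzero(valid)
        codes = codes[qpos]
        # query in sorted order for cache-friendly binary search
        qorder = np.argsort(codes, kind="stable")
        inv = np.empty_like(qorder)
        inv[qorder] = np.arange(qorder.size)
        lo = np.searchsorted(self.codes, codes[qorder], side="left")[inv]
        hi = np.searchsorted(self.codes, codes[qorder], side="right")[inv]
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_hits)
        single = keep & (counts == 1)
        t_list = [qpos[single]]
        g_list = [self.pos[lo[single]]]
        for i in np.flatnonzero(keep & (counts > 1)):
            g = self.pos[lo[i]:hi[i]]
            t_list.append(np.full(g.size, qpos[i], dtype=np.int64))
            g_list.append(g)
        t = np.concatenate(t_list)
        g = np.concatenate(g_list)
        return t, g


# ---------------------------------------------------------------------------
# spliced mapping


@dataclass(frozen=True)
class MapParams:
    k: int = 16
    min_exon_seed: int = 16
    min_identity: float = 0.85
    min_report_coverage: float = 0.25
    min_intron: int = 30
    max_intron: int = 50_000
    min_run: int = 2          # anchors needed to accept a block
    max_hits: int = 50


@dataclass
class Gap:
    t_pos: int
    g_pos: int          # chromosome coordinate of the gap start
    t_gap: int
    g_gap: int
    is_intron: bool
    canonical: bool = False


@dataclass
class LocusAlignment:
    transcript_id: str
    chrom: str
    strand: str
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    gaps: list[Gap]
    identity: float
    coverage: float
    matches: int
    transcript_length: int

    @property
    def g_start(self) -> int:
        return self.blocks[0][1][0]

    @property
    def g_end(self) -> int:
        return self.blocks[-1][1][1]


def _runs_to_blocks(t: np.ndarray, g: np.ndarray, k: int, min_run: int):
    """Merge co-diagonal anchor runs into exact-match blocks."""
    order = np.lexsort((g, t))
    t, g = t[order], g[order]
    diag = g - t
    if t.size == 0:
        return []
    brk = np.flatnonzero((np.diff(diag) != 0) | (np.diff(t) > k) | (np.diff(t) <= 0))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk + 1, [t.size]])
    blocks = []
    for s, e in zip(starts, ends):
        if e - s < min_run:
            continue
        blocks.append(((int(t[s]), int(t[e - 1]) + k),
                       (int(g[s]), int(g[e - 1]) + k)))
    return blocks


def _chain(blocks):
    """Co-linear chain of blocks maximizing matched bases (small-n DP)."""
    blocks = sorted(blocks, key=lambda b: (b[0][0], b[1][0]))
    n = len(blocks)
    best = [b[0][1] - b[0][0] for b in blocks]
    back = [-1] * n
    for i in range(n):
        (ti, _tie), (gi, _gie) = blocks[i]
        li = blocks[i][0][1] - blocks[i][0][0]
        for j in range(i):
            (tj, tje), (gj, gje) = blocks[j]
            if tj < ti and gj < gi and tje <= ti + 32 and gje <= gi + 32:
                cand = best[j] + li - 1
                if cand > best[i]:
                    best[i], back[i] = cand, j
    i = int(np.argmax(best))
    chain = []
    while i != -1:
        chain.append(blocks[i])
        i = back[i]
    chain.reverse()
    # trim residual micro-overlaps between consecutive blocks
    out = [chain[0]]
    for (t0, t1), (g0, g1) in chain[1:]:
        (pt0, pt1), (pg0, pg1) = out[-1]
        ov = max(pt1 - t0, pg1 - g0, 0)
        if t0 + ov < t1 and g0 + ov < g1:
            out.append(((t0 + ov, t1), (g0 + ov, g1)))
    return out


def _classify_gaps(chain, chrom_seq, params, strand="+"):
    gaps = []
    for ((_pt0, pt1), (_pg0, pg1)), ((t0, _t1), (g0, _g1)) in zip(chain, chain[1:]):
        t_gap, g_gap = t0 - pt1, g0 - pg1
        if t_gap == 0 and g_gap == 0:
            continue
        is_intron = t_gap <= 2 and g_gap >= params.min_intron
        canonical = False
        if is_intron:
            # exact gap placement is ambiguous under micro-homology, so the
            # intron is canonical if some small shift lands on the motif
            want = ("GT", "AG") if strand == "+" else ("CT", "AC")
            for s in range(-3, 4):
                if (chrom_seq[pg1 + s:pg1 + s + 2] == want[0]
                        and chrom_seq[g0 + s - 2:g0 + s] == want[1]):
                    canonical = True
                    break
        gaps.append(Gap(pt1, pg1, t_gap, g_gap, is_intron, canonical))
    return gaps


def _map_oriented(tid, query, index, params, strand):
    try:
        t, g = index.anchors(query, params.max_hits)
    except ValueError:
        return []
    if t.size == 0:
        return []
    order = np.argsort(g, kind="stable")
    gs, ts = g[order], t[order]
    splits = np.flatnonzero(np.diff(gs) > params.max_intron)
    bounds = np.concatenate([[0], splits + 1, [gs.size]])
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        blocks = _runs_to_blocks(ts[s:e], gs[s:e], params.k, params.min_run)
        if not blocks:
            continue
        chain = _chain(blocks)
        matches = sum(t1 - t0 for (t0, t1), _ in chain)
        coverage = matches / len(query)
        if coverage < params.min_report_coverage:
            continue
        chrom, base = index.chrom_of(chain[0][1][0])
        local = [((t0, t1), (g0 - index.offsets[chrom], g1 - index.offsets[chrom]))
                 for (t0, t1), (g0, g1) in chain]
        gaps = _classify_gaps(local, index.seqs[chrom], params, strand)
        mism = sum(min(gp.t_gap, gp.g_gap) for gp in gaps if not gp.is_intron)
        t_extra = sum(max(gp.t_gap - gp.g_gap, 0) for gp in gaps if not gp.is_intron)
        denom = matches + mism + t_extra
        identity = matches / denom if denom else 0.0
        if identity < params.min_identity:
            continue
        out.append(LocusAlignment(tid, chrom, strand, local, gaps, identity,
                                  coverage, matches, len(query)))
    return out


def map_transcript(transcript: str, index: KmerIndex,
                   params: MapParams = MapParams(),
                   transcript_id: str = "query") -> list[LocusAlignment]:
    """Map a transcript to the genome; loci sorted by matched bases.

    Both orientations are tried; reverse-strand hits carry ``strand='-'``
    with block transcript coordinates expressed on the reverse complement.
    """
    if len(transcript) < params.min_exon_seed:
        raise ValueError("transcript shorter than min_exon_seed")
    loci = _map_oriented(transcript_id, transcript, index, params, "+")
    best_cov = max((a.coverage for a in loci), default=0.0)
    if best_cov < 0.95:  # a fully mapped forward hit cannot hide a better locus
        loci += _map_oriented(transcript_id, revcomp(transcript), index, params, "-")
    # an exactly palindromic locus would be reported once per orientation;
    # keep the better-scoring duplicate
    loci.sort(key=lambda a: (-a.matches, a.chrom, a.g_start))
    dedup: list[LocusAlignment] = []
    for a in loci:
        if any(d.chrom == a.chrom and not (a.g_end <= d.g_start or d.g_end <= a.g_start)
               for d in dedup):
            continue
        dedup.append(a)
    return dedup


# ---------------------------------------------------------------------------
# indel detection


@dataclass
class IndelEvent:
    chrom: str
    position: int
    kind: str            # what the build gained ("insertion") or lost ("deletion")
    length: int
    frameshifting: bool


def detect_indels(alignment: LocusAlignment,
                  cds_tx_interval: tuple[int, int] | None) -> list[IndelEvent]:
    """One event per non-intron gap whose two sides differ in length.

    ``cds_tx_interval`` is the CDS window in original transcript coordinates;
    it is mirrored automatically for reverse-strand alignments. Events are
    sorted by genome position; ``frameshifting`` is set iff the event lies in
    the CDS and its length is not a multiple of 3.
    """
    cds = None
    if cds_tx_interval is not None:
        a, b = cds_tx_interval
        L = alignment.transcript_length
        cds = (a, b) if alignment.strand == "+" else (L - b, L - a)
    events = []
    for gp in alignment.gaps:
        if gp.is_intron or gp.t_gap == gp.g_gap:
            continue
        diff = gp.g_gap - gp.t_gap
        kind = "insertion" if diff > 0 else "deletion"
        length = abs(diff)
        in_cds = cds is not None and (cds[0] <= gp.t_pos < cds[1])
        events.append(IndelEvent(alignment.chrom, gp.g_pos, kind, length,
                                 in_cds and length % 3 != 0))
    events.sort(key=lambda e: e.position)
    return events
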