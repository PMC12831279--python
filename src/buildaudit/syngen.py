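"""Synthetic truth genomes and corrupted builds with a machine-readable ledger.

The generator emulates a curated transcript/protein library and the genome it
came from: multi-exon genes, true- and CDS-intronless genes, selenoproteins
(UGA recoded to Sec), adjacent readthrough parent pairs and a planted
retroelement ORF. :func:`inject_build_errors` then corrupts a copy of that
genome with the error classes a build audit must recover — coding indels
(Poisson along the CDS), missing sequence, missing annotation, split and
merged loci, and selenoprotein premature-stop annotation — while writing every
corruption to an :class:`~buildaudit.models.ErrorLedger`.

Two indel "dialects" are modelled: ``n_fill`` masks a window around the indel
with ambiguous nucleotides and leaves the annotation (and hence the annotated
protein length) untouched; ``truncate`` edits the assembly sequence itself and
lifts all annotation coordinates through the edits.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp, substream
from .buildqc import translate_cds
from .models import (AnnotationGene, ErrorLedger, ErrorProfile, GeneModel,
                     GenomeBuild, LedgerRecord)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                 if "".join(c) not in _STOPS]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class GenerationConfig:
    """Parameters of the synthetic gene library.

    ``counts`` gives the number of genes per gene class. Length parameters are
    inclusive (lo, hi) ranges in bp or codons. Defaults are sized for a
    desk-scale genome whose genes look like compact mammalian protein-coding
    genes: ~0.3-1.2 kb CDS, 1-8 exons, 0.1-3 kb introns.
    """

    counts: dict[str, int] = field(default_factory=lambda: {"multi_exon": 20})
    cds_codons: tuple[int, int] = (100, 400)       # internal codons, excl. start/stop
    exon_count: tuple[int, int] = (2, 8)           # for multi-exon classes
    utr5_len: tuple[int, int] = (100, 250)
    utr3_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (120, 3000)
    intergenic_len: tuple[int, int] = (1000, 5000)
    readthrough_gap: tuple[int, int] = (300, 800)
    min_exon_len: int = 40
    p_minus_strand: float = 0.3
    retro_cds_codons: int = 300
    n_sec_range: tuple[int, int] = (1, 3)
    chrom: str = "chr1"
    genome_length: int | None = None               # optional hard cap

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cls}")
        for name in ("cds_codons", "exon_count", "utr5_len", "utr3_len",
                     "intron_len", "intergenic_len"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"bad range for {name}: ({lo},{hi})")
        if not 0.0 <= self.p_minus_strand <= 1.0:
            raise ValueError("p_minus_strand must be in [0,1]")


@dataclass
class DraftGene:
    """A generated gene before genome placement: local coordinates + body."""
    model: GeneModel      # coordinates relative to the gene body
    body: str             # genomic-forward sequence of the gene region
    transcript: str
    protein: str


@dataclass
class TruthSet:
    """A placed truth genome: sequences, gene models and library records."""
    genome: dict[str, str]
    models: list[GeneModel]
    transcripts: dict[str, str]
    proteins: dict[str, str]

    def annotation_view(self) -> list[AnnotationGene]:
        return [AnnotationGene(m.gene_id, m.chrom, m.strand,
                               list(m.exons), list(m.cds_spans))
                for m in self.models]


def _uniform(rng, lohi) -> int:
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1))


def _build_gene(rng, cfg: GenerationConfig, gid: str, gene_class: str,
                strand: str, shared_cds: str | None = None) -> DraftGene:
    # --- transcript layout -------------------------------------------------
    if gene_class == "retroelement":
        n_cod = cfg.retro_cds_codons
    else:
        n_cod = _uniform(rng, cfg.cds_codons)
    sec_positions: list[int] = []
    if shared_cds is not None:
        cds = shared_cds
    else:
        internal = list(rng.choice(_SENSE_CODONS, n_cod))
        if gene_class == "selenoprotein":
            n_sec = min(_uniform(rng, cfg.n_sec_range), n_cod)
            for i in sorted(rng.choice(n_cod, n_sec, replace=False)):
                internal[int(i)] = "TGA"
                sec_positions.append(int(i) + 1)  # +1 for the ATG codon
        cds = "ATG" + "".join(internal) + "TAA"
    utr5 = _random_bases(rng, _uniform(rng, cfg.utr5_len))
    utr3 = _random_bases(rng, _uniform(rng, cfg.utr3_len))
    tx = utr5 + cds + utr3
    cds_t = (len(utr5), len(utr5) + len(cds))

    # --- exon structure ----------------------------------------------------
    m = cfg.min_exon_len
    if gene_class in ("true_intronless", "retroelement"):
        junctions: list[int] = []
    elif gene_class == "cds_intronless":
        junctions = []
        if cds_t[0] >= 2 * m:
            junctions.append(int(rng.integers(m, cds_t[0] - m + 1)))
        if len(tx) - cds_t[1] >= 2 * m:
            junctions.append(int(rng.integers(cds_t[1] + m, len(tx) - m + 1)))
        if not junctions:  # UTRs too short for an intron; force one in 3'UTR
            tx = tx + _random_bases(rng, 2 * m)
            junctions = [len(tx) - m]
    else:
        n_ex = _uniform(rng, cfg.exon_count)
        cuts = set()
        for _ in range(200):
            if len(cuts) >= n_ex - 1:
                break
            c = int(rng.integers(m, len(tx) - m + 1))
            if all(abs(c - o) >= m for o in cuts):
                cuts.add(c)
        junctions = sorted(cuts)

    # --- lay exons and introns onto the genome-forward body ----------------
    bounds = [0] + junctions + [len(tx)]
    exon_tx = list(zip(bounds[:-1], bounds[1:]))
    body_parts, exons_g, g = [], [], 0
    for i, (ta, tb) in enumerate(exon_tx):
        body_parts.append(tx[ta:tb])
        exons_g.append((g, g + (tb - ta)))
        g += tb - ta
        if i < len(exon_tx) - 1:
            ilen = _uniform(rng, cfg.intron_len)
            body_parts.append("GT" + _random_bases(rng, max(ilen - 4, 0)) + "AG")
            g += max(ilen, 4)
    body = "".join(body_parts)

    # genomic CDS spans = exon intervals clipped to the CDS transcript window
    cds_g = []
    for (ta, tb), (ga, _gb) in zip(exon_tx, exons_g):
        a, b = max(ta, cds_t[0]), min(tb, cds_t[1])
        if a < b:
            cds_g.append((ga + (a - ta), ga + (b - ta)))

    if strand == "-":
        B = len(body)
        body = revcomp(body)
        exons_g = sorted((B - b, B - a) for a, b in exons_g)
        cds_g = sorted((B - b, B - a) for a, b in cds_g)

    model = GeneModel(gid, cfg.chrom, strand, exons_g, cds_g, gene_class,
                      sec_positions, (len(cds) // 3) - 1)
    protein, premature, _ = translate_cds(model.cds_seq(body), sec_positions)
    if premature or len(protein) != model.expected_protein_length:
        raise AssertionError(f"{gid}: generated CDS does not translate cleanly")
    return DraftGene(model, body, tx, protein)


def generate_gene_models(config: GenerationConfig, seed: int) -> list[DraftGene]:
    """Generate the truth gene library (deterministic for a given seed)."""
    rng = substream(seed, "gene_models")
    drafts: list[DraftGene] = []
    idx = 0
    retro_cds: str | None = None
    for gene_class in (c for c in ("multi_exon", "true_intronless",
                                   "cds_intronless", "selenoprotein",
                                   "readthrough_parent", "retroelement")
                       if config.counts.get(c, 0) > 0):
        n = config.counts[gene_class]
        if gene_class == "readthrough_parent" and n % 2:
            raise ValueError("readthrough_parent count must be even (pairs)")
        pair_strand = "+"
        for j in range(n):
            idx += 1
            gid = f"g{idx:05d}"
            if gene_class == "readthrough_parent":
                if j % 2 == 0:
                    pair_strand = "-" if rng.random() < config.p_minus_strand else "+"
                strand = pair_strand
            else:
                strand = "-" if rng.random() < config.p_minus_strand else "+"
            shared = None
            if gene_class == "retroelement":
                if retro_cds is None:
                    internal = rng.choice(_SENSE_CODONS, config.retro_cds_codons)
                    retro_cds = "ATG" + "".join(internal) + "TAA"
                shared = retro_cds
            d = _build_gene(rng, config, gid, gene_class, strand, shared)
            drafts.append(d)
        if gene_class == "readthrough_parent":
            for a, b in zip(drafts[-n::2], drafts[-n + 1::2]):
                a.model.partner_id = b.model.gene_id
                b.model.partner_id = a.model.gene_id
    return drafts


def emit_genome(drafts: list[DraftGene], config: GenerationConfig,
                seed: int) -> TruthSet:
    """Place gene bodies on a chromosome with random intergenic spacers.

    Readthrough parent pairs stay adjacent on the same strand, upstream
    partner first. Raises a sizing error when a requested ``genome_length``
    cannot hold the gene set.
    """
    rng = substream(seed, "genome")
    pieces, models, pos = [], [], 0
    for i, d in enumerate(drafts):
        prev = drafts[i - 1] if i else None
        if (prev is not None and prev.model.gene_class == "readthrough_parent"
                and prev.model.partner_id == d.model.gene_id):
            gap = _uniform(rng, config.readthrough_gap)
        else:
            gap = _uniform(rng, config.intergenic_len)
        pieces.append(_random_bases(rng, gap))
        pos += gap
        pieces.append(d.body)
        models.append(d.model.shifted(pos))
        pos += len(d.body)
    pieces.append(_random_bases(rng, _uniform(rng, config.intergenic_len)))
    pos += len(pieces[-1])
    if config.genome_length is not None and pos > config.genome_length:
        raise ValueError(
            f"genes need {pos} bp but genome_length={config.genome_length}")
    genome = {config.chrom: "".join(pieces)}
    return TruthSet(genome, models,
                    {d.model.gene_id: d.transcript for d in drafts},
                    {d.model.gene_id: d.protein for d in drafts})


def simulate(config: GenerationConfig, seed: int) -> TruthSet:
    """Convenience: generate_gene_models + emit_genome under one seed."""
    return emit_genome(generate_gene_models(config, seed), config, seed)


# ---------------------------------------------------------------------------
# corruption


class _Lift:
    """Coordinate liftover through disjoint indel edits on one chromosome.

    Insertions of length L at p shift every coordinate >= p by +L; deletions
    of [p, p+L) shift coordinates >= p+L by -L and collapse interior
    coordinates onto p. Edits must be added in genomic order.
    """

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.lens: list[int] = []
        self.kinds: list[str] = []
        self.cum: list[int] = [0]   # cumulative delta after the first i edits

    def add(self, pos: int, length: int, kind: str) -> None:
        self.starts.append(pos)
        self.lens.append(length)
        self.kinds.append(kind)
        self.cum.append(self.cum[-1] + (length if kind == "ins" else -length))

    def __call__(self, pos: int) -> int:
        from bisect import bisect_right
        j = bisect_right(self.starts, pos)
        if j and self.kinds[j - 1] == "del" \
                and pos < self.starts[j - 1] + self.lens[j - 1]:
            return self.starts[j - 1] + self.cum[j - 1]
        return pos + self.cum[j]


def _gene_cds_cumlen(model: GeneModel) -> int:
    return sum(b - a for a, b in model.cds_spans)


def _trim_cds_to_codons(model: GeneModel, n_codons: int) -> list[tuple[int, int]]:
    """Genomic CDS spans covering the first ``n_codons`` codons (5'->3')."""
    keep = 3 * n_codons
    spans = model.cds_spans if model.strand == "+" else list(reversed(model.cds_spans))
    out = []
    for a, b in spans:
        if keep <= 0:
            break
        take = min(b - a, keep)
        if model.strand == "+":
            out.append((a, a + take))
        else:
            out.append((b - take, b))
        keep -= take
    return sorted(out)


def inject_build_errors(truth: TruthSet, profile: ErrorProfile,
                        build_id: str = "synthetic") -> tuple[GenomeBuild, ErrorLedger]:
    """Corrupt a truth genome per ``profile`` and ledger every corruption.

    With a zero profile this is the identity: sequences and annotation equal
    the truth. Error assignment is per gene and mutually exclusive — merged
    loci are drawn on disjoint adjacent gene pairs first, the remaining
    categorical errors gene by gene, and coding indels last as a homogeneous
    Poisson process over the CDS of still-uncorrupted genes with mean spacing
    ``indel_spacing_bp``.
    """
    models = sorted(truth.models, key=lambda m: (m.chrom, m.start))
    n_genes = len(models)
    if profile.p_merged_locus > 0 and n_genes < 2:
        raise ValueError("merged_locus injection needs at least 2 genes")

    rng_cat = substream(profile.seed, "categorical_errors")
    assigned: dict[str, str] = {m.gene_id: "none" for m in models}
    detail: dict[str, dict] = {m.gene_id: {} for m in models}

    # merged pairs: disjoint adjacent pairs, pair-level Bernoulli
    for i in range(0, n_genes - 1, 2):
        a, b = models[i], models[i + 1]
        if a.chrom != b.chrom:
            continue
        if rng_cat.random() < profile.p_merged_locus:
            assigned[a.gene_id] = assigned[b.gene_id] = "merged_locus"
            detail[a.gene_id]["partner"] = b.gene_id
            detail[b.gene_id]["partner"] = a.gene_id

    # per-gene categorical errors
    for m in models:
        if assigned[m.gene_id] != "none":
            continue
        if (m.gene_class == "selenoprotein"
                and rng_cat.random() < profile.p_premature_stop_seleno):
            assigned[m.gene_id] = "premature_stop"
            detail[m.gene_id]["sec_codon"] = m.sec_positions[0]
            continue
        u = rng_cat.random()
        if u < profile.p_missing_segment:
            assigned[m.gene_id] = "missing_segment"
        elif u < profile.p_missing_segment + profile.p_unannotated:
            assigned[m.gene_id] = "unannotated"
        elif u < (profile.p_missing_segment + profile.p_unannotated
                  + profile.p_split_locus):
            assigned[m.gene_id] = "split_locus"

    # coding indels over the CDS of untouched genes
    rng_ind = substream(profile.seed, "indels")
    indel_by_gene: dict[str, list[tuple[int, str, int]]] = {}
    if profile.indel_spacing_bp is not None:
        eligible = [m for m in models if assigned[m.gene_id] == "none"]
        lens = np.array([_gene_cds_cumlen(m) for m in eligible], dtype=np.int64)
        total = int(lens.sum())
        n_ev = int(rng_ind.poisson(total / profile.indel_spacing_bp))
        offs = np.sort(rng_ind.integers(0, total, n_ev))
        kinds = rng_ind.random(n_ev) < 0.5
        sizes = rng_ind.choice(profile.indel_lengths, n_ev)
        # thin events closer than 4 bp so sequence edits stay disjoint (the
        # coordinate liftover requires non-overlapping edits); the ledger
        # records exactly the surviving events
        keep, last = np.ones(n_ev, dtype=bool), -10
        for i, o in enumerate(offs):
            if o - last < 4:
                keep[i] = False
            else:
                last = o
        offs, kinds, sizes = offs[keep], kinds[keep], sizes[keep]
        n_ev = int(keep.sum())
        cum = np.concatenate([[0], np.cumsum(lens)])
        gene_idx = np.searchsorted(cum, offs, side="right") - 1
        for o, gi, isdel, sz in zip(offs, gene_idx, kinds, sizes):
            m = eligible[int(gi)]
            within = int(o - cum[gi])  # offset into this gene's genomic CDS bp
            gpos = None
            for a, b in m.cds_spans:
                if within < b - a:
                    gpos = a + within
                    break
                within -= b - a
            assigned[m.gene_id] = "indel"
            indel_by_gene.setdefault(m.gene_id, []).append(
                (int(gpos), "deletion" if isdel else "insertion", int(sz)))

    # ---- apply edits ------------------------------------------------------
    rng_fill = substream(profile.seed, "missing_fill")
    rng_ins = substream(profile.seed, "insert_bases")
    seqs = {c: s for c, s in truth.genome.items()}
    lifts = {c: _Lift() for c in seqs}
    # (chrom, pos, kind, payload); kinds: sub (same length), del, ins
    edits: dict[str, list[tuple[int, str, str | int]]] = {c: [] for c in seqs}
    appended: dict[str, list[tuple[str, str, GeneModel, int]]] = {c: [] for c in seqs}
    split_cut: dict[str, int] = {}

    for m in models:
        err = assigned[m.gene_id]
        if err == "missing_segment":
            edits[m.chrom].append(
                (m.start, "sub", _random_bases(rng_fill, m.end - m.start)))
            detail[m.gene_id]["span"] = [m.start, m.end]
        elif err == "split_locus":
            # cut so each relocated part keeps 35-65% of the exonic bases:
            # prefer an exon boundary in that window, else cut mid-exon
            tlen = m.transcript_length
            cum, best = 0, None
            for a, b in m.exons[:-1]:
                cum += b - a
                frac = cum / tlen
                if 0.35 <= frac <= 0.65 and (
                        best is None or abs(frac - 0.5) < abs(best[0] - 0.5)):
                    best = (frac, b)
            if best is not None:
                cut = best[1]
            else:  # genomic position holding half the exonic bases
                half, cum = tlen // 2, 0
                cut = m.exons[-1][1] - 1
                for a, b in m.exons:
                    if cum + (b - a) > half:
                        cut = a + (half - cum)
                        break
                    cum += b - a
            split_cut[m.gene_id] = cut
            moved = truth.genome[m.chrom][cut:m.end]
            edits[m.chrom].append((cut, "sub", _random_bases(rng_fill, len(moved))))
            appended[m.chrom].append(("split", m.gene_id, m, cut))
            detail[m.gene_id]["cut"] = cut

    for gid, events in indel_by_gene.items():
        m = next(x for x in models if x.gene_id == gid)
        for gpos, kind, sz in sorted(events):
            if profile.dialect == "n_fill":
                w = profile.n_fill_halfwidth
                a = max(gpos - w, 0)
                b = min(gpos + w + 1, len(seqs[m.chrom]))
                edits[m.chrom].append((a, "sub", "N" * (b - a)))
            elif kind == "deletion":
                edits[m.chrom].append((gpos, "del", sz))
            else:
                edits[m.chrom].append((gpos, "ins", _random_bases(rng_ins, sz)))
        detail[gid]["indels"] = [[p, k, s] for p, k, s in sorted(events)]

    for chrom in seqs:
        seq = seqs[chrom]
        parts, cursor = [], 0
        lift = lifts[chrom]
        for pos, kind, payload in sorted(edits[chrom], key=lambda e: e[0]):
            if kind == "sub" and pos < cursor:
                # overlapping same-length masks (adjacent n_fill windows):
                # clip the already-written prefix
                payload = payload[cursor - pos:]
                pos = cursor
                if not payload:
                    continue
            parts.append(seq[cursor:pos])
            if kind == "sub":
                parts.append(payload)            # same length: no shift
                cursor = pos + len(payload)
            elif kind == "del":
                lift.add(pos, int(payload), "del")
                cursor = pos + int(payload)
            else:
                parts.append(payload)
                lift.add(pos, len(payload), "ins")
                cursor = pos
        parts.append(seq[cursor:])
        seqs[chrom] = "".join(parts)

    # ---- annotation -------------------------------------------------------
    ann: list[AnnotationGene] = []
    merged_done: set[str] = set()
    for m in models:
        err = assigned[m.gene_id]
        lift = lifts[m.chrom]

        def lifted(ivs):
            out = [(lift(a), lift(b)) for a, b in ivs]
            return [(a, b) for a, b in out if a < b]

        if err in ("missing_segment", "unannotated"):
            continue
        if err == "merged_locus":
            if m.gene_id in merged_done:
                continue
            partner = next(x for x in models
                           if x.gene_id == detail[m.gene_id]["partner"])
            merged_done.update({m.gene_id, partner.gene_id})
            first, second = sorted([m, partner], key=lambda x: x.start)
            exons = lifted(sorted(first.exons + second.exons))
            ann.append(AnnotationGene(f"{first.gene_id}--{second.gene_id}",
                                      m.chrom, first.strand, exons,
                                      lifted(first.cds_spans)))
            continue
        if err == "premature_stop":
            cds = _trim_cds_to_codons(m, m.sec_positions[0] + 1)
            ann.append(AnnotationGene(m.gene_id, m.chrom, m.strand,
                                      lifted(m.exons), lifted(cds)))
            continue
        if err == "split_locus":
            cut = split_cut[m.gene_id]
            pre_ex = [(a, min(b, cut)) for a, b in m.exons if a < cut]
            pre_cds = [(a, min(b, cut)) for a, b in m.cds_spans if a < cut]
            ann.append(AnnotationGene(m.gene_id, m.chrom, m.strand,
                                      lifted(pre_ex), lifted(pre_cds)))
            continue  # suffix feature added with the appended blocks below
        ann.append(AnnotationGene(m.gene_id, m.chrom, m.strand,
                                  lifted(m.exons), lifted(m.cds_spans)))

    # appended relocation blocks + retroelement copies, after a spacer that
    # keeps them clearly off every original locus
    copy_positions: list[tuple[str, int]] = []
    for chrom in seqs:
        blocks = list(appended[chrom])
        n_copies = profile.retroelement_copies if chrom == models[0].chrom else 0
        if not blocks and not n_copies:
            continue
        seq = seqs[chrom]
        seq += _random_bases(rng_fill, 60000)
        retro = next((m for m in truth.models if m.gene_class == "retroelement"),
                     None)
        for kind, gid, m, cut in blocks:
            base = len(seq)
            seq += truth.genome[chrom][cut:m.end]
            delta = base - cut
            suf_ex = [(max(a, cut) + delta, b + delta) for a, b in m.exons if b > cut]
            suf_cds = [(max(a, cut) + delta, b + delta)
                       for a, b in m.cds_spans if b > cut]
            ann.append(AnnotationGene(f"{gid}_b", chrom, m.strand, suf_ex, suf_cds))
            detail[gid]["relocated_to"] = base
            seq += _random_bases(rng_fill, 5000)
        if n_copies:
            if retro is None:
                raise ValueError("retroelement_copies set but truth has no "
                                 "retroelement gene")
            cds = retro.cds_seq(truth.genome[retro.chrom])
            for i in range(n_copies):
                base = len(seq)
                seq += cds
                ann.append(AnnotationGene(f"{retro.gene_id}_copy{i + 1}", chrom,
                                          "+", [(base, base + len(cds))],
                                          [(base, base + len(cds))]))
                copy_positions.append((chrom, base))
            seq += _random_bases(rng_fill, 2000)
        seqs[chrom] = seq

    records = [LedgerRecord(m.gene_id, assigned[m.gene_id], detail[m.gene_id])
               for m in models]
    indel_positions = []
    for gid, events in indel_by_gene.items():
        m = next(x for x in models if x.gene_id == gid)
        for gpos, kind, sz in sorted(events):
            indel_positions.append((m.chrom, lifts[m.chrom](gpos)))
    ann.sort(key=lambda a: (a.chrom, a.start))
    build = GenomeBuild(build_id, seqs, ann, profile.dialect)
    return build, ErrorLedger(records, indel_positions, copy_positions)
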