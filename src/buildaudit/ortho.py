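"""Tiered 1:1 orthology, three-species Venn partition and asymmetry ratios.

Orthology is assigned in three tiers. Tier *protein*: reciprocal best local
alignment score, accepted only when the best score beats the runner-up by a
configurable margin (guards against equally scoring paralogs) and alignment
identity clears a floor. Genes left unpaired are retried on the RNA (tier
*rna*) and finally by conserved gene order (tier *synteny*): a candidate is
accepted when enough already-paired flanking genes on both sides support the
same co-linear location. Pig-specific paralog families get symbols
``<REF>L<rank>*`` with rank 1 the closest homolog.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_up
from .align import pairwise_nucleotide_align, pairwise_protein_align


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    tier: str           # protein | rna | synteny
    score: float
    reciprocal: bool = True


@dataclass(frozen=True)
class OrthoParams:
    t_protein_identity: float = 0.35
    t_rna_identity: float = 0.60
    margin: float = 0.05          # best must beat runner-up by this fraction
    synteny_flank: int = 4        # neighbours examined on each side
    synteny_support: int = 2      # paired, co-linear neighbours required per side


def _best_two(scores: dict[str, tuple[float, float]]):
    """(best_id, best_score, best_identity, runner_up_score)."""
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], kv[0]))
    bid, (bs, bi) = ranked[0]
    runner = ranked[1][1][0] if len(ranked) > 1 else None
    return bid, bs, bi, runner


def _rbh_tier(seqs_a, seqs_b, align_fn, t_identity, margin, tier, exclude_a,
              exclude_b):
    ids_a = [i for i in seqs_a if i not in exclude_a]
    ids_b = [i for i in seqs_b if i not in exclude_b]
    if not ids_a or not ids_b:
        return []
    cache: dict[tuple[str, str], tuple[float, float]] = {}
    for a in ids_a:
        for b in ids_b:
            r = align_fn(seqs_a[a], seqs_b[b])
            cache[(a, b)] = (r.score, r.identity or 0.0)
    pairs = []
    used_b: set[str] = set()
    for a in ids_a:
        bid, bs, bi, run = _best_two({b: cache[(a, b)] for b in ids_b})
        if bs <= 0 or bi < t_identity:
            continue
        if run is not None and bs < (1.0 + margin) * run:
            continue
        # reciprocal check with the same margin rule from b's side
        aid, as_, _ai, arun = _best_two({x: cache[(x, bid)] for x in ids_a})
        if aid != a or (arun is not None and as_ < (1.0 + margin) * arun):
            continue
        if bid in used_b:
            continue
        used_b.add(bid)
        pairs.append(OrthologPair(a, bid, tier, bs))
    return pairs


def _synteny_tier(unpaired_a, unpaired_b, order_a, order_b, paired_ab, params):
    """Pair leftover genes supported by flanking, already-paired orthologs."""
    pos_a = {g: (c, i) for c, genes in order_a.items() for i, g in enumerate(genes)}
    pos_b = {g: (c, i) for c, genes in order_b.items() for i, g in enumerate(genes)}
    pairs = []
    used_b: set[str] = set()
    for a in sorted(unpaired_a):
        if a not in pos_a:
            continue
        chrom, i = pos_a[a]
        genes = order_a[chrom]

        def side_partners(rng):
            out = []
            for j in rng:
                if 0 <= j < len(genes) and genes[j] in paired_ab:
                    out.append(paired_ab[genes[j]])
            return out

        f = params.synteny_flank
        left = side_partners(range(i - 1, i - 1 - f, -1))
        right = side_partners(range(i + 1, i + 1 + f))
        if len(left) < params.synteny_support or len(right) < params.synteny_support:
            continue
        lpos = [pos_b[g] for g in left if g in pos_b]
        rpos = [pos_b[g] for g in right if g in pos_b]
        if not lpos or not rpos:
            continue
        chroms = {c for c, _ in lpos} | {c for c, _ in rpos}
        if len(chroms) != 1:
            continue
        (bc,) = chroms
        lo = min(i for _, i in lpos + rpos)
        hi = max(i for _, i in lpos + rpos)
        cands = [g for g in order_b[bc][lo:hi + 1]
                 if g in unpaired_b and g not in used_b]
        if len(cands) != 1:
            continue
        used_b.add(cands[0])
        pairs.append(OrthologPair(a, cands[0], "synteny", 0.0))
    return pairs


def tiered_orthology(proteome_a: dict[str, str], proteome_b: dict[str, str],
                     rna_a: dict[str, str] | None = None,
                     rna_b: dict[str, str] | None = None,
                     gene_order_a: dict[str, list[str]] | None = None,
                     gene_order_b: dict[str, list[str]] | None = None,
                     params: OrthoParams = OrthoParams(),
                     exclude: set[str] = frozenset()) -> list[OrthologPair]:
    """1:1 orthology between two species; each gene appears in at most one pair.

    ``gene_order_*`` maps chromosome -> gene ids in genomic order and enables
    the synteny fallback. ``exclude`` removes hard-to-orthologize families
    (e.g. OR/TCR/BCR/MHC) from consideration entirely.
    """
    for name, d in (("a", proteome_a), ("b", proteome_b)):
        if len(d) != len(set(d)):
            raise ValueError(f"duplicate ids in proteome_{name}")
    pairs = _rbh_tier(proteome_a, proteome_b, pairwise_protein_align,
                      params.t_protein_identity, params.margin, "protein",
                      exclude, exclude)
    paired_a = {p.gene_a for p in pairs}
    paired_b = {p.gene_b for p in pairs}
    if rna_a and rna_b:
        rna_pairs = _rbh_tier(
            {k: v for k, v in rna_a.items() if k not in paired_a},
            {k: v for k, v in rna_b.items() if k not in paired_b},
            pairwise_nucleotide_align, params.t_rna_identity, params.margin,
            "rna", exclude, exclude)
        pairs += rna_pairs
        paired_a |= {p.gene_a for p in rna_pairs}
        paired_b |= {p.gene_b for p in rna_pairs}
    if gene_order_a and gene_order_b:
        paired_ab = {p.gene_a: p.gene_b for p in pairs}
        un_a = (set(proteome_a) - paired_a) - set(exclude)
        un_b = (set(proteome_b) - paired_b) - set(exclude)
        pairs += _synteny_tier(un_a, un_b, gene_order_a, gene_order_b,
                               paired_ab, params)
    return pairs


# ---------------------------------------------------------------------------
# Venn partition over {pig, mouse, human}


@dataclass
class VennPartition:
    """Counts for the 7 regions of the three-species presence Venn."""
    pmh: int = 0
    pm: int = 0
    ph: int = 0
    mh: int = 0
    p: int = 0
    m: int = 0
    h: int = 0

    def species_totals(self) -> dict[str, int]:
        return {"pig": self.pmh + self.pm + self.ph + self.p,
                "mouse": self.pmh + self.pm + self.mh + self.m,
                "human": self.pmh + self.ph + self.mh + self.h}


def _pair_map(pairs, label):
    fwd: dict[str, str] = {}
    for p in pairs:
        if p.gene_a in fwd and fwd[p.gene_a] != p.gene_b:
            raise ValueError(f"{label}: {p.gene_a} paired twice")
        fwd[p.gene_a] = p.gene_b
    if len(set(fwd.values())) != len(fwd):
        raise ValueError(f"{label}: a partner gene is paired twice")
    return fwd


def venn_partition(pairs_ph: list[OrthologPair], pairs_pm: list[OrthologPair],
                   pairs_mh: list[OrthologPair],
                   universes: dict[str, set[str]]) -> VennPartition:
    """Partition the three gene universes by orthology-mediated presence.

    A consistent triple (p,m,h) — p-m and p-h paired, with m-h paired to each
    other — counts once in PMH. Pairs not closing a triangle count in their
    two-species region; unpaired genes count in their species-specific region.
    """
    ph = _pair_map(pairs_ph, "pig-human")
    pm = _pair_map(pairs_pm, "pig-mouse")
    mh = _pair_map(pairs_mh, "mouse-human")
    v = VennPartition()
    in_triple_p, in_triple_m, in_triple_h = set(), set(), set()
    for p in universes["pig"]:
        m, h = pm.get(p), ph.get(p)
        if m is not None and h is not None and mh.get(m) == h:
            v.pmh += 1
            in_triple_p.add(p)
            in_triple_m.add(m)
            in_triple_h.add(h)
    used_p, used_m, used_h = set(in_triple_p), set(in_triple_m), set(in_triple_h)
    for p, m in pm.items():
        if p not in used_p and m not in used_m:
            v.pm += 1
            used_p.add(p)
            used_m.add(m)
    for p, h in ph.items():
        if p not in used_p and h not in used_h:
            v.ph += 1
            used_p.add(p)
            used_h.add(h)
    for m, h in mh.items():
        if m not in used_m and h not in used_h:
            v.mh += 1
            used_m.add(m)
            used_h.add(h)
    v.p = len(universes["pig"] - used_p)
    v.m = len(universes["mouse"] - used_m)
    v.h = len(universes["human"] - used_h)
    totals = v.species_totals()
    for sp in ("pig", "mouse", "human"):
        if totals[sp] != len(universes[sp]):
            raise AssertionError(f"Venn partition does not cover {sp} universe")
    return v


@dataclass
class AsymmetryRatios:
    ph_over_mh: float | None
    m_over_h: float | None
    m_over_p: float | None

    def reported(self) -> dict[str, float | None]:
        return {k: (round_half_up(x, 1) if x is not None else None)
                for k, x in (("ph_over_mh", self.ph_over_mh),
                             ("m_over_h", self.m_over_h),
                             ("m_over_p", self.m_over_p))}


def asymmetry_ratios(venn: VennPartition) -> AsymmetryRatios:
    """Missing-gene asymmetry: PH/MH, M/H and M/P (None when undefined)."""
    def ratio(a, b):
        return a / b if b > 0 else None
    return AsymmetryRatios(ratio(venn.ph, venn.mh), ratio(venn.m, venn.h),
                           ratio(venn.m, venn.p))


# ---------------------------------------------------------------------------
# paralog symbols


def assign_paralog_symbols(family: list[str], reference_symbol: str,
                           scores: dict[str, float] | None = None) -> list[str]:
    """Symbols ``<REF>L<rank>*`` for species-specific paralogs of a reference.

    ``family`` is ranked by similarity (closest first) unless ``scores`` is
    given, in which case members are ranked by descending score with ties
    broken by gene id. Returns symbols in the order of the ranked family.
    """
    if not family:
        raise ValueError("empty paralog family")
    ranked = list(family)
    if scores is not None:
        ranked.sort(key=lambda g: (-scores.get(g, float("-inf")), g))
    return [f"{reference_symbol}L{i}*" for i in range(1, len(ranked) + 1)]
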