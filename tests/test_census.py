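import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from buildaudit._util import revcomp
from buildaudit.buildqc import _CODON_TABLE
from buildaudit.census import (DomainArchitecture, PATTERNS,
                               ReadthroughEvidence, compare_architectures,
                               detect_intronless, domain_sharing_ratio,
                               orf_homology_search, readthrough_total,
                               score_readthrough, splice_conservation,
                               utr_conservation)
from buildaudit.models import AnnotationGene

# ---------------------------------------------------------------------------
# domain architectures


def arch(pid, *names):
    return DomainArchitecture(pid, [(n, 10 * i, 10 * i + 8)
                                    for i, n in enumerate(names)])


def test_architecture_order_enforced():
    with pytest.raises(ValueError):
        DomainArchitecture("p", [("A", 50, 60), ("B", 10, 20)])


def test_compare_architectures_patterns():
    # IL12B-style: one domain present in pig+human, absent in mouse
    d = compare_architectures(arch("p", "IG", "FN3"), arch("m", "IG"),
                              arch("h", "IG", "FN3"), "IL12B")
    assert ("IG", 0, "shared_all") in d.instances
    assert ("FN3", 0, "pig_human") in d.instances
    assert d.pattern_counts()["pig_human"] == 1


def test_compare_architectures_rank_matching():
    # PTPRJ-style: second occurrence of a repeated domain missing in pig
    d = compare_architectures(arch("p", "FN3"), arch("m", "FN3", "FN3"),
                              arch("h", "FN3", "FN3"))
    assert ("FN3", 0, "shared_all") in d.instances
    assert ("FN3", 1, "mouse_human") in d.instances


def test_compare_architectures_all_empty_raises():
    with pytest.raises(ValueError):
        compare_architectures(arch("p"), arch("m"), arch("h"))


@given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3),
                          st.integers(0, 3)), min_size=1, max_size=5))
def test_domain_pattern_partition_property(counts):
    """Every matched instance falls in exactly one pattern; counts sum up."""
    names = [f"D{i}" for i in range(len(counts))]
    total = sum(max(c) for c in counts)
    if total == 0:
        return
    def mk(pid, idx):
        doms = []
        for n, c in zip(names, counts):
            doms.extend([n] * c[idx])
        return arch(pid, *doms)
    d = compare_architectures(mk("p", 0), mk("m", 1), mk("h", 2))
    pc = d.pattern_counts()
    assert set(pc) == set(PATTERNS)
    assert sum(pc.values()) == len(d.instances) == total


def test_domain_sharing_ratio():
    d1 = compare_architectures(arch("p", "A", "B"), arch("m", "A"),
                               arch("h", "A", "B"))
    d2 = compare_architectures(arch("p", "C"), arch("m", "C", "D"),
                               arch("h", "C", "D"))
    assert domain_sharing_ratio([d1, d2]) == 1.0   # 1 pig_human / 1 mouse_human
    assert domain_sharing_ratio([d1]) is None      # no mouse_human instance


# ---------------------------------------------------------------------------
# intronless classes


def test_detect_intronless_classes():
    one = AnnotationGene("a", "c", "+", [(0, 500)], [(50, 450)])
    assert detect_intronless(one) == "true_intronless"
    cdsin = AnnotationGene("b", "c", "+", [(0, 100), (200, 900), (1000, 1100)],
                           [(250, 850)])
    assert detect_intronless(cdsin) == "cds_intronless"
    multi = AnnotationGene("c", "c", "+", [(0, 300), (400, 900)],
                           [(100, 300), (400, 600)])
    assert detect_intronless(multi) == "multi_exon"
    with pytest.raises(ValueError):
        detect_intronless(AnnotationGene("d", "c", "+", [(0, 100)], []))


# ---------------------------------------------------------------------------
# readthrough scoring


def expected_score(pred, n_other, pig):
    if not pred:
        return 0
    if not pig:
        return 1 if n_other == 0 else 2
    return 3 if n_other < 2 else 4


def test_score_readthrough_examples():
    assert score_readthrough(ReadthroughEvidence("x", False, 3, True)) == 0
    assert score_readthrough(ReadthroughEvidence("x", True, 0, False)) == 1
    assert score_readthrough(ReadthroughEvidence("x", True, 3, True)) == 4


def test_score_readthrough_total_function_grid():
    for pred, n_other, pig in itertools.product([False, True], range(7),
                                                [False, True]):
        got = score_readthrough(ReadthroughEvidence("x", pred, n_other, pig))
        assert got == expected_score(pred, n_other, pig)
        assert 0 <= got <= 4


def test_readthrough_evidence_validation():
    with pytest.raises(ValueError):
        ReadthroughEvidence("x", True, -1, False)


def test_readthrough_total():
    assert readthrough_total({1: 7, 2: 30, 3: 42, 4: 24}) == 103


# ---------------------------------------------------------------------------
# UTR and splice conservation


def test_utr_conservation_identical():
    rng = np.random.default_rng(3)
    mrna = "".join(rng.choice(list("ACGT"), 600))
    r = utr_conservation(mrna, (150, 450), mrna, (150, 450))
    assert r.utr5_identity == 1.0 and r.cds_identity == 1.0
    assert r.utr3_identity == 1.0
    assert not r.low5 and not r.low3


def test_utr_conservation_divergent_3utr():
    rng = np.random.default_rng(4)
    core = "".join(rng.choice(list("ACGT"), 450))
    a = core + "A" * 150
    b = core + "T" * 150
    r = utr_conservation(a, (150, 450), b, (150, 450))
    assert r.cds_identity == 1.0
    assert r.low3 and not r.low5
    assert r.utr3_identity < 0.60


def test_utr_conservation_empty_utr_undefined():
    r = utr_conservation("ATGAAATAA", (0, 9), "ATGAAATAA", (0, 9))
    assert r.utr5_identity is None and r.utr3_identity is None
    assert not r.low5 and not r.low3


def test_utr_conservation_bad_boundaries():
    with pytest.raises(ValueError):
        utr_conservation("ACGT", (0, 10), "ACGT", (0, 4))


def test_splice_conservation():
    assert splice_conservation(10, 10)[0] == 0
    assert splice_conservation(26, 20)[0] == 6       # MBD1-style delta
    delta, frac = splice_conservation(5, 5, {f"v{i}": i < 9 for i in range(10)})
    assert frac == 0.9
    with pytest.raises(ValueError):
        splice_conservation(0, 3)


# ---------------------------------------------------------------------------
# six-frame ORF homology scan


AA2CODON = {}
for codon, aa in sorted(_CODON_TABLE.items()):
    AA2CODON.setdefault(aa, codon)


def encode_protein(protein):
    return "".join(AA2CODON[a] for a in protein)


@pytest.fixture(scope="module")
def orf_query():
    rng = np.random.default_rng(11)
    return "".join(rng.choice(sorted(AA2CODON), 40))


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def test_orf_scan_single_intact_copy(orf_query):
    rng = np.random.default_rng(1)
    cds = encode_protein(orf_query)
    genome = {"c1": rand_dna(rng, 1501) + cds + rand_dna(rng, 1500)}
    hits = orf_homology_search(orf_query, genome)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.strand) == (1501, 1501 + len(cds), "+")
    assert h.intact and not h.pseudogenized and h.identity == 1.0


def test_orf_scan_internal_stop_pseudogenized(orf_query):
    rng = np.random.default_rng(2)
    cds = encode_protein(orf_query)
    broken = cds[:60] + "TAA" + cds[63:]
    genome = {"c1": rand_dna(rng, 1000) + broken + rand_dna(rng, 1000)}
    hits = orf_homology_search(orf_query, genome)
    assert len(hits) == 1
    assert not hits[0].intact and hits[0].pseudogenized


def test_orf_scan_reverse_strand(orf_query):
    rng = np.random.default_rng(3)
    cds = encode_protein(orf_query)
    genome = {"c1": rand_dna(rng, 900) + revcomp(cds) + rand_dna(rng, 900)}
    hits = orf_homology_search(orf_query, genome)
    assert len(hits) == 1 and hits[0].strand == "-" and hits[0].intact


def test_orf_scan_absent_query(orf_query):
    rng = np.random.default_rng(4)
    assert orf_homology_search(orf_query, {"c1": rand_dna(rng, 3000)}) == []


def test_orf_scan_short_query_rejected():
    with pytest.raises(ValueError):
        orf_homology_search("M" * 29, {"c1": "ACGT" * 100})
    with pytest.raises(ValueError):
        orf_homology_search("M" * 40, {"c1": ""})


def test_orf_scan_planted_copy_counting(orf_query):
    """Genome-scale copy census: 150 planted copies recovered exactly."""
    rng = np.random.default_rng(5)
    cds = encode_protein(orf_query)
    parts = []
    for _ in range(150):
        parts.append(rand_dna(rng, int(rng.integers(150, 260))))
        parts.append(cds)
    parts.append(rand_dna(rng, 300))
    hits = orf_homology_search(orf_query, {"c1": "".join(parts)})
    assert len(hits) == 150
    assert all(h.intact for h in hits)
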