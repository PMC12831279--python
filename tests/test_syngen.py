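import numpy as np
import pytest

from buildaudit.buildqc import translate_cds
from buildaudit.models import ErrorProfile
from buildaudit.syngen import _Lift, inject_build_errors, simulate

from conftest import small_config


# ---------------------------------------------------------------------------
# generation


def test_generation_deterministic():
    a = simulate(small_config(), 3)
    b = simulate(small_config(), 3)
    c = simulate(small_config(), 4)
    assert a.genome == b.genome
    assert a.transcripts == b.transcripts
    assert a.genome != c.genome


def test_generated_classes_and_counts(small_truth):
    classes = [m.gene_class for m in small_truth.models]
    assert classes.count("multi_exon") == 8
    assert classes.count("true_intronless") == 3
    assert classes.count("cds_intronless") == 3
    assert classes.count("selenoprotein") == 3
    assert classes.count("readthrough_parent") == 2


def test_transcripts_match_genome(small_truth):
    for m in small_truth.models:
        assert m.spliced(small_truth.genome[m.chrom]) == \
            small_truth.transcripts[m.gene_id]


def test_generated_cds_translates_cleanly(small_truth):
    for m in small_truth.models:
        cds = m.cds_seq(small_truth.genome[m.chrom])
        protein, premature, _ = translate_cds(cds, m.sec_positions)
        assert not premature, m.gene_id
        assert protein == small_truth.proteins[m.gene_id]
        assert len(protein) == m.expected_protein_length


def test_selenoproteins_have_internal_tga(small_truth):
    selenos = [m for m in small_truth.models if m.gene_class == "selenoprotein"]
    assert selenos
    for m in selenos:
        cds = m.cds_seq(small_truth.genome[m.chrom])
        for p in m.sec_positions:
            assert cds[3 * p:3 * p + 3] == "TGA"
        assert small_truth.proteins[m.gene_id].count("U") == len(m.sec_positions)


def test_readthrough_pairs_adjacent_same_strand(small_truth):
    parents = [m for m in small_truth.models
               if m.gene_class == "readthrough_parent"]
    a, b = sorted(parents, key=lambda m: m.start)
    assert a.partner_id == b.gene_id and b.partner_id == a.gene_id
    assert a.strand == b.strand
    assert 0 < b.start - a.end <= 800  # readthrough_gap range


def test_genome_length_cap():
    cfg = small_config(genome_length=100)
    with pytest.raises(ValueError):
        simulate(cfg, 1)


def test_readthrough_count_must_be_even():
    with pytest.raises(ValueError):
        simulate(small_config(counts={"readthrough_parent": 3}), 1)


# ---------------------------------------------------------------------------
# coordinate liftover


def test_lift_insertion_shifts_downstream():
    lift = _Lift()
    lift.add(100, 5, "ins")
    assert lift(99) == 99
    assert lift(100) == 105
    assert lift(200) == 205


def test_lift_deletion_collapses_interior():
    lift = _Lift()
    lift.add(100, 10, "del")
    assert lift(99) == 99
    assert lift(100) == 100    # collapses onto the cut
    assert lift(105) == 100
    assert lift(110) == 100
    assert lift(111) == 101


def test_lift_mixed_edits_in_order():
    lift = _Lift()
    lift.add(10, 2, "ins")
    lift.add(50, 3, "del")
    assert lift(5) == 5
    assert lift(20) == 22
    assert lift(51) == 52      # interior of the deletion
    assert lift(60) == 59


# ---------------------------------------------------------------------------
# corruption


def test_zero_profile_is_identity(small_truth):
    build, ledger = inject_build_errors(small_truth, ErrorProfile(seed=1))
    assert build.seqs == small_truth.genome
    assert all(r.error == "none" for r in ledger.records)
    assert len(build.genes) == len(small_truth.models)
    for g, m in zip(build.genes, sorted(small_truth.models,
                                        key=lambda m: (m.chrom, m.start))):
        assert g.gene_id == m.gene_id
        assert g.exons == m.exons and g.cds_spans == m.cds_spans


def test_ledger_conservation(small_truth):
    profile = ErrorProfile(seed=5, indel_spacing_bp=2000.0,
                           p_missing_segment=0.2, p_unannotated=0.2,
                           p_split_locus=0.2, p_merged_locus=0.3,
                           p_premature_stop_seleno=0.5)
    _build, ledger = inject_build_errors(small_truth, profile)
    # exactly one record per truth gene
    assert sorted(r.gene_id for r in ledger.records) == \
        sorted(m.gene_id for m in small_truth.models)
    assert sum(ledger.counts().values()) == len(small_truth.models)
    # indel positions ledgered one per injected event
    n_events = sum(len(r.detail.get("indels", [])) for r in ledger.records)
    assert len(ledger.indel_positions) == n_events


def test_missing_segment_replaces_sequence(small_truth):
    profile = ErrorProfile(seed=2, p_missing_segment=1.0)
    build, ledger = inject_build_errors(small_truth, profile)
    assert all(r.error == "missing_segment" for r in ledger.records)
    assert build.genes == []  # nothing annotated
    for m in small_truth.models:
        assert build.seqs[m.chrom][m.start:m.end] != \
            small_truth.genome[m.chrom][m.start:m.end]


def test_unannotated_keeps_sequence(small_truth):
    profile = ErrorProfile(seed=2, p_unannotated=1.0)
    build, ledger = inject_build_errors(small_truth, profile)
    assert build.seqs == small_truth.genome
    assert build.genes == []
    assert all(r.error == "unannotated" for r in ledger.records)


def test_split_locus_structure(small_truth):
    profile = ErrorProfile(seed=2, p_split_locus=1.0)
    build, ledger = inject_build_errors(small_truth, profile)
    assert all(r.error == "split_locus" for r in ledger.records)
    ids = {g.gene_id for g in build.genes}
    for m in small_truth.models:
        assert m.gene_id in ids and f"{m.gene_id}_b" in ids
        cut = ledger.by_gene()[m.gene_id].detail["cut"]
        # each relocated part keeps 35-65% of the exonic bases
        kept = sum(min(b, cut) - a for a, b in m.exons if a < cut)
        assert 0.35 <= kept / m.transcript_length <= 0.65


def test_merged_locus_structure(small_truth):
    profile = ErrorProfile(seed=2, p_merged_locus=1.0)
    build, ledger = inject_build_errors(small_truth, profile)
    merged = [r for r in ledger.records if r.error == "merged_locus"]
    assert len(merged) >= 2 and len(merged) % 2 == 0
    names = {g.gene_id for g in build.genes}
    done = set()
    for r in merged:
        if r.gene_id in done:
            continue
        partner = r.detail["partner"]
        done.update({r.gene_id, partner})
        a, b = sorted([r.gene_id, partner])
        assert f"{a}--{b}" in names or f"{b}--{a}" in names


def test_premature_stop_trims_annotated_cds(small_truth):
    profile = ErrorProfile(seed=2, p_premature_stop_seleno=1.0)
    build, ledger = inject_build_errors(small_truth, profile)
    by_gene = ledger.by_gene()
    ann = {g.gene_id: g for g in build.genes}
    for m in small_truth.models:
        if m.gene_class != "selenoprotein":
            assert by_gene[m.gene_id].error == "none"
            continue
        assert by_gene[m.gene_id].error == "premature_stop"
        g = ann[m.gene_id]
        want = 3 * (m.sec_positions[0] + 1)
        assert sum(b - a for a, b in g.cds_spans) == want


def test_truncate_dialect_changes_genome_length(small_truth):
    profile = ErrorProfile(seed=9, indel_spacing_bp=1500.0, dialect="truncate")
    build, ledger = inject_build_errors(small_truth, profile)
    delta = 0
    for r in ledger.records:
        for _pos, kind, size in r.detail.get("indels", []):
            delta += size if kind == "insertion" else -size
    assert len(build.seqs["chr1"]) == len(small_truth.genome["chr1"]) + delta


def test_n_fill_dialect_masks_without_shifting(small_truth):
    profile = ErrorProfile(seed=9, indel_spacing_bp=1500.0, dialect="n_fill")
    build, ledger = inject_build_errors(small_truth, profile)
    assert len(build.seqs["chr1"]) == len(small_truth.genome["chr1"])
    assert len(ledger.indel_positions) > 0
    for chrom, pos in ledger.indel_positions:
        assert build.seqs[chrom][pos] == "N"
    # annotation coordinates are untouched in n_fill
    truth_by_id = {m.gene_id: m for m in small_truth.models}
    for g in build.genes:
        assert g.exons == truth_by_id[g.gene_id].exons


def test_indel_count_matches_poisson_expectation(small_truth):
    # mean over seeds close to total CDS length / spacing
    spacing = 800.0
    total_cds = sum(sum(b - a for a, b in m.cds_spans)
                    for m in small_truth.models)
    counts = []
    for seed in range(20):
        _b, led = inject_build_errors(
            small_truth, ErrorProfile(seed=seed, indel_spacing_bp=spacing))
        counts.append(len(led.indel_positions))
    mean = np.mean(counts)
    expect = total_cds / spacing
    assert abs(mean - expect) < 4 * np.sqrt(expect / len(counts))


def test_retroelement_copies_planted():
    cfg = small_config(counts={"multi_exon": 3, "retroelement": 1})
    truth = simulate(cfg, 5)
    profile = ErrorProfile(seed=1, retroelement_copies=4)
    build, ledger = inject_build_errors(truth, profile)
    assert len(ledger.planted_copies) == 4
    retro = next(m for m in truth.models if m.gene_class == "retroelement")
    cds = retro.cds_seq(truth.genome[retro.chrom])
    for chrom, pos in ledger.planted_copies:
        assert build.seqs[chrom][pos:pos + len(cds)] == cds
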