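"""Reusable injection-recovery experiments.

These drive the full pipeline — generate a truth genome, corrupt it, map the
truth transcripts back to the corrupted build with the ledger-blind aligner,
and measure recovery. They are used both by the test suite and by the
repository's acceptance script.

The indel experiment uses "coding panels": long single-exon genes whose CDS
supplies the surveyed coding span, so the Poisson indel process and its
rate estimate are exercised at scale without per-exon overhead. The
classification experiment uses a realistic mixed gene set and calibrates the
corruption profile so the expected error-free fraction equals a requested
target exactly (solving for the residual indel spacing against the generated
CDS lengths).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import KmerIndex, detect_indels, map_transcript
from .buildqc import (BuildSummary, ErrorCall, IndelEstimate, audit_build,
                      estimate_indel_rate, summarize_build)
from .models import ErrorLedger, ErrorProfile
from .syngen import GenerationConfig, TruthSet, inject_build_errors, simulate


def coding_panel_config(n_genes: int, codons_per_gene: int) -> GenerationConfig:
    """Single-exon 'coding panel' genes supplying a large surveyed CDS span."""
    return GenerationConfig(
        counts={"true_intronless": n_genes},
        cds_codons=(codons_per_gene, codons_per_gene),
        utr5_len=(100, 100), utr3_len=(100, 100),
        intergenic_len=(2000, 4000), p_minus_strand=0.3,
    )


@dataclass
class IndelRecovery:
    injected: int
    detected: int
    covered_bp: int
    estimate: IndelEstimate

    @property
    def ci_covers(self) -> bool:
        lo, hi = self.estimate.ci95
        return lo <= self.spacing <= hi

    spacing: float = 12465.0


def detect_build_indels(truth: TruthSet, build) -> int:
    """Count coding indel events by mapping every truth transcript."""
    index = KmerIndex(build.seqs)
    n = 0
    for m in truth.models:
        alns = map_transcript(truth.transcripts[m.gene_id], index,
                              transcript_id=m.gene_id)
        if alns:
            n += len(detect_indels(alns[0], m.cds_tx_interval()))
    return n


def indel_rate_experiment(truth: TruthSet, seed: int,
                          spacing: float = 12465.0) -> IndelRecovery:
    """Inject Poisson coding indels at ``spacing`` and recover the rate."""
    covered = sum(sum(b - a for a, b in m.cds_spans) for m in truth.models)
    profile = ErrorProfile(seed=seed, indel_spacing_bp=spacing,
                           dialect="truncate")
    build, ledger = inject_build_errors(truth, profile)
    detected = detect_build_indels(truth, build)
    est = estimate_indel_rate(detected, covered)
    return IndelRecovery(len(ledger.indel_positions), detected, covered, est,
                         spacing=spacing)


def indel_ci_coverage(seeds, n_genes: int, codons_per_gene: int,
                      spacing: float = 12465.0,
                      truth_seed: int = 1) -> tuple[int, list[IndelRecovery]]:
    """How many injection seeds give a 95% CI covering the true spacing.

    The truth genome is generated once; each seed draws an independent indel
    realization and runs the full detect-and-estimate pipeline.
    """
    truth = simulate(coding_panel_config(n_genes, codons_per_gene), truth_seed)
    runs = [indel_rate_experiment(truth, s, spacing) for s in seeds]
    return sum(r.ci_covers for r in runs), runs


# ---------------------------------------------------------------------------
# end-to-end classification recovery


def mixed_gene_config(n_genes: int, seleno_fraction: float = 0.02
                      ) -> GenerationConfig:
    n_sel = int(round(n_genes * seleno_fraction))
    n_rest = n_genes - n_sel
    return GenerationConfig(
        counts={"multi_exon": int(n_rest * 0.8),
                "true_intronless": int(n_rest * 0.1),
                "cds_intronless": n_rest - int(n_rest * 0.8) - int(n_rest * 0.1),
                "selenoprotein": n_sel},
        cds_codons=(100, 400), exon_count=(2, 8),
        intron_len=(120, 1500), intergenic_len=(800, 2000),
    )


def calibrated_profile(truth: TruthSet, target_correct: float, seed: int,
                       p_missing: float = 0.06, p_unannotated: float = 0.06,
                       p_split: float = 0.06, p_merged: float = 0.05,
                       p_premature_seleno: float = 0.4) -> ErrorProfile:
    """Corruption profile whose expected error-free fraction is the target.

    Categorical rates are fixed; the residual coding-indel spacing is solved
    by bisection against the generated CDS lengths so that

        mean_i  P(no merge) * P(no categorical_i) * exp(-L_i / s)  =  target.
    """
    models = sorted(truth.models, key=lambda m: (m.chrom, m.start))
    L = np.array([sum(b - a for a, b in m.cds_spans) for m in models],
                 dtype=float)
    seleno = np.array([m.gene_class == "selenoprotein" for m in models])
    p_cat = np.where(seleno,
                     p_premature_seleno
                     + (1 - p_premature_seleno) * (p_missing + p_unannotated + p_split),
                     p_missing + p_unannotated + p_split)
    pre = (1.0 - p_merged) * (1.0 - p_cat)
    if pre.mean() < target_correct:
        raise ValueError("categorical rates alone exceed the error budget")

    def expected(s):
        return float(np.mean(pre * np.exp(-L / s)))

    lo, hi = 10.0, 1e9
    for _ in range(200):
        mid = (lo * hi) ** 0.5
        if expected(mid) < target_correct:
            lo = mid
        else:
            hi = mid
    return ErrorProfile(seed=seed, indel_spacing_bp=(lo * hi) ** 0.5,
                        p_missing_segment=p_missing, p_unannotated=p_unannotated,
                        p_split_locus=p_split, p_merged_locus=p_merged,
                        p_premature_stop_seleno=p_premature_seleno,
                        dialect="truncate")


#: mapping from injected error class to the category the classifier must call
EXPECTED_CATEGORY = {
    "none": "correct",
    "indel": "error_in_locus",
    "premature_stop": "error_in_locus",
    "missing_segment": "sequence_not_present",
    "unannotated": "not_annotated",
    "split_locus": "split_multiple_loci",
    "merged_locus": "multiple_genes_one_locus",
}


@dataclass
class ClassificationRecovery:
    summary: BuildSummary
    calls: list[ErrorCall]
    ledger: ErrorLedger
    injected_correct_fraction: float

    def per_class_recall(self) -> dict[str, tuple[int, int]]:
        by_gene = self.ledger.by_gene()
        out: dict[str, list[int]] = {}
        for c in self.calls:
            inj = by_gene[c.gene_id].error
            hit, tot = out.setdefault(inj, [0, 0])
            out[inj][1] += 1
            if c.category == EXPECTED_CATEGORY[inj]:
                out[inj][0] += 1
        return {k: (v[0], v[1]) for k, v in out.items()}


def classification_experiment(seed: int, n_genes: int = 2000,
                              target_correct: float = 0.589
                              ) -> ClassificationRecovery:
    """Generate, corrupt at a calibrated error-free fraction, audit, compare."""
    truth = simulate(mixed_gene_config(n_genes), seed)
    profile = calibrated_profile(truth, target_correct, seed)
    build, ledger = inject_build_errors(truth, profile)
    calls = audit_build(truth, build)
    injected_correct = sum(r.error == "none" for r in ledger.records) / n_genes
    return ClassificationRecovery(summarize_build(calls), calls, ledger,
                                  injected_correct)
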