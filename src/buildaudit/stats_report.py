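"""Over-representation statistics and consolidated report rendering.

The enrichment statistic is the classic gene-set over-representation test:
for a query of n genes from a background of N, of which K carry a term and k
of the query do, fold enrichment is (k/n)/(K/N) and the p-value is the
hypergeometric upper tail P(X >= k) (one-sided, enrichment only), corrected
per collection by Benjamini-Hochberg.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import round_half_up


@dataclass
class EnrichmentResult:
    term_id: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    q: float


def over_representation(query: set[str], background: set[str],
                        collection: dict[str, set[str]]) -> list[EnrichmentResult]:
    """Test every term of a collection for enrichment in a query gene set.

    Terms are restricted to the background before testing; q-values are BH
    over all tested terms of this collection. Results sorted by p.
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n, N = len(query), len(background)
    rows = []
    for term_id in sorted(collection):
        members = collection[term_id] & background
        if not members:
            continue
        K = len(members)
        k = len(query & members)
        fold = (k / n) / (K / N) if n else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, fold, min(p, 1.0)))
    if not rows:
        return []
    q = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    out = [EnrichmentResult(t, k, n, K, N, fold, p, float(qi))
           for (t, k, K, fold, p), qi in zip(rows, q)]
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (term, description, genes...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out


# ---------------------------------------------------------------------------
# report rendering


def _fmt_p(p: float) -> str:
    return f"{p:.1E}"


def render_report(build_summaries=None, venn=None, ratios=None,
                  enrichments=None, census_lines=None) -> str:
    """Deterministic plain-text summation of an audit run.

    Missing sections are marked absent rather than dropped, so a report's
    shape is stable across runs.
    """
    lines = ["# buildaudit summation of results", ""]
    lines.append("## Build error classification")
    if build_summaries:
        for s in build_summaries:
            lines.append(f"build {s.build_id}: {s.total} genes, "
                         f"{s.percent_correct}% correct")
            for cat, cnt in sorted(s.counts.items()):
                lines.append(f"  {cat}\t{cnt}")
    else:
        lines.append("(absent)")
    lines.append("")
    lines.append("## Three-species orthology Venn")
    if venn is not None:
        for region in ("pmh", "pm", "ph", "mh", "p", "m", "h"):
            lines.append(f"  {region.upper()}\t{getattr(venn, region)}")
    else:
        lines.append("(absent)")
    lines.append("")
    lines.append("## Asymmetry ratios")
    if ratios is not None:
        for k, v in ratios.reported().items():
            lines.append(f"  {k}\t{'undefined' if v is None else v}")
    else:
        lines.append("(absent)")
    lines.append("")
    lines.append("## Enrichment")
    if enrichments:
        for r in enrichments:
            lines.append(f"  {r.term_id}\t{round_half_up(r.fold, 1)} fold\t"
                         f"p={_fmt_p(r.p)}\tq={_fmt_p(r.q)}")
    else:
        lines.append("(absent)")
    lines.append("")
    lines.append("## Census")
    if census_lines:
        lines.extend(f"  {ln}" for ln in census_lines)
    else:
        lines.append("(absent)")
    lines.append("")
    return "\n".join(lines)
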