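"""Gene-list overlap statistics over a shared background.

Cross-species comparisons ask whether two differentially-expressed gene
lists (projected into a common orthologue space) share more members than
expected by chance.  Each comparison is a 2x2 contingency table over the
background of orthologues present in both studies, tested with a two-sided
Fisher exact test and Bonferroni-corrected for the size of the comparison
family (supplied per batch, not inferred).  Also provided: re-testing after
excluding a gene set (e.g. diapause-associated genes), pipeline-concordance
proportions between DE callers, and the exact binomial test used to score
mRNA-seq vs qRT-PCR congruence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats


@dataclass
class OverlapTest:
    list_a: frozenset
    list_b: frozenset
    background: frozenset
    table: list[list[int]]
    odds_ratio: float
    p: float
    p_adjusted: float
    family_size: int


def overlap_test(
    list_a: Iterable[str],
    list_b: Iterable[str],
    background: Iterable[str],
    family_size: int = 1,
) -> OverlapTest:
    """Fisher exact test of overlap between two gene lists on a background.

    Table: [[|a&b|, |a-b|], [|b-a|, |bg - (a|b)|]]; cells sum to the
    background size.  ``p_adjusted`` is the Bonferroni correction
    min(1, p * family_size).
    """
    a, b, bg = set(list_a), set(list_b), set(background)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if not bg:
        raise ValueError("empty background")
    for name, lst in (("list_a", a), ("list_b", b)):
        outside = lst - bg
        if outside:
            raise ValueError(
                f"{name} contains ids outside the background: {sorted(outside)[:5]}"
            )
    table = [
        [len(a & b), len(a - b)],
        [len(b - a), len(bg - (a | b))],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return OverlapTest(
        list_a=frozenset(a),
        list_b=frozenset(b),
        background=frozenset(bg),
        table=table,
        odds_ratio=float(odds),
        p=float(p),
        p_adjusted=min(1.0, float(p) * family_size),
        family_size=family_size,
    )


def exclude_and_retest(test: OverlapTest, exclusion: Iterable[str]) -> OverlapTest:
    """Remove an exclusion set from both lists and the background, re-test.

    Used to check robustness of a cross-species overlap to a confounding
    gene set (e.g. genes associated with queen diapause).
    """
    excl = set(exclusion)
    bg = set(test.background) - excl
    if not bg:
        raise ValueError("exclusion removes the entire background")
    return overlap_test(
        set(test.list_a) - excl,
        set(test.list_b) - excl,
        bg,
        family_size=test.family_size,
    )


def pipeline_concordance(
    calls_x: Iterable[str], calls_y: Iterable[str]
) -> tuple[float | None, float | None]:
    """Mutual recovery proportions between two DE-caller outputs.

    Returns (|x&y|/|y|, |x&y|/|x|): the fraction of y's calls recovered by
    x, and vice versa.  ``None`` where the denominator list is empty.
    """
    x, y = set(calls_x), set(calls_y)
    inter = len(x & y)
    return (
        inter / len(y) if y else None,
        inter / len(x) if x else None,
    )


@dataclass
class CongruenceRecord:
    """Agreement of one gene x stage comparison across the two platforms."""

    gene_id: str
    stage: str
    seq_result: str  # sig_up_Q | sig_up_W | not_sig
    pcr_result: str
    match: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        valid = {"sig_up_Q", "sig_up_W", "not_sig", "missing"}
        if self.seq_result not in valid or self.pcr_result not in valid:
            raise ValueError("results must be sig_up_Q, sig_up_W, not_sig or missing")
        self.missing = "missing" in (self.seq_result, self.pcr_result)
        self.match = (not self.missing) and self.seq_result == self.pcr_result


def congruence_binomial(
    records: Iterable[CongruenceRecord],
    alternative: str = "greater",
) -> tuple[int, int, float]:
    """Exact binomial test of platform agreement against chance (0.5).

    Counts matches among non-missing records and tests the proportion of
    matches vs mismatches.  One-sided ("greater") by default; sidedness is
    a flag.  Returns (n_match, n_total, p).
    """
    recs = [r for r in records if not r.missing]
    n_total = len(recs)
    if n_total < 1:
        raise ValueError("no scorable records")
    n_match = sum(r.match for r in recs)
    p = stats.binomtest(n_match, n_total, p=0.5, alternative=alternative).pvalue
    return n_match, n_total, float(p)
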