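"""Annotation classes, taxonomic novelty, coding status and novelty enrichment.

Transcripts fall into four classes: annotated (maps to a gene annotation),
unannotated-but-not-novel (homology to other insect genera), novel
non-coding and novel coding.  A transcript is novel (taxonomically
restricted) when its homology hits at E <= 1e-5, across both nucleotide and
protein searches, are confined to the genus Bombus -- including the case of
no hits at all, which satisfies the no-other-genus condition and is flagged
as "no-hit novel" for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

EVALUE_THRESHOLD = 1e-5
FOCAL_GENUS = "Bombus"
MIN_ORF_CODONS = 100

CLASSES = ("annotated", "unannotated_not_novel", "novel_noncoding", "novel_coding")


@dataclass(frozen=True)
class Hit:
    """A single homology search hit (one row of an outfmt-6-style table)."""

    subject: str
    genus: str
    evalue: float
    search_type: str = "prot"  # "nucl" | "prot"

    def __post_init__(self) -> None:
        ev = float(self.evalue)
        if not np.isfinite(ev) or ev < 0:
            raise ValueError(f"malformed E-value for hit {self.subject!r}: {self.evalue!r}")


@dataclass
class FeatureAnnotation:
    feature_id: str
    annotation_class: str
    is_novel: bool
    coding: bool
    best_hits: list[Hit] = field(default_factory=list)
    no_hit_novel: bool = False

    def __post_init__(self) -> None:
        if self.annotation_class not in CLASSES:
            raise ValueError(f"unknown class {self.annotation_class!r}")


def classify_feature(
    feature_id: str,
    gff_annotated: bool,
    hits: list[Hit],
    coding: bool,
    evalue_threshold: float = EVALUE_THRESHOLD,
    focal_genus: str = FOCAL_GENUS,
) -> FeatureAnnotation:
    """Assign one of the four annotation classes to a feature.

    Precedence: a feature mapping to an existing gene annotation is
    ``annotated`` regardless of hits.  Otherwise a significant hit
    (E <= threshold) to any genus other than the focal one makes it
    ``unannotated_not_novel``; else it is novel, split into coding /
    non-coding by the ``coding`` flag.
    """
    for h in hits:
        float(h.evalue)  # Hit validates; defensive for plain tuples
    if gff_annotated:
        cls, novel = "annotated", False
    else:
        sig = [h for h in hits if h.evalue <= evalue_threshold]
        other = [h for h in sig if h.genus != focal_genus]
        if other:
            cls, novel = "unannotated_not_novel", False
        else:
            cls = "novel_coding" if coding else "novel_noncoding"
            novel = True
    return FeatureAnnotation(
        feature_id=feature_id,
        annotation_class=cls,
        is_novel=novel,
        coding=coding,
        best_hits=sorted(hits, key=lambda h: h.evalue)[:5],
        no_hit_novel=novel and not hits,
    )


def classify_table(
    hit_table: pd.DataFrame,
    annotated_ids: set[str],
    coding_flags: dict[str, bool],
    feature_ids: list[str] | None = None,
    evalue_threshold: float = EVALUE_THRESHOLD,
    focal_genus: str = FOCAL_GENUS,
) -> pd.DataFrame:
    """Classify every feature of a hit table (columns qseqid, subject_genus, evalue).

    ``feature_ids`` extends the universe to features with no hits at all.
    Returns a DataFrame indexed by feature_id with columns annotation_class,
    is_novel, coding.
    """
    universe: list[str] = list(feature_ids) if feature_ids is not None else sorted(
        set(hit_table["qseqid"])
    )
    ev = pd.to_numeric(hit_table["evalue"], errors="raise")
    if (ev < 0).any() or not np.isfinite(ev).all():
        raise ValueError("malformed E-value in hit table")
    sig = hit_table[ev <= evalue_threshold]
    has_other = set(sig.loc[sig["subject_genus"] != focal_genus, "qseqid"])
    rows = []
    for f in universe:
        coding = bool(coding_flags.get(f, False))
        if f in annotated_ids:
            cls, novel = "annotated", False
        elif f in has_other:
            cls, novel = "unannotated_not_novel", False
        else:
            cls = "novel_coding" if coding else "novel_noncoding"
            novel = True
        rows.append({"feature_id": f, "annotation_class": cls, "is_novel": novel, "coding": coding})
    return pd.DataFrame(rows).set_index("feature_id")


def coding_status(sequence: str, min_codons: int = MIN_ORF_CODONS) -> bool:
    """Predict coding status from the longest open reading frame.

    A sequence is called coding when some frame (three frames, forward and
    reverse strand) contains an ATG...stop ORF of at least ``min_codons``
    codons (stop codon excluded).  This is a deliberately simple, documented
    stand-in for a full coding-potential predictor; the codon threshold is
    configurable.  Alphabet must be ACGTN.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides in sequence: {sorted(bad)}")
    stops = {"TAA", "TAG", "TGA"}
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            codons = [strand_seq[i: i + 3] for i in range(frame, len(strand_seq) - 2, 3)]
            start = None
            for i, codon in enumerate(codons):
                if start is None:
                    if codon == "ATG":
                        start = i
                elif codon in stops:
                    if i - start >= min_codons:
                        return True
                    start = None
    return False


# -- novelty enrichment --------------------------------------------------------


@dataclass
class NoveltyEnrichment:
    stage: str
    table: list[list[int]]
    p: float | None
    testable: bool
    note: str = ""


def novel_proportion_test(
    novel_a: int,
    total_a: int,
    novel_b: int,
    total_b: int,
    columns: str = "total",
) -> tuple[list[list[int]], float]:
    """Two-sided Fisher exact test comparing novel-gene proportions.

    ``columns="total"`` builds the 2x2 table as [[novel_a, total_a],
    [novel_b, total_b]], the construction under which the published
    late-instar and mid-instar comparisons evaluate to 0.042 and 0.813;
    ``columns="rest"`` uses the textbook [[novel, not-novel], ...] table.
    Both conventions are exposed; the default reproduces the published
    analysis.
    """
    if columns == "total":
        table = [[novel_a, total_a], [novel_b, total_b]]
    elif columns == "rest":
        table = [[novel_a, total_a - novel_a], [novel_b, total_b - novel_b]]
    else:
        raise ValueError("columns must be 'total' or 'rest'")
    if min(novel_a, novel_b) < 0 or novel_a > total_a or novel_b > total_b:
        raise ValueError("novel counts must lie within totals")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def novelty_enrichment(
    hdegs_by_phenotype: dict[str, set[str]],
    annotations: pd.DataFrame,
    columns: str = "total",
) -> list[NoveltyEnrichment]:
    """Per-stage Fisher tests on novel-gene proportions of W-up vs Q-up HDEGs.

    ``hdegs_by_phenotype`` maps two-letter phenotype labels (MQ, MW, ...) to
    HDEG feature sets; ``annotations`` is the classify_table output.  Stages
    where either caste has no HDEGs are reported untestable (as for the
    early stage of the study design) rather than given p = 1.
    """
    is_novel = annotations["is_novel"]
    out = []
    for stage, (w_label, q_label) in {
        "early": ("EW", "EQ"),
        "mid": ("MW", "MQ"),
        "late": ("LW", "LQ"),
    }.items():
        w = hdegs_by_phenotype.get(w_label, set())
        q = hdegs_by_phenotype.get(q_label, set())
        if not w or not q:
            out.append(
                NoveltyEnrichment(stage=stage, table=[[0, 0], [0, 0]], p=None,
                                  testable=False, note="no HDEGs on one or both sides")
            )
            continue
        novel_w = sum(bool(is_novel.get(f, False)) for f in w)
        novel_q = sum(bool(is_novel.get(f, False)) for f in q)
        table, p = novel_proportion_test(novel_w, len(w), novel_q, len(q), columns=columns)
        out.append(NoveltyEnrichment(stage=stage, table=table, p=p, testable=True))
    return out
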