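"""Synthetic study-design generator for end-to-end testing without downloads.

The generator emulates the structure of a two-caste, three-stage larval
expression study: six phenotype groups (EQ, EW, MQ, MW, LQ, LW) with 2-4
biological replicates each, strong stage-wise expression structure with
much weaker caste-wise differences, negative-binomial count noise,
library-depth variation, a configurable set of true caste-DE features per
stage, a mix of annotated / unannotated / taxonomically-restricted (novel)
transcripts, a two-species orthologue table with a tunable shared-DE rate,
and qRT-PCR Cq plates with reference genes of graded stability.

All generators are deterministic under a fixed seed and record their
ground truth (:class:`~casteseq.containers.SimTruth`) so downstream callers
can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SimTruth, phenotype_label

SPECIES_A = "Bterrestris"
SPECIES_B = "Amellifera"


@dataclass(frozen=True)
class DEBlock:
    """A block of true caste-DE features within one stage."""

    n: int
    direction: str  # "Q" | "W"
    log2_fold: float = 4.0
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.direction not in ("Q", "W"):
            raise ValueError("direction must be 'Q' or 'W'")
        if not np.isfinite(self.log2_fold):
            raise ValueError("effect size must be finite")
        if self.n < 0 or self.dispersion < 0:
            raise ValueError("n and dispersion must be non-negative")


#: Default replicate structure: the six phenotypes with the replicate counts
#: retained after QC in the emulated design (17 libraries).
DEFAULT_PHENOTYPES = (
    ("early", "Q", 3),
    ("early", "W", 3),
    ("mid", "Q", 3),
    ("mid", "W", 2),
    ("late", "Q", 3),
    ("late", "W", 3),
)

#: Default true-DE structure: 200 caste-DE features concentrated in mid and
#: late stages (none early), mirroring the stage profile of strong caste
#: differences in this study design.
DEFAULT_DE_SPEC: dict[str, tuple[DEBlock, ...]] = {
    "mid": (DEBlock(60, "Q"), DEBlock(90, "W")),
    "late": (DEBlock(36, "Q"), DEBlock(14, "W")),
}


@dataclass
class SimDesign:
    """Parameters of the simulated study.

    Defaults are the conditions of the emulated design: 15,000 features,
    17 libraries across six phenotypes, library depths around 1e6 reads,
    200 true caste-DE features at log2-fold 4 with NB dispersion 0.05, a
    stage effect on 60% of features so replicates cluster by stage rather
    than caste, ~30% unannotated transcripts of which ~31% are novel, and
    half of all features having an orthologue in the comparison species.
    """

    n_features: int = 15000
    phenotypes: tuple[tuple[str, str, int], ...] = DEFAULT_PHENOTYPES
    depth_range: tuple[int, int] = (800_000, 1_200_000)
    de_spec: dict[str, tuple[DEBlock, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DE_SPEC)
    )
    frac_unannotated: float = 0.30
    frac_novel_of_unannotated: float = 0.314
    frac_coding_of_novel: float = 0.03
    ortho_fraction: float = 0.51
    ortho_shared_de_rate: float = 0.10
    ortho_background_de_rate: float = 0.02
    base_dispersion: float = 0.05
    frac_stage_responsive: float = 0.60
    stage_effect_sd: float = 1.0  # log2 units
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_unannotated",
            "frac_novel_of_unannotated",
            "frac_coding_of_novel",
            "ortho_fraction",
            "ortho_shared_de_rate",
            "ortho_background_de_rate",
            "frac_stage_responsive",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for stage, caste, n_rep in self.phenotypes:
            if n_rep < 2:
                raise ValueError(
                    f"phenotype {phenotype_label(stage, caste)} needs >= 2 replicates"
                )
        if self.depth_range[0] <= 0 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth_range")
        n_de = self.n_true_de()
        if self.n_features < n_de:
            raise ValueError(
                f"n_features={self.n_features} is smaller than the "
                f"{n_de} true-DE features requested"
            )

    def n_true_de(self) -> int:
        return sum(b.n for blocks in self.de_spec.values() for b in blocks)

    def sample_ids(self) -> list[str]:
        out = []
        for stage, caste, n_rep in self.phenotypes:
            label = phenotype_label(stage, caste)
            out.extend(f"{label}{r + 1}" for r in range(n_rep))
        return out

    def metadata(self) -> pd.DataFrame:
        rows = []
        for stage, caste, n_rep in self.phenotypes:
            label = phenotype_label(stage, caste)
            for r in range(n_rep):
                rows.append(
                    {"sample_id": f"{label}{r + 1}", "stage": stage,
                     "caste": caste, "replicate": r + 1}
                )
        return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(design: SimDesign) -> tuple[CountMatrix, SimTruth]:
    """Generate a raw count matrix plus ground truth under the design.

    Counts are negative binomial with per-feature dispersion around a mean
    built from a log-normal baseline, a shared per-stage factor on the
    stage-responsive features, and a caste factor of 2**log2_fold applied
    only to the true-DE features within their stage.  Per-library depths
    are drawn uniformly from ``depth_range`` and each column of means is
    scaled to its library depth.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_features
    features = [f"g{i:05d}" for i in range(n)]
    meta = design.metadata()
    samples = list(meta.index)

    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n)

    stages = ["early", "mid", "late"]
    stage_factor = np.ones((n, len(stages)))
    responsive = rng.random(n) < design.frac_stage_responsive
    stage_factor[responsive] = 2.0 ** rng.normal(
        0.0, design.stage_effect_sd, (int(responsive.sum()), len(stages))
    )

    # disjoint allocation of true-DE features across (stage, block)
    order = rng.permutation(n)
    dispersion = np.full(n, design.base_dispersion)
    caste_factor = np.ones((n, len(samples)))
    truth = SimTruth()
    cursor = 0
    sample_stage = meta["stage"].to_numpy()
    sample_caste = meta["caste"].to_numpy()
    for stage, blocks in design.de_spec.items():
        for block in blocks:
            idx = order[cursor: cursor + block.n]
            cursor += block.n
            dispersion[idx] = block.dispersion
            col_mask = (sample_stage == stage) & (sample_caste == block.direction)
            caste_factor[np.ix_(idx, np.where(col_mask)[0])] = 2.0 ** block.log2_fold
            truth.true_de_features[(stage, block.direction)] = {
                features[i] for i in idx
            }

    stage_col = np.array([stages.index(s) for s in sample_stage])
    w = baseline[:, None] * stage_factor[:, stage_col] * caste_factor
    depths = rng.integers(design.depth_range[0], design.depth_range[1] + 1, len(samples))
    mu = w / w.sum(axis=0, keepdims=True) * depths[None, :]

    disp = np.maximum(dispersion, 1e-8)[:, None]
    r = 1.0 / disp
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(features, name="feature_id"),
                            columns=samples),
        metadata=meta,
        normalized=False,
    )

    # annotation classes
    n_unann = int(round(design.frac_unannotated * n))
    unann = rng.permutation(n)[:n_unann]
    unann_set = {features[i] for i in unann}
    n_novel = int(round(design.frac_novel_of_unannotated * n_unann))
    novel = set(list(unann_set)[:n_novel])
    n_coding = int(round(design.frac_coding_of_novel * n_novel))
    novel_coding = set(sorted(novel)[:n_coding])
    for f in features:
        if f not in unann_set:
            truth.true_classes[f] = "annotated"
        elif f not in novel:
            truth.true_classes[f] = "unannotated_not_novel"
        elif f in novel_coding:
            truth.true_classes[f] = "novel_coding"
        else:
            truth.true_classes[f] = "novel_noncoding"

    # orthologues and partner-species DE status
    n_ortho = int(round(design.ortho_fraction * n))
    ortho_idx = np.sort(rng.permutation(n)[:n_ortho])
    all_de = truth.all_de_features()
    for k, i in enumerate(ortho_idx):
        a_id = features[i]
        b_id = f"Amel{k:05d}"
        truth.true_orthologues.append((a_id, b_id))
        if a_id in all_de:
            shared = rng.random() < design.ortho_shared_de_rate
        else:
            shared = rng.random() < design.ortho_background_de_rate
        if shared:
            truth.partner_de.add(b_id)
    return matrix, truth


# -- homology hit tables -------------------------------------------------------

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "subject_genus", "search_type",
]

_OTHER_GENERA = ("Apis", "Megachile", "Drosophila", "Nasonia")


def _hit_row(rng, q, genus, evalue, search_type):
    length = int(rng.integers(80, 500))
    return {
        "qseqid": q,
        "sseqid": f"{genus}_{rng.integers(0, 10**6):06d}",
        "pident": float(np.round(rng.uniform(70, 99), 2)),
        "length": length,
        "mismatch": int(rng.integers(0, 30)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": float(np.round(max(30.0, -10 * np.log10(evalue + 1e-300)), 1)),
        "subject_genus": genus,
        "search_type": search_type,
    }


def simulate_hit_tables(truth: SimTruth, seed: int = 0) -> pd.DataFrame:
    """Homology hit table (outfmt-6-style plus genus column) matching the truth.

    Rows are constructed so that the taxonomic-novelty rule recovers
    ``truth.true_classes`` exactly: non-novel features get at least one
    significant (E <= 1e-5) hit outside the focal genus; novel features get
    hits only within the focal genus at the significant level (some with a
    weak non-significant outside hit, and some with no hits at all).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f, cls in truth.true_classes.items():
        if cls in ("annotated", "unannotated_not_novel"):
            genus = _OTHER_GENERA[int(rng.integers(0, len(_OTHER_GENERA)))]
            ev = 10.0 ** rng.uniform(-40, -6)
            rows.append(_hit_row(rng, f, genus, ev, "prot"))
            if rng.random() < 0.7:
                rows.append(_hit_row(rng, f, "Bombus", 10.0 ** rng.uniform(-60, -10), "nucl"))
        else:  # novel
            u = rng.random()
            if u < 0.15:
                continue  # no hits at all: still novel by the rule
            rows.append(_hit_row(rng, f, "Bombus", 10.0 ** rng.uniform(-60, -10), "nucl"))
            if rng.random() < 0.4:
                # outside-genus hit above the significance threshold
                rows.append(_hit_row(rng, f, "Apis", 10.0 ** rng.uniform(-4, 0), "prot"))
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def simulate_orthology_hits(
    truth: SimTruth, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise cross-species hit tables whose RBH equals ``true_orthologues``.

    Every true pair gets mutual best hits; a fraction of queries also get
    decoy hits with worse E-values, and some unpaired ids get one-sided
    best hits that must not survive the reciprocity requirement.
    """
    rng = np.random.default_rng(seed)
    ab_rows, ba_rows = [], []

    def hit(q, s, ev, bits):
        return {"qseqid": q, "sseqid": s, "evalue": ev, "bitscore": bits}

    b_ids = [b for _, b in truth.true_orthologues]
    for a, b in truth.true_orthologues:
        ev = 10.0 ** rng.uniform(-120, -20)
        bits = float(np.round(rng.uniform(200, 900), 1))
        ab_rows.append(hit(a, b, ev, bits))
        ba_rows.append(hit(b, a, ev, bits))
        if rng.random() < 0.3 and len(b_ids) > 1:
            decoy = b_ids[int(rng.integers(0, len(b_ids)))]
            if decoy != b:
                ab_rows.append(hit(a, decoy, ev * 10 ** rng.uniform(2, 8), bits / 2))
    # one-sided distractors: a few extra B ids whose best A hit is taken
    if truth.true_orthologues:
        a0, _ = truth.true_orthologues[0]
        for j in range(3):
            ba_rows.append(hit(f"AmelX{j:03d}", a0, 1e-10, 100.0))
    return pd.DataFrame(ab_rows), pd.DataFrame(ba_rows)


# -- qRT-PCR plates ------------------------------------------------------------


@dataclass(frozen=True)
class CqTarget:
    """A simulated qPCR target with a known caste fold difference in one stage."""

    gene_id: str
    stage: str
    direction: str  # caste with higher expression
    fold: float


DEFAULT_CQ_TARGETS = (
    CqTarget("TQ4X", "mid", "Q", 4.0),
    CqTarget("TW2X", "late", "W", 2.0),
)

#: Graded per-gene Cq noise (cycles) for the candidate reference genes; the
#: first two form the near-constant-ratio stable pair.
REFERENCE_SIGMAS = (0.03, 0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65)


@dataclass
class CqTruth:
    reference_sigmas: dict[str, float]
    targets: tuple[CqTarget, ...]
    efficiencies: dict[str, float]


def simulate_cq_plates(
    design: SimDesign,
    seed: int = 0,
    n_replicates: int = 6,
    targets: tuple[CqTarget, ...] = DEFAULT_CQ_TARGETS,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, CqTruth]:
    """Long-format Cq plates for reference candidates and fold-change targets.

    One plate per gene, each carrying all biological replicates (six per
    phenotype by default) plus an inter-plate calibrator well.  Reference
    candidates track total cDNA input with graded gene-specific noise;
    targets add a known caste fold difference in one stage.  Per-gene
    amplification efficiencies are drawn in [1.8, 2.1] and reported.  With
    ``noise_scale=0`` all replicates of a phenotype have identical Cq.

    Returns (plates, sample metadata, truth).
    """
    rng = np.random.default_rng(seed)
    phenos = sorted({(s, c) for s, c, _ in design.phenotypes},
                    key=lambda p: phenotype_label(*p))
    meta_rows = []
    for stage, caste in phenos:
        label = phenotype_label(stage, caste)
        for r in range(n_replicates):
            meta_rows.append(
                {"sample_id": f"{label}_s{r + 1}", "stage": stage,
                 "caste": caste, "replicate": r + 1}
            )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    ref_genes = [f"REF{i + 1}" for i in range(len(REFERENCE_SIGMAS))]
    genes = ref_genes + [t.gene_id for t in targets]
    eff = {g: float(np.round(rng.uniform(1.8, 2.1), 3)) for g in genes}
    base_cq = {g: float(rng.uniform(18, 28)) for g in genes}
    plate_offset = {g: float(rng.normal(0, 0.7)) for g in genes}

    input_factor = 2.0 ** rng.normal(0.0, 0.25 * noise_scale, len(meta))

    rows = []
    sigma = dict(zip(ref_genes, REFERENCE_SIGMAS))
    for g in genes:
        for k, (sample, row) in enumerate(meta.iterrows()):
            expr = input_factor[k]
            for t in targets:
                if g == t.gene_id and row["stage"] == t.stage and row["caste"] == t.direction:
                    expr *= t.fold
            gene_sd = sigma.get(g, 0.15)
            cq = (
                base_cq[g]
                - np.log(expr) / np.log(eff[g])
                + rng.normal(0, gene_sd * noise_scale)
                + plate_offset[g]
            )
            rows.append(
                {"plate_id": f"plate_{g}", "well": f"W{k + 1:02d}", "gene_id": g,
                 "sample_id": sample, "Cq": float(cq), "is_IPC": False}
            )
        rows.append(
            {"plate_id": f"plate_{g}", "well": "IPC", "gene_id": "IPC",
             "sample_id": "IPC", "is_IPC": True,
             "Cq": float(22.0 + plate_offset[g] + rng.normal(0, 0.02 * noise_scale))}
        )
    plates = pd.DataFrame(rows)
    truth = CqTruth(
        reference_sigmas={g: float(s) for g, s in zip(ref_genes, REFERENCE_SIGMAS)},
        targets=tuple(targets),
        efficiencies=eff,
    )
    return plates, meta, truth
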