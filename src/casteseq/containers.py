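"""Shared in-memory containers for the pipeline.

The central object is :class:`CountMatrix`: a features x samples table of
read counts together with per-sample phenotype metadata (developmental
stage x caste path x replicate).  Counts are held in a pandas DataFrame so
that downstream steps can use ordinary vectorised operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("early", "mid", "late")
CASTES = ("Q", "W")

#: Canonical two-letter phenotype labels: EQ, EW, MQ, MW, LQ, LW.
PHENOTYPE_LABELS = {
    ("early", "Q"): "EQ",
    ("early", "W"): "EW",
    ("mid", "Q"): "MQ",
    ("mid", "W"): "MW",
    ("late", "Q"): "LQ",
    ("late", "W"): "LW",
}


def phenotype_label(stage: str, caste: str) -> str:
    """Two-letter label for a (stage, caste) phenotype, e.g. ('mid','Q') -> 'MQ'."""
    return PHENOTYPE_LABELS[(stage, caste)]


@dataclass
class CountMatrix:
    """A gene/transcript x sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id, one column per sample.  Raw counts
        must be non-negative; normalized matrices may hold fractional means
        of subsampling draws.
    metadata
        DataFrame indexed by sample id with columns ``stage`` (early/mid/late),
        ``caste`` (Q/W) and ``replicate``.
    normalized
        Whether the matrix has been depth-normalized.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("stage", "caste"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        bad_stage = set(self.metadata["stage"]) - set(STAGES)
        bad_caste = set(self.metadata["caste"]) - set(CASTES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        if bad_caste:
            raise ValueError(f"unknown castes: {sorted(bad_caste)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, stage: str, caste: str | None = None) -> list[str]:
        """Sample ids belonging to a stage (optionally restricted to a caste)."""
        meta = self.metadata.loc[list(self.counts.columns)]
        mask = meta["stage"] == stage
        if caste is not None:
            mask &= meta["caste"] == caste
        return list(meta.index[mask])

    def phenotypes(self) -> list[tuple[str, str]]:
        """Distinct (stage, caste) pairs present, in canonical order."""
        meta = self.metadata.loc[list(self.counts.columns)]
        present = set(zip(meta["stage"], meta["caste"]))
        return [p for p in PHENOTYPE_LABELS if p in present]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_samples(self, sample_ids: list[str]) -> "CountMatrix":
        """Return a copy with the given samples removed (explicit exclusion)."""
        keep = [s for s in self.counts.columns if s not in set(sample_ids)]
        return CountMatrix(
            counts=self.counts[keep].copy(),
            metadata=self.metadata.loc[keep].copy(),
            normalized=self.normalized,
        )


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generator.

    ``true_de_features`` maps (stage, direction) -> set of feature ids carrying
    a real caste effect; ``true_classes`` maps feature id -> annotation class;
    ``true_orthologues`` lists (species-A id, species-B id) orthologue pairs;
    ``partner_de`` is the set of species-B ids differentially expressed in the
    simulated comparison species.
    """

    true_de_features: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    true_classes: dict[str, str] = field(default_factory=dict)
    true_orthologues: list[tuple[str, str]] = field(default_factory=list)
    partner_de: set[str] = field(default_factory=set)

    def all_de_features(self) -> set[str]:
        out: set[str] = set()
        for s in self.true_de_features.values():
            out |= s
        return out
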