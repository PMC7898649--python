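"""Count aggregation, subsampling normalization and replicate QC.

Gene expression is summarised as the algebraic sum of the abundances of
reads incident to each transcript.  Libraries are then equalised in depth by
repeated subsampling without replacement (multivariate hypergeometric over
features), averaging the per-feature counts over the draws.  Replicate QC
flags libraries that correlate poorly with same-phenotype replicates on a
log scale; flagged libraries are reported, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CountMatrix, phenotype_label

#: Base-level offset added before taking logs, shared with the OFC statistic.
LOG_OFFSET = 20.0


@dataclass(frozen=True)
class AlignmentRecord:
    """One collapsed read aligned to a feature in one library."""

    read_id: str
    sample_id: str
    feature_id: str
    abundance: int = 1

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError(f"read {self.read_id}: abundance must be >= 1")


def aggregate_counts(
    records: Iterable[AlignmentRecord],
    features: list[str],
    metadata: pd.DataFrame,
) -> CountMatrix:
    """Sum read abundances per (feature, sample) into a raw count matrix.

    Features with no incident reads get zero counts.  Records referring to a
    feature outside ``features`` raise a ``KeyError`` naming the id.
    Aggregation is a plain sum, hence invariant to record order and additive
    over any partition of the record stream.
    """
    known = set(features)
    samples = list(metadata.index)
    counts = pd.DataFrame(0, index=pd.Index(features, name="feature_id"), columns=samples, dtype=np.int64)
    for rec in records:
        if rec.feature_id not in known:
            raise KeyError(f"unknown feature_id in alignment records: {rec.feature_id!r}")
        counts.loc[rec.feature_id, rec.sample_id] += rec.abundance
    return CountMatrix(counts=counts, metadata=metadata, normalized=False)


def subsample_normalize(
    m: CountMatrix,
    target_depth: int | str = "min",
    n_draws: int = 10,
    seed: int = 0,
) -> CountMatrix:
    """Depth-normalize by repeated subsampling without replacement.

    For each library, ``n_draws`` subsamples of exactly ``target_depth`` reads
    are drawn from the library's reads (multivariate hypergeometric over
    features) and the per-feature mean over draws is returned.  Each single
    draw sums to ``target_depth`` exactly, and the expected normalized count
    is ``raw * target_depth / library_total``.

    ``target_depth="min"`` uses the smallest library total.  A library
    already at ``target_depth`` is returned unchanged (the only possible
    draw is the library itself).
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    raw = m.counts.to_numpy()
    if not np.allclose(raw, np.round(raw)):
        raise ValueError("subsampling requires integer raw counts")
    raw = np.round(raw).astype(np.int64)
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        empty = list(m.counts.columns[totals == 0])
        raise ValueError(f"zero-depth libraries cannot be subsampled: {empty}")
    if target_depth == "min":
        depth = int(totals.min())
    else:
        depth = int(target_depth)
        if depth <= 0:
            raise ValueError("target_depth must be positive")
        if (totals < depth).any():
            small = list(m.counts.columns[totals < depth])
            raise ValueError(
                f"target_depth {depth} exceeds library totals of: {small}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        if totals[j] == depth:
            out[:, j] = col
            continue
        draws = rng.multivariate_hypergeometric(col, depth, size=n_draws)
        out[:, j] = draws.mean(axis=0)
    counts = pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)
    return CountMatrix(counts=counts, metadata=m.metadata.copy(), normalized=True)


def replicate_qc(m: CountMatrix, min_corr: float = 0.9) -> pd.DataFrame:
    """Flag libraries poorly correlated with their same-phenotype replicates.

    For each library the mean Pearson correlation of ``log2(count + 20)``
    with every other replicate of the same (stage, caste) phenotype is
    computed.  Libraries below ``min_corr`` are flagged; phenotypes with a
    single library are marked ``unassessable``.  The report only flags --
    removal is an explicit downstream action (``CountMatrix.drop_samples``).
    """
    logc = np.log2(m.counts + LOG_OFFSET)
    meta = m.metadata.loc[list(m.counts.columns)]
    rows = []
    for stage, caste in m.phenotypes():
        samples = m.samples_for(stage, caste)
        label = phenotype_label(stage, caste)
        if len(samples) < 2:
            rows.append(
                {"sample_id": samples[0], "phenotype": label,
                 "mean_corr": np.nan, "flag": "unassessable"}
            )
            continue
        sub = logc[samples]
        corr = sub.corr(method="pearson")
        for s in samples:
            others = [t for t in samples if t != s]
            mean_corr = float(corr.loc[s, others].mean())
            flag = "low_correlation" if mean_corr < min_corr else "ok"
            rows.append(
                {"sample_id": s, "phenotype": label,
                 "mean_corr": mean_corr, "flag": flag}
            )
    return pd.DataFrame(rows).set_index("sample_id")
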