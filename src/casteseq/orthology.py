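"""Reciprocal-best-hit orthology and projection of DE lists into orthologue space.

Orthologues between two species are called as reciprocal best hits (RBH):
a pair (a, b) is kept when b is a's best hit in the A->B search and a is
b's best hit in the B->A search.  "Best" means lowest E-value, ties broken
by highest bitscore, then by lexicographically smallest subject id, which
makes the map deterministic and one-to-one.

DEG/HDEG lists projected through the map become DEO/HDEO lists: the subset
of calls with an orthologue in the comparison species, optionally translated
to the partner namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

HIT_COLUMNS = ["qseqid", "sseqid", "evalue", "bitscore"]


@dataclass
class OrthologueMap:
    """One-to-one orthologue pairs between species A and species B."""

    pairs: list[tuple[str, str]]
    species_a: str = "A"
    species_b: str = "B"
    a_to_b: dict[str, str] = field(init=False)
    b_to_a: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("orthologue map must be one-to-one")
        self.a_to_b = dict(self.pairs)
        self.b_to_a = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "OrthologueMap":
        return OrthologueMap(
            pairs=[(b, a) for a, b in self.pairs],
            species_a=self.species_b,
            species_b=self.species_a,
        )


def _best_hits(table: pd.DataFrame) -> pd.Series:
    """Best subject per query: lowest evalue, then highest bitscore, then id."""
    if table.empty:
        return pd.Series(dtype=object)
    t = table.copy()
    dup = t.duplicated(subset=["qseqid", "sseqid"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (query, subject) hit rows; keeping best-scoring",
            stacklevel=3,
        )
    t = t.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = t.drop_duplicates(subset="qseqid", keep="first")
    return best.set_index("qseqid")["sseqid"]


def rbh(
    map_ab: pd.DataFrame,
    map_ba: pd.DataFrame,
    species_a: str = "A",
    species_b: str = "B",
    max_evalue: float | None = None,
) -> OrthologueMap:
    """Reciprocal best hits from a pair of BLAST-style hit tables.

    Tables need columns qseqid, sseqid, evalue, bitscore.  ``max_evalue``
    optionally filters hits before best-hit selection (off by default).
    """
    for name, t in (("A->B", map_ab), ("B->A", map_ba)):
        missing = [c for c in HIT_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")
    if max_evalue is not None:
        map_ab = map_ab[map_ab["evalue"] <= max_evalue]
        map_ba = map_ba[map_ba["evalue"] <= max_evalue]
    best_ab = _best_hits(map_ab)
    best_ba = _best_hits(map_ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    pairs.sort()
    return OrthologueMap(pairs=pairs, species_a=species_a, species_b=species_b)


def project_lists(
    lists_by_phenotype: dict[str, set[str]],
    omap: OrthologueMap,
    translate: bool = False,
) -> dict[str, set[str]]:
    """Filter per-phenotype feature lists to features with an orthologue.

    With ``translate=True`` the returned ids are the partner species' ids
    (e.g., honeybee accession numbers for bumblebee DEGs); otherwise the
    original ids are kept.  The projected list is always a subset of the
    input list.
    """
    out: dict[str, set[str]] = {}
    for label, features in lists_by_phenotype.items():
        present = {f for f in features if f in omap.a_to_b}
        out[label] = {omap.a_to_b[f] for f in present} if translate else present
    return out
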