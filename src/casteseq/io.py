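"""TSV readers and writers for the pipeline's external formats.

All tables are plain TSV.  Count matrices are feature rows x sample
columns; sample metadata is (sample_id, stage, caste, replicate); hit
tables are BLAST outfmt-6 columns plus ``subject_genus`` and
``search_type``; Cq plates are long format (plate_id, well, gene_id,
sample_id, Cq, is_IPC); gene lists are one id per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CountMatrix


def read_counts(counts_path: str | Path, metadata_path: str | Path,
                normalized: bool = False) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = read_metadata(metadata_path)
    return CountMatrix(counts=counts, metadata=meta, normalized=normalized)


def write_counts(m: CountMatrix, counts_path: str | Path,
                 metadata_path: str | Path | None = None) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        m.metadata.to_csv(metadata_path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#").set_index("sample_id")
    return meta


def read_hit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_cq_plates(path: str | Path) -> pd.DataFrame:
    plates = pd.read_csv(path, sep="\t", comment="#")
    plates["is_IPC"] = plates["is_IPC"].astype(bool)
    return plates


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """Write a result table with an optional commented provenance header."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
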