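"""Genomic predictors: duplicated-gene counts and per-category gene counts.

Duplicated genes are called from an all-against-all protein homology search:
a gene is *duplicated* if it participates — as query or subject — in at least
one same-species, non-self hit with E-value below ``e_max`` and query
coverage above ``cov_min_pct`` (both strict inequalities).  Marking is
symmetric: a passing hit flags both genes, since duplication is a property
of the pair.

NOGF (number of genes per functional category) counts distinct genes
annotated to each category of a flat gene -> category map; a gene in k
categories contributes once to each.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "read_hit_table",
    "count_duplicated_genes",
    "read_gene_category_map",
    "count_nogf",
]

#: The 12 standard columns of tabular homology-search output ("outfmt 6").
HIT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_hit_table(
    path: str | Path,
    species: str,
    extra_col: str = "qcov",
) -> pd.DataFrame:
    """Read one species' homology hits from a 12- or 13-column TSV.

    The 12 columns are the standard tabular dialect; a 13th column is either
    an explicit query-coverage percentage (``extra_col='qcov'``) or the query
    length (``extra_col='qlen'``), from which coverage is computed as
    ``alignment length / query length * 100``.  Standard 12-column tables
    carry no length reference, so coverage cannot be derived and an error is
    raised.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = list(HIT_COLUMNS) + [extra_col]
        if extra_col == "qlen":
            df["qcov"] = df["length"] / df["qlen"] * 100.0
        elif extra_col != "qcov":
            raise ValueError("extra_col must be 'qcov' or 'qlen'")
    elif df.shape[1] == 12:
        raise ValueError(
            "12-column hit table carries no query length or coverage; "
            "append a qcov or qlen column"
        )
    else:
        raise ValueError(f"expected 12 or 13 columns, found {df.shape[1]}")
    out = df.loc[:, ["qseqid", "sseqid", "evalue", "qcov"]].copy()
    out.insert(0, "species", species)
    return _validate_hits(out)


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    required = ["species", "qseqid", "sseqid", "evalue", "qcov"]
    missing = [c for c in required if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns: {missing}")
    bad = hits.index[(hits["evalue"] < 0) | hits["evalue"].isna()]
    if len(bad):
        raise ValueError(f"negative or missing E-value at rows {list(bad[:5])}")
    bad = hits.index[(hits["qcov"] < 0) | (hits["qcov"] > 100) | hits["qcov"].isna()]
    if len(bad):
        raise ValueError(f"coverage outside [0, 100] at rows {list(bad[:5])}")
    return hits


def count_duplicated_genes(
    hits: pd.DataFrame,
    e_max: float = 1e-5,
    cov_min_pct: float = 30.0,
) -> pd.Series:
    """Per-species count of distinct duplicated genes, N_d.

    ``hits`` needs columns ``species, qseqid, sseqid, evalue, qcov``.  Self
    hits and cross-species pairs never count.  Thresholds are strict
    (``E < e_max`` and ``coverage > cov_min_pct``), so boundary hits at
    exactly ``e_max`` or ``cov_min_pct`` are excluded.
    """
    hits = _validate_hits(hits)
    passing = hits[
        (hits["qseqid"] != hits["sseqid"])
        & (hits["evalue"] < e_max)
        & (hits["qcov"] > cov_min_pct)
    ]
    counts: dict[str, int] = {sp: 0 for sp in hits["species"].unique()}
    for sp, grp in passing.groupby("species", sort=False):
        genes = set(grp["qseqid"]) | set(grp["sseqid"])
        counts[sp] = len(genes)
    return pd.Series(counts, name="N_d", dtype=int)


def read_gene_category_map(path: str | Path, species: str) -> pd.DataFrame:
    """Read a two-column gene -> functional-category TSV for one species."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"],
                     comment="#", dtype=str)
    df.insert(0, "species", species)
    return df


def count_nogf(
    gene_map: pd.DataFrame,
    catalogue: Sequence[str],
) -> pd.DataFrame:
    """Distinct-gene counts per functional category (NOGF), per species.

    ``gene_map`` has columns ``species, gene, category``.  Returns a
    species x category DataFrame covering the full ``catalogue`` (absent
    categories are 0).  Duplicate (gene, category) records count once; a
    category outside the catalogue is an error.
    """
    cats = list(catalogue)
    if len(set(cats)) != len(cats):
        raise ValueError("catalogue contains duplicate categories")
    species = list(pd.unique(gene_map["species"])) if len(gene_map) else []
    table = pd.DataFrame(0, index=pd.Index(species, name="species"),
                         columns=cats, dtype=int)
    if len(gene_map) == 0:
        return table
    unknown = sorted(set(gene_map["category"]) - set(cats))
    if unknown:
        raise ValueError(f"categories outside the catalogue: {unknown}")
    dedup = gene_map.drop_duplicates(subset=["species", "gene", "category"])
    counts = dedup.groupby(["species", "category"], sort=False)["gene"].nunique()
    for (sp, cat), k in counts.items():
        table.loc[sp, cat] = int(k)
    return table
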