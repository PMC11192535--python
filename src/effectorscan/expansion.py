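"""Gene-family (functional-domain) expansion ranking across species.

Given a species × domain table of gene-copy counts, each domain's expansion in
a focal species is scored against the *best* comparator:

    score  = focal_count − max(other species' counts)
    ratio  = (focal_count + 1) / (max_other + 1)

Domains are ranked by score (ties by ratio, then accession), and extreme
expansions are flagged with a robust z score over the score distribution
(median / 1.4826·MAD, with mean-absolute-deviation and no-outlier fallbacks
for degenerate dispersion).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "DomainCountTable",
    "ExpansionResult",
    "count_domains",
    "rank_expansions",
    "flag_outliers",
]


@dataclass
class DomainCountTable:
    """Species × domain gene-copy counts (non-negative integers)."""

    counts: pd.DataFrame  # index: species, columns: domain accessions

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.isfinite(arr.astype(float)).all():
                raise InputError("domain counts must be finite")
            if (arr < 0).any():
                raise InputError("domain counts must be >= 0")
            if not np.array_equal(arr.astype(float), np.floor(arr.astype(float))):
                raise InputError("domain counts must be integers")
        self.counts = self.counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpansionResult:
    domain: str
    focal_count: int
    max_other: int
    score: int
    ratio: float
    rank: int = 0
    robust_z: float = float("nan")
    outlier: bool = False


def count_domains(annotations: pd.DataFrame) -> DomainCountTable:
    """Build the count table from (species, gene, domain) annotation rows.

    A domain's count in a species is the number of *distinct* genes carrying
    it; a gene listing the same domain twice counts once.  Missing
    (species, domain) pairs are zero.
    """
    required = {"species", "gene", "domain"}
    missing = required - set(annotations.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    bad = annotations["domain"].isna() | (annotations["domain"].astype(str).str.strip() == "")
    if bad.any():
        raise InputError(
            f"malformed domain accession in {int(bad.sum())} annotation row(s)"
        )
    dedup = annotations.drop_duplicates(subset=["species", "gene", "domain"])
    counts = (
        dedup.groupby(["species", "domain"])["gene"]
        .nunique()
        .unstack(fill_value=0)
        .sort_index()
    )
    counts = counts[sorted(counts.columns)]
    return DomainCountTable(counts)


def rank_expansions(table: DomainCountTable, focal_species: str) -> list[ExpansionResult]:
    """Rank domains by expansion of the focal species over the best comparator.

    Sort key: score descending, then ratio descending, then accession
    ascending — fully deterministic.  Domains absent from the focal species
    are retained (score <= 0) so contractions stay visible.
    """
    if focal_species not in table.counts.index:
        raise InputError(f"focal species {focal_species!r} absent from table")
    if len(table.counts.index) < 2:
        raise InputError("expansion ranking needs >= 2 species")
    focal = table.counts.loc[focal_species]
    others = table.counts.drop(index=focal_species)
    max_other = others.max(axis=0)
    results = [
        ExpansionResult(
            domain=dom,
            focal_count=int(focal[dom]),
            max_other=int(max_other[dom]),
            score=int(focal[dom] - max_other[dom]),
            ratio=(int(focal[dom]) + 1) / (int(max_other[dom]) + 1),
        )
        for dom in table.counts.columns
    ]
    results.sort(key=lambda r: (-r.score, -r.ratio, r.domain))
    for i, res in enumerate(results, start=1):
        res.rank = i
    return results


def flag_outliers(
    results: list[ExpansionResult], cutoff: float = 5.0
) -> list[ExpansionResult]:
    """Flag extreme expansions by robust z over the score distribution.

    robust_z = (score − median) / (1.4826 × MAD).  If the MAD is zero the
    scale falls back to the mean absolute deviation from the median; if that
    is also zero every score equals the median, so nothing is flagged.
    """
    if len(results) < 5:
        raise InputError(f"outlier flagging needs >= 5 domains; got {len(results)}")
    scores = np.array([r.score for r in results], dtype=float)
    center = float(np.median(scores))
    mad = float(np.median(np.abs(scores - center)))
    scale = 1.4826 * mad
    if scale == 0:
        # mean abs dev == 0 would imply all scores equal the median
        scale = float(np.mean(np.abs(scores - center)))
    for res in results:
        dev = res.score - center
        res.robust_z = dev / scale if scale > 0 else 0.0
        res.outlier = bool(res.robust_z > cutoff)
    return results
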