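"""Expression statistics for tissue-level effector screens.

The substrate is a gene × sample matrix of TPM values with per-sample tissue /
stage / sex / replicate metadata.  The operations implemented here are the
transcriptomic half of the screen:

* the N99 expressed-gene threshold — the TPM value at which the cumulative,
  descending-sorted abundance of a sample group first reaches 99% of its total;
* the tissue-specialization index — the ratio of a gene's mean expression in a
  focal tissue to the mean of all other tissue/stage group means;
* a one-sided Z test on log2(TPM+1) that flags genes with significantly high
  expression among a candidate set;
* expression-pattern hierarchical clustering (1 − Pearson, average linkage)
  and PCA sample ordination, as used for profile heatmaps and tissue maps;
* the 2^−ΔΔCt fold-change utility for qPCR validation data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateDistributionError, InputError

__all__ = [
    "ExpressionMatrix",
    "ExpressionThreshold",
    "SpecializationScore",
    "HighExpressionCall",
    "ProfileOrdering",
    "SampleProjection",
    "compute_n99",
    "call_expressed",
    "specialization_index",
    "specialization_table",
    "call_high_expression",
    "cluster_profiles",
    "project_samples",
    "ddct_fold_change",
]

METADATA_COLUMNS = ("tissue", "stage", "sex", "replicate")


@dataclass
class ExpressionMatrix:
    """Gene × sample TPM matrix plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    sample; ``metadata`` is indexed by sample identifier and carries at least
    tissue, stage, sex and replicate columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene identifiers: {list(dupes)}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise InputError(f"duplicate sample identifiers: {list(dupes)}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                "non-finite TPM value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise InputError(
                "negative TPM value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise InputError(f"metadata missing required columns: {missing}")
        mat_samples = set(self.values.columns)
        meta_samples = set(self.metadata.index)
        if mat_samples != meta_samples:
            orphans_mat = sorted(mat_samples - meta_samples)
            orphans_meta = sorted(meta_samples - mat_samples)
            raise InputError(
                "sample set mismatch between matrix and metadata; "
                f"matrix-only: {orphans_mat}; metadata-only: {orphans_meta}"
            )
        # keep metadata rows aligned with the matrix column order
        self.metadata = self.metadata.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for_tissue(self, tissue: str) -> list[str]:
        return list(self.metadata.index[self.metadata["tissue"] == tissue])

    def group_keys(self) -> pd.Series:
        """(tissue, stage, sex) group key per sample."""
        return pd.Series(
            list(
                zip(
                    self.metadata["tissue"],
                    self.metadata["stage"],
                    self.metadata["sex"],
                )
            ),
            index=self.metadata.index,
        )

    def group_means(self) -> pd.DataFrame:
        """Gene × group matrix of replicate-averaged TPM."""
        keys = self.group_keys()
        return self.values.T.groupby(keys).mean().T

    def scaled(self, c: float) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values * c, self.metadata.copy())


@dataclass
class ExpressionThreshold:
    group: object
    fraction: float
    threshold: float
    n_expressed: int


@dataclass
class SpecializationScore:
    gene: str
    focal_group: object
    index: float  # may be math.inf; NaN marks the undefined 0/0 case


@dataclass
class HighExpressionCall:
    gene: str
    z: float
    p: float
    called: bool


@dataclass
class ProfileOrdering:
    leaf_order: list[str]
    merge_heights: list[float] = field(default_factory=list)


@dataclass
class SampleProjection:
    coordinates: pd.DataFrame  # samples × axes
    variance_fractions: np.ndarray


def compute_n99(
    values,
    fraction: float = 0.99,
    expressed_rule: str = "inclusive_ge",
    group: object = None,
) -> ExpressionThreshold:
    """Expressed-gene threshold from cumulative descending abundance.

    Sort TPM values descending and take the value at the first position where
    the running cumulative sum reaches ``fraction`` of the total.  Genes are
    counted expressed against that threshold per ``expressed_rule``.  An
    all-zero group yields threshold 0 with nothing expressed.
    """
    if not 0 < fraction < 1:
        raise InputError(f"fraction must lie in (0, 1); got {fraction}")
    arr = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    if arr.size and ((arr < 0).any() or not np.isfinite(arr).all()):
        raise InputError("TPM values must be finite and >= 0")
    total = arr.sum()
    if arr.size == 0 or total <= 0:
        return ExpressionThreshold(group, fraction, 0.0, 0)
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    pos = int(np.argmax(cum >= fraction * total))
    threshold = float(desc[pos])
    if expressed_rule == "inclusive_ge":
        n_expressed = int((arr >= threshold).sum())
    elif expressed_rule == "strict_gt":
        n_expressed = int((arr > threshold).sum())
    else:
        raise InputError(f"unknown expressed_rule {expressed_rule!r}")
    return ExpressionThreshold(group, fraction, threshold, n_expressed)


def _group_mean_expression(matrix: ExpressionMatrix, sample_group) -> pd.Series:
    group = list(sample_group)
    if not group:
        raise InputError("sample group is empty")
    unknown = [s for s in group if s not in matrix.values.columns]
    if unknown:
        raise InputError(f"unknown samples in group: {unknown}")
    return matrix.values[group].mean(axis=1)


def call_expressed(
    matrix: ExpressionMatrix,
    sample_group,
    fraction: float = 0.99,
    expressed_rule: str = "inclusive_ge",
) -> set[str]:
    """Genes expressed in a sample group per its N99 threshold.

    Group expression is the mean TPM across the group's samples; the threshold
    is computed on that vector and genes pass per ``expressed_rule``.
    """
    mean_tpm = _group_mean_expression(matrix, sample_group)
    thr = compute_n99(mean_tpm, fraction, expressed_rule)
    if thr.n_expressed == 0:
        return set()
    if expressed_rule == "inclusive_ge":
        mask = mean_tpm >= thr.threshold
    else:
        mask = mean_tpm > thr.threshold
    return set(mean_tpm.index[mask])


def specialization_index(
    matrix: ExpressionMatrix, gene: str, focal_group
) -> SpecializationScore:
    """Ratio of focal-group mean expression to the mean of other group means.

    The denominator averages each non-focal tissue/stage group's replicates
    first and then averages across groups, so heavily replicated groups do not
    dominate.  Edge cases: 0/positive → 0, positive/0 → +inf, 0/0 → NaN.
    """
    if gene not in matrix.values.index:
        raise InputError(f"gene {gene!r} absent from matrix")
    focal = list(focal_group)
    focal_mean = float(_group_mean_expression(matrix, focal).loc[gene])
    keys = matrix.group_keys()
    focal_set = set(focal)
    other_samples = [s for s in matrix.samples if s not in focal_set]
    if not other_samples:
        raise InputError("no non-focal samples available")
    other = matrix.values.loc[gene, other_samples]
    group_means = other.groupby(keys.loc[other_samples]).mean()
    denom = float(group_means.mean())
    if denom > 0:
        index = focal_mean / denom
    elif focal_mean > 0:
        index = math.inf
    else:
        index = math.nan
    return SpecializationScore(gene, tuple(focal), index)


def specialization_table(
    matrix: ExpressionMatrix, focal_group, pseudocount: float = 0.0
) -> pd.Series:
    """Vectorized specialization index for every gene (same rule as above).

    ``pseudocount`` > 0 is an optional ranking-stability device added to both
    numerator and denominator; 0 keeps the plain ratio with its inf/NaN
    sentinels.
    """
    focal = list(focal_group)
    focal_mean = _group_mean_expression(matrix, focal)
    keys = matrix.group_keys()
    focal_set = set(focal)
    other_samples = [s for s in matrix.samples if s not in focal_set]
    if not other_samples:
        raise InputError("no non-focal samples available")
    other = matrix.values[other_samples]
    denom = other.T.groupby(keys.loc[other_samples]).mean().T.mean(axis=1)
    if pseudocount > 0:
        return (focal_mean + pseudocount) / (denom + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = focal_mean / denom
    ratio[(focal_mean > 0) & (denom == 0)] = math.inf
    ratio[(focal_mean == 0) & (denom == 0)] = math.nan
    return ratio


def call_high_expression(
    candidate_values, alpha: float = 0.05
) -> list[HighExpressionCall]:
    """One-sided Z test for significantly high expression among candidates.

    TPM values are transformed to log2(TPM+1); each candidate's standard score
    uses the candidate-set mean and sample (n−1) standard deviation, and the
    upper-tail standard-normal probability is compared against ``alpha``.
    """
    series = pd.Series(candidate_values, dtype=float)
    if len(series) < 3:
        raise InputError(
            f"high-expression Z test needs >= 3 candidates; got {len(series)}"
        )
    if (series < 0).any() or not np.isfinite(series.to_numpy()).all():
        raise InputError("TPM values must be finite and >= 0")
    x = np.log2(series.to_numpy() + 1.0)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError(
            "all candidates have identical expression; the Z test is undefined "
            "and no high-expression call is possible"
        )
    z = (x - x.mean()) / sd
    p = stats.norm.sf(z)
    return [
        HighExpressionCall(gene, float(zi), float(pi), bool(pi < alpha))
        for gene, zi, pi in zip(series.index, z, p)
    ]


def cluster_profiles(matrix: ExpressionMatrix, genes=None) -> ProfileOrdering:
    """Order genes by expression-pattern similarity.

    Profiles are standardized per gene across samples; agglomerative
    clustering uses distance 1 − Pearson correlation with average linkage.
    Zero-variance genes have no defined correlation and are appended last in
    lexicographic order; ties elsewhere break lexicographically because the
    input is pre-sorted by gene id.
    """
    sub = matrix.values if genes is None else matrix.values.loc[list(genes)]
    sub = sub.sort_index()  # lexicographic tie-break
    if len(sub) == 0:
        raise InputError("no genes to cluster")
    if len(sub) == 1:
        return ProfileOrdering(list(sub.index), [])
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    variable = sd > 0
    constant_genes = list(sub.index[~variable])
    var_genes = list(sub.index[variable])
    if len(var_genes) < 2:
        return ProfileOrdering(var_genes + constant_genes, [])
    zs = arr[variable]
    zs = (zs - zs.mean(axis=1, keepdims=True)) / zs.std(axis=1, keepdims=True)
    corr = np.corrcoef(zs)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="average")
    order = [var_genes[i] for i in leaves_list(link)]
    return ProfileOrdering(order + constant_genes, [float(h) for h in link[:, 2]])


def project_samples(matrix: ExpressionMatrix, n_axes: int | None = None) -> SampleProjection:
    """PCA ordination of samples on log2(TPM+1) expression profiles.

    Genes are centered; principal axes come from the SVD of the sample × gene
    matrix.  The sign of each axis is fixed so its largest-magnitude gene
    loading is positive, which makes the projection deterministic.
    """
    if len(matrix.samples) < 2:
        raise InputError("PCA ordination needs >= 2 samples")
    x = np.log2(matrix.values.to_numpy(dtype=float).T + 1.0)  # samples × genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-magnitude loading per axis positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = u * s
    total_var = float((s**2).sum())
    if total_var > 0:
        fractions = s**2 / total_var
    else:
        fractions = np.zeros_like(s)
    keep = len(s) if n_axes is None else min(n_axes, len(s))
    axes = [f"PC{k + 1}" for k in range(keep)]
    return SampleProjection(
        pd.DataFrame(coords[:, :keep], index=matrix.samples, columns=axes),
        fractions[:keep],
    )


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression by the 2^−ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference gene) within each condition;
    ΔΔCt = ΔCt(sample) − ΔCt(control); fold change = 2^−ΔΔCt.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise InputError("all Ct values must be finite")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_control = ct_target_control - ct_ref_control
    return float(2.0 ** (-(dct_sample - dct_control)))
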