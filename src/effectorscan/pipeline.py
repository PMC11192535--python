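"""End-to-end pipeline orchestration.

``run_pipeline`` executes the four analysis stages in order — expression
profiling, effector calling, family-expansion ranking, ecology statistics —
over the input files named in ``RunConfig.paths`` and returns a
:class:`ResultBundle` whose JSON payload is byte-identical across runs for a
fixed seed and fixed inputs (no timestamps are embedded).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import io as esio
from .config import RunConfig
from .ecology import (
    choice_indices,
    fold_recovery,
    mann_whitney_u,
    oviposition_rate,
    signed_rank_test,
    summarize_conditions,
)
from .effectors import (
    call_highly_expressed_vps,
    call_teratocyte_effectors,
    call_venom_proteins,
    match_peptides_many,
)
from .errors import StageError
from .expansion import flag_outliers, rank_expansions
from .profiles import (
    cluster_profiles,
    compute_n99,
    call_expressed,
    project_samples,
    specialization_table,
)

logger = logging.getLogger("effectorscan")

__version__ = "0.1.0"

INPUT_KEYS = (
    "expression",
    "metadata",
    "fasta",
    "peptides",
    "annotation",
    "domain_counts",
    "parasitism",
    "choice",
    "dissection",
)


def _jsonable(obj):
    """Recursively convert to JSON-serializable types; inf/nan become strings."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return "nan"
        return obj
    if hasattr(obj, "item"):  # numpy scalars
        return _jsonable(obj.item())
    return obj


@dataclass
class ResultBundle:
    """Serializable results of a full pipeline run with provenance."""

    profile: dict = field(default_factory=dict)
    effectors: dict = field(default_factory=dict)
    expansion: dict = field(default_factory=dict)
    ecology: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_payload(self) -> str:
        data = {
            "profile": self.profile,
            "effectors": self.effectors,
            "expansion": self.expansion,
            "ecology": self.ecology,
            "provenance": self.provenance,
        }
        return json.dumps(_jsonable(data), indent=2, sort_keys=True)

    @classmethod
    def from_payload(cls, text: str) -> "ResultBundle":
        data = json.loads(text)
        return cls(
            profile=data["profile"],
            effectors=data["effectors"],
            expansion=data["expansion"],
            ecology=data["ecology"],
            provenance=data["provenance"],
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_payload() + "\n")


def _provenance(config: RunConfig) -> dict:
    checksums = {}
    for key in INPUT_KEYS:
        path = config.paths.get(key)
        if path and Path(path).exists():
            checksums[key] = esio.file_checksum(path)
    return {
        "tool": "effectorscan",
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": checksums,
    }


def profile_stage(config: RunConfig, matrix) -> dict:
    """Expression thresholds, specialization, ordination."""
    thresholds = {}
    keys = matrix.group_keys()
    for group_key in sorted(set(keys)):
        samples = list(keys.index[keys == group_key])
        mean_tpm = matrix.values[samples].mean(axis=1)
        thr = compute_n99(mean_tpm, config.n99_fraction, config.expressed_rule, group_key)
        thresholds["/".join(map(str, group_key))] = {
            "threshold": thr.threshold,
            "n_expressed": thr.n_expressed,
        }
    out = {"n99_thresholds": thresholds}
    for label, tissue in (
        ("venom_gland", config.venom_tissue),
        ("teratocyte", config.teratocyte_tissue),
    ):
        samples = matrix.samples_for_tissue(tissue)
        if samples:
            spec = specialization_table(matrix, samples)
            top = spec.sort_values(ascending=False).head(50)
            out[f"specialization_top50_{label}"] = {g: float(v) for g, v in top.items()}
    proj = project_samples(matrix, n_axes=2)
    out["sample_projection"] = {
        "coordinates": {
            s: [float(v) for v in row] for s, row in proj.coordinates.iterrows()
        },
        "variance_fractions": [float(v) for v in proj.variance_fractions],
    }
    # expression-pattern ordering of the most venom-specialized genes
    vg_samples = matrix.samples_for_tissue(config.venom_tissue)
    if vg_samples:
        spec = specialization_table(matrix, vg_samples, pseudocount=1.0)
        top_genes = list(spec.sort_values(ascending=False).head(50).index)
        out["profile_ordering_top50_vg"] = cluster_profiles(matrix, top_genes).leaf_order
    return out


def effector_stage(config: RunConfig, matrix, proteins, peptides, annotation) -> dict:
    vg_samples = matrix.samples_for_tissue(config.venom_tissue)
    vg_expressed = call_expressed(
        matrix, vg_samples, config.n99_fraction, config.expressed_rule
    )
    vg_mean = matrix.values[vg_samples].mean(axis=1)
    vg_thr = compute_n99(vg_mean, config.n99_fraction, config.expressed_rule)
    expressed_proteins = [p for p in proteins if p.identifier in vg_expressed]
    supports = match_peptides_many(
        expressed_proteins, peptides["peptide"], config.il_equivalence
    )
    venom_calls = call_venom_proteins(
        vg_expressed,
        supports,
        config.min_peptides,
        vg_threshold=vg_thr.threshold,
        known_genes=matrix.genes,
    )
    high_vps = (
        call_highly_expressed_vps(venom_calls, vg_mean, config.alpha)
        if len(venom_calls) >= 3
        else []
    )
    teratocyte_calls = call_teratocyte_effectors(
        matrix,
        annotation,
        teratocyte_tissue=config.teratocyte_tissue,
        fraction=config.n99_fraction,
        expressed_rule=config.expressed_rule,
        alpha=config.alpha,
        digestion_keywords=config.digestion_keywords,
    )
    return {
        "vg_threshold": vg_thr.threshold,
        "n_vg_expressed": len(vg_expressed),
        "venom_proteins": [
            {"gene": c.gene, "evidence": c.evidence} for c in venom_calls
        ],
        "highly_expressed_vps": [
            {"gene": c.gene, "evidence": c.evidence} for c in high_vps
        ],
        "teratocyte": {
            "n_expressed": len(teratocyte_calls),
            "high": [
                {"gene": c.gene, "evidence": c.evidence}
                for c in teratocyte_calls
                if c.category == "teratocyte_high"
            ],
        },
    }


def expansion_stage(config: RunConfig, domain_table) -> dict:
    results = rank_expansions(domain_table, config.focal_species)
    if len(results) >= 5:
        results = flag_outliers(results, config.outlier_cutoff)
    return {
        "ranking": [
            {
                "domain": r.domain,
                "focal_count": r.focal_count,
                "max_other": r.max_other,
                "score": r.score,
                "ratio": r.ratio,
                "rank": r.rank,
                "robust_z": r.robust_z,
                "outlier": r.outlier,
            }
            for r in results
        ]
    }


def ecology_stage(config: RunConfig, parasitism, choice, dissection) -> dict:
    summaries = summarize_conditions(parasitism)
    by_key = {(s.condition, s.metric): s for s in summaries}
    out: dict = {
        "rates": [
            {
                "condition": list(s.condition),
                "metric": s.metric,
                "mean": s.mean,
                "sem": s.sem,
                "n": s.n,
            }
            for s in summaries
        ]
    }
    # superparasitism fold recovery at the oldest assayed host age
    ages = sorted({s.condition[1] for s in summaries})
    folds = {}
    if ages:
        age = ages[-1]
        species = summaries[0].condition[0]
        for metric in ("parasitism", "emergence"):
            mono = by_key.get(((species, age, "mono"), metric))
            sup = by_key.get(((species, age, "super"), metric))
            if mono and sup and mono.mean > 0:
                folds[metric] = fold_recovery(mono, sup)
        out["fold_recovery"] = {"host_age_days": age, **folds}
    indices = choice_indices(choice)
    out["oviposition"] = {}
    for age, vals in sorted(indices.items()):
        entry: dict = {
            "indices": vals,
            "mean_index": sum(vals) / len(vals) if vals else None,
        }
        try:
            res = signed_rank_test(vals)
            entry["signed_rank"] = {
                "statistic": res.statistic,
                "p": res.p,
                "n": res.n,
                "method": res.method_detail,
            }
        except Exception as exc:  # no usable replicates
            entry["signed_rank"] = {"error": str(exc)}
        out["oviposition"][str(age)] = entry
    nh = [oviposition_rate(r) for r in dissection if r.group == "NH"]
    ph = [oviposition_rate(r) for r in dissection if r.group == "PH"]
    if nh and ph:
        res = mann_whitney_u(nh, ph)
        out["competition"] = {
            "oviposition_rate_nh_mean": sum(nh) / len(nh),
            "oviposition_rate_ph_mean": sum(ph) / len(ph),
            "mann_whitney": {
                "statistic": res.statistic,
                "p": res.p,
                "n": res.n,
                "method": res.method_detail,
            },
        }
    return out


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute profile → effector calling → expansion → ecology."""
    bundle = ResultBundle(provenance=_provenance(config))
    paths = config.paths

    def _path(key: str) -> str:
        if key not in paths:
            raise KeyError(f"config.paths is missing input {key!r}")
        return paths[key]

    try:
        matrix = esio.read_expression_table(_path("expression"), _path("metadata"))
    except Exception as exc:
        raise StageError("load", exc) from exc
    try:
        logger.info("profile stage: %d genes × %d samples", *matrix.values.shape)
        bundle.profile = profile_stage(config, matrix)
    except Exception as exc:
        raise StageError("profile", exc) from exc
    try:
        proteins = esio.read_fasta(_path("fasta"))
        peptides = esio.read_peptide_table(_path("peptides"))
        annotation = esio.read_annotation_table(_path("annotation"))
        logger.info("effector stage: %d proteins, %d peptide rows", len(proteins), len(peptides))
        bundle.effectors = effector_stage(config, matrix, proteins, peptides, annotation)
    except Exception as exc:
        raise StageError("effectors", exc) from exc
    try:
        domain_table = esio.read_domain_count_table(_path("domain_counts"))
        bundle.expansion = expansion_stage(config, domain_table)
    except Exception as exc:
        raise StageError("expansion", exc) from exc
    try:
        parasitism = esio.read_parasitism_records(_path("parasitism"))
        choice = esio.read_choice_records(_path("choice"))
        dissection = esio.read_dissection_records(_path("dissection"))
        bundle.ecology = ecology_stage(config, parasitism, choice, dissection)
    except Exception as exc:
        raise StageError("ecology", exc) from exc
    return bundle


def default_paths(directory: str | Path) -> dict[str, str]:
    """Paths of the standard file set emitted by the simulator."""
    d = Path(directory)
    names = {
        "expression": "expression.tsv",
        "metadata": "metadata.tsv",
        "fasta": "proteins.fasta",
        "peptides": "peptides.tsv",
        "annotation": "annotation.tsv",
        "domain_counts": "domain_counts.tsv",
        "parasitism": "parasitism.csv",
        "choice": "choice.csv",
        "dissection": "dissection.csv",
    }
    return {k: str(d / v) for k, v in names.items()}
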