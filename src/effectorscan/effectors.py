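"""Venom-protein and teratocyte-effector calling.

Integrates the two evidence channels of the screen:

* transcriptomic — a gene is venom-gland (or teratocyte) *expressed* when its
  group-mean TPM passes the group's N99 threshold, and *highly expressed* when
  a one-sided Z test on log2(TPM+1) over the candidate set is significant;
* proteomic — a venom-gland-expressed gene is a *venom protein* when at least
  ``min_peptides`` distinct proteomic peptides align fully (exact contiguous
  substring, optionally with I/L equivalence) to its protein product.

Free-text functional annotation is reduced to coarse classes (digestion,
ribosome, immunity) by keyword matching with a fixed class priority.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import (
    DEFAULT_DIGESTION_KEYWORDS,
    DEFAULT_IMMUNITY_KEYWORDS,
    DEFAULT_RIBOSOME_KEYWORDS,
)
from .errors import InputError
from .profiles import ExpressionMatrix, call_expressed, call_high_expression

__all__ = [
    "ProteinRecord",
    "PeptideSupport",
    "EffectorCall",
    "FunctionalClass",
    "match_peptides",
    "match_peptides_many",
    "call_venom_proteins",
    "call_highly_expressed_vps",
    "classify_function",
    "call_teratocyte_effectors",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """A protein sequence keyed by its gene identifier."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError(f"protein {self.identifier!r} has an empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise InputError(
                    f"protein {self.identifier!r}: illegal character {ch!r} "
                    f"at position {pos}"
                )


@dataclass
class PeptideSupport:
    protein_id: str
    n_distinct_matched: int
    matched_peptides: list[str] = field(default_factory=list)


@dataclass
class EffectorCall:
    gene: str
    category: str  # venom_protein | highly_expressed_vp | teratocyte_effector | teratocyte_high
    evidence: dict = field(default_factory=dict)


@dataclass
class FunctionalClass:
    gene: str
    functional_class: str  # digestion | ribosome | immunity | other | unknown
    matched_keyword: str | None = None


def _il_collapse(s: str) -> str:
    return s.replace("L", "I")


def match_peptides(
    protein: ProteinRecord,
    peptides: Iterable[str],
    il_equivalence: bool = False,
) -> PeptideSupport:
    """Count distinct peptides fully aligned to a protein.

    A peptide matches iff it occurs as a contiguous substring of the protein
    sequence; with ``il_equivalence`` the isobaric residues I and L are
    interchangeable.  Repeated observations of the same peptide sequence count
    once.
    """
    target = protein.sequence
    if il_equivalence:
        target = _il_collapse(target)
    matched: list[str] = []
    seen: set[str] = set()
    for pep in peptides:
        if not pep:
            raise InputError("empty peptide in input")
        pep = pep.upper()
        if pep in seen:
            continue
        seen.add(pep)
        query = _il_collapse(pep) if il_equivalence else pep
        if query in target:
            matched.append(pep)
    return PeptideSupport(protein.identifier, len(matched), matched)


def match_peptides_many(
    proteins: Iterable[ProteinRecord],
    peptides: Iterable[str],
    il_equivalence: bool = False,
) -> dict[str, PeptideSupport]:
    """Peptide support for every protein; shared peptides support each match."""
    unique = list(dict.fromkeys(p.upper() for p in peptides))
    return {
        prot.identifier: match_peptides(prot, unique, il_equivalence)
        for prot in proteins
    }


def call_venom_proteins(
    vg_expressed: Iterable[str],
    peptide_supports: Mapping[str, PeptideSupport],
    min_peptides: int = 3,
    vg_threshold: float | None = None,
    known_genes: Iterable[str] | None = None,
) -> list[EffectorCall]:
    """Venom proteins = VG-expressed genes with >= ``min_peptides`` distinct peptides."""
    expressed = set(vg_expressed)
    if known_genes is not None:
        known = set(known_genes)
        unknown = sorted(set(peptide_supports) - known)
        if unknown:
            raise InputError(f"peptide support for unknown gene(s): {unknown}")
    calls = []
    for gene in sorted(expressed):
        support = peptide_supports.get(gene)
        n = support.n_distinct_matched if support is not None else 0
        if n >= min_peptides:
            calls.append(
                EffectorCall(
                    gene,
                    "venom_protein",
                    evidence={
                        "vg_expressed": True,
                        "vg_threshold": vg_threshold,
                        "n_distinct_peptides": n,
                        "min_peptides": min_peptides,
                        "matched_peptides": list(support.matched_peptides),
                    },
                )
            )
    return calls


def call_highly_expressed_vps(
    venom_calls: Sequence[EffectorCall],
    vg_expression: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
) -> list[EffectorCall]:
    """Promote venom proteins with significantly high VG expression.

    Applies the one-sided Z test over the venom-protein set's venom-gland
    expression (log2(TPM+1) scale) and promotes significant genes to the
    ``highly_expressed_vp`` category.
    """
    if len(venom_calls) < 3:
        raise InputError(
            f"high-expression promotion needs >= 3 venom proteins; got {len(venom_calls)}"
        )
    expr = pd.Series(vg_expression, dtype=float)
    missing = [c.gene for c in venom_calls if c.gene not in expr.index]
    if missing:
        raise InputError(f"venom proteins missing VG expression values: {missing}")
    values = expr.loc[[c.gene for c in venom_calls]]
    ztests = {c.gene: r for c, r in zip(venom_calls, call_high_expression(values, alpha))}
    promoted = []
    for call in venom_calls:
        res = ztests[call.gene]
        if res.called:
            evidence = dict(call.evidence)
            evidence.update({"z": res.z, "p": res.p, "alpha": alpha})
            promoted.append(EffectorCall(call.gene, "highly_expressed_vp", evidence))
    return promoted


def classify_function(
    annotation: pd.DataFrame,
    digestion_keywords: Sequence[str] = DEFAULT_DIGESTION_KEYWORDS,
    ribosome_keywords: Sequence[str] = DEFAULT_RIBOSOME_KEYWORDS,
    immunity_keywords: Sequence[str] = DEFAULT_IMMUNITY_KEYWORDS,
) -> list[FunctionalClass]:
    """Keyword classification of free-text gene function.

    First matching keyword wins within a class; classes are tried in priority
    order digestion > ribosome > immunity.  Genes whose text matches nothing
    are ``other``; empty or placeholder text is ``unknown``.
    """
    required = {"gene_id", "function_text"}
    missing = required - set(annotation.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    tiers = (
        ("digestion", tuple(k.lower() for k in digestion_keywords)),
        ("ribosome", tuple(k.lower() for k in ribosome_keywords)),
        ("immunity", tuple(k.lower() for k in immunity_keywords)),
    )
    out = []
    for gene, text in zip(annotation["gene_id"], annotation["function_text"]):
        text_lc = ("" if pd.isna(text) else str(text)).lower().strip()
        if not text_lc or text_lc in ("unknown", "hypothetical protein", "na"):
            out.append(FunctionalClass(gene, "unknown"))
            continue
        assigned = None
        for cls, keywords in tiers:
            for kw in keywords:
                if kw in text_lc:
                    assigned = FunctionalClass(gene, cls, kw)
                    break
            if assigned:
                break
        out.append(assigned or FunctionalClass(gene, "other"))
    return out


def call_teratocyte_effectors(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    teratocyte_tissue: str = "teratocyte",
    fraction: float = 0.99,
    expressed_rule: str = "inclusive_ge",
    alpha: float = 0.05,
    digestion_keywords: Sequence[str] = DEFAULT_DIGESTION_KEYWORDS,
) -> list[EffectorCall]:
    """Teratocyte effectors and their highly expressed subset.

    The expressed set comes from the N99 threshold on the teratocyte sample
    group; the high subset from the Z test over the expressed set's
    teratocyte-mean expression.  When an annotation table is supplied, each
    call carries its keyword-derived functional class.
    """
    group = matrix.samples_for_tissue(teratocyte_tissue)
    if not group:
        raise InputError(
            f"no samples with tissue {teratocyte_tissue!r} in metadata"
        )
    expressed = call_expressed(matrix, group, fraction, expressed_rule)
    classes: dict[str, FunctionalClass] = {}
    if annotation is not None:
        classes = {
            fc.gene: fc for fc in classify_function(annotation, digestion_keywords)
        }
    calls: list[EffectorCall] = []
    if not expressed:
        return calls
    mean_tpm = matrix.values[group].mean(axis=1)
    high: set[str] = set()
    z_by_gene: dict[str, tuple[float, float]] = {}
    if len(expressed) >= 3:
        candidates = mean_tpm.loc[sorted(expressed)]
        if candidates.nunique() > 1:
            for res in call_high_expression(candidates, alpha):
                z_by_gene[res.gene] = (res.z, res.p)
                if res.called:
                    high.add(res.gene)
    for gene in sorted(expressed):
        fc = classes.get(gene)
        evidence = {
            "teratocyte_expressed": True,
            "mean_tpm": float(mean_tpm.loc[gene]),
            "functional_class": fc.functional_class if fc else None,
        }
        if gene in z_by_gene:
            evidence["z"], evidence["p"] = z_by_gene[gene]
        category = "teratocyte_high" if gene in high else "teratocyte_effector"
        calls.append(EffectorCall(gene, category, evidence))
    return calls
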