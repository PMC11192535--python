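"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the data a proteotranscriptomic effector screen
consumes — a multi-tissue TPM panel, protein sequences, venom-fluid peptide
evidence, per-species domain counts, and replicate-level assay records — with
known planted structure so every downstream stage can be validated:

* baseline expression is log-normal on the TPM scale (TPM = 2^N(μ, σ));
  a planted specialized gene has its focal-tissue samples multiplied by a
  fold factor;
* a subset of the venom-specialized genes is *secreted*: each tryptic peptide
  of their protein (length >= 6 residues) shows up in the peptide table
  independently with a detection probability;
* one domain accession is planted as a focal-species family expansion against
  comparator counts drawn i.i.d. Poisson;
* assay records draw per-host outcomes from stated parasitism/emergence
  probabilities, and two-choice egg counts from side-specific Poisson
  intensities.

Each output table draws from its own random stream spawned from the master
seed, so changing one design block never perturbs the others.
"""
from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecology import ChoiceAssayRecord, DissectionRecord, ParasitismAssayRecord
from .effectors import ProteinRecord
from .errors import ConfigError, InputError
from .profiles import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "digest_tryptic",
    "eligible_peptides",
    "simulate_expression",
    "simulate_proteins",
    "simulate_peptide_evidence",
    "simulate_domain_counts",
    "simulate_annotation",
    "simulate_assays",
    "simulate_all",
]

# amino-acid alphabet with roughly proteome-like frequencies; K+R ~ 11% so a
# tryptic digest yields peptides of mean length ~9
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_RESIDUE_FREQS = np.array(
    [
        0.074, 0.025, 0.054, 0.058, 0.047, 0.074, 0.029, 0.038, 0.058, 0.076,
        0.018, 0.044, 0.038, 0.037, 0.052, 0.081, 0.062, 0.068, 0.013, 0.054,
    ]
)
_RESIDUE_FREQS = _RESIDUE_FREQS / _RESIDUE_FREQS.sum()

_TRYPTIC_RE = re.compile(r"(?<=[KR])(?!P)")

#: tissue panel emulating a multi-stage, multi-tissue transcriptome design:
#: whole-body developmental stages plus the dissected adult tissues the screen
#: compares against (venom gland, teratocytes, sensory organs).
DEFAULT_SAMPLE_DESIGN: tuple[tuple[str, str, str, int], ...] = (
    ("whole_body", "egg", "mixed", 1),
    ("whole_body", "larva_early", "mixed", 1),
    ("whole_body", "larva_mid", "mixed", 1),
    ("whole_body", "larva_late", "mixed", 1),
    ("whole_body", "pupa_early", "mixed", 1),
    ("whole_body", "pupa_mid", "mixed", 1),
    ("whole_body", "pupa_late", "mixed", 1),
    ("whole_body", "adult", "male", 1),
    ("whole_body", "adult", "female", 1),
    ("venom_gland", "adult", "female", 3),
    ("teratocyte", "larva_early", "mixed", 3),
    ("ovipositor", "adult", "female", 2),
    ("antenna", "adult", "female", 2),
    ("leg", "adult", "female", 2),
)

_GENERIC_FUNCTIONS = (
    "hypothetical protein",
    "cytochrome P450",
    "odorant binding protein",
    "cuticular protein",
    "heat shock protein 70",
    "ATP synthase subunit beta",
    "40S ribosomal protein S3",
    "60S ribosomal protein L7",
    "C-type lectin",
    "glutathione S-transferase",
    "tubulin alpha chain",
    "elongation factor 1-alpha",
)
_DIGESTION_FUNCTIONS = (
    "trypsin-like serine protease",
    "trypsin alpha",
    "chymotrypsin-like protease",
    "carboxypeptidase B",
    "lipase member H",
)


def default_gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def _default_planted_specialized() -> tuple[tuple[str, str, float], ...]:
    genes = default_gene_ids(45)
    vg = tuple((g, "venom_gland", 8.0) for g in genes[:30])
    tc = tuple((g, "teratocyte", 8.0) for g in genes[30:45])
    return vg + tc


def _default_planted_secreted() -> tuple[str, ...]:
    return tuple(default_gene_ids(20))


def _default_assay_probs() -> dict:
    # (host_age_days, mode) -> (p_parasitism, p_emergence); monoparasitism
    # efficiency decays with host age while superparasitism largely rescues it
    return {
        (1, "mono"): (0.85, 0.77),
        (2, "mono"): (0.75, 0.65),
        (3, "mono"): (0.55, 0.45),
        (4, "mono"): (0.30, 0.20),
        (1, "super"): (0.88, 0.80),
        (2, "super"): (0.82, 0.72),
        (3, "super"): (0.75, 0.68),
        (4, "super"): (0.66, 0.64),
    }


@dataclass
class SimulationConfig:
    """Generator design; defaults are the package's reference study conditions."""

    seed: int = 0
    n_genes: int = 5000
    sample_design: tuple = DEFAULT_SAMPLE_DESIGN
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    planted_specialized: tuple = field(default_factory=_default_planted_specialized)
    planted_secreted: tuple = field(default_factory=_default_planted_secreted)
    peptide_detection_prob: float = 0.8
    min_peptide_length: int = 6
    protein_length_range: tuple[int, int] = (150, 450)
    # domain-count block: one planted expansion among Poisson comparators
    planted_domain: tuple = ("IPR900001", 29, 2.0)  # (accession, focal_count, lambda)
    n_domains: int = 200
    n_other_species: int = 13
    focal_species: str = "focal_sp"
    # assay block
    assay_probs: dict = field(default_factory=_default_assay_probs)
    host_species: str = "D_suzukii"
    n_assay_replicates: int = 6
    n_hosts_per_replicate: int = 20
    choice_intensity: float = 30.0
    side_preference: float = 1.0  # left/right intensity ratio; 1 = no bias
    choice_ages: tuple[int, ...] = (1, 2, 3, 4)
    choice_durations: tuple[float, ...] = (2.0, 4.0)
    n_choice_replicates: int = 5
    p_oviposition_nh: float = 0.93
    p_oviposition_ph: float = 0.05
    n_dissected: int = 30
    n_dissection_replicates: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if len(self.planted_specialized) > self.n_genes:
            raise ConfigError("more planted specialized genes than genes")
        tissues = {t for t, _, _, _ in self.sample_design}
        gene_set = set(default_gene_ids(self.n_genes))
        planted_genes = set()
        for gene, tissue, fold in self.planted_specialized:
            if tissue not in tissues:
                raise ConfigError(
                    f"planted focal tissue {tissue!r} absent from sample design"
                )
            if gene not in gene_set:
                raise ConfigError(f"planted gene {gene!r} outside the gene set")
            if fold < 1:
                raise ConfigError(f"fold_factor must be >= 1; got {fold} for {gene!r}")
            planted_genes.add(gene)
        orphan_secreted = set(self.planted_secreted) - planted_genes
        if orphan_secreted and self.planted_specialized:
            raise ConfigError(
                f"planted_secreted genes not in planted_specialized: {sorted(orphan_secreted)}"
            )
        if self.planted_secreted and not self.planted_specialized:
            raise ConfigError("planted_secreted requires planted_specialized")
        if not 0 <= self.peptide_detection_prob <= 1:
            raise ConfigError("peptide_detection_prob must lie in [0, 1]")
        accession, focal_count, lam = self.planted_domain
        if focal_count < 0:
            raise ConfigError("planted domain focal_count must be >= 0")
        if lam < 0:
            raise ConfigError("other_count_lambda must be >= 0")
        if self.n_other_species < 1:
            raise ConfigError("n_other_species must be >= 1")
        for (age, mode), (p_par, p_emg) in self.assay_probs.items():
            if not (0 <= p_par <= 1 and 0 <= p_emg <= 1):
                raise ConfigError(f"assay probabilities for ({age}, {mode}) outside [0, 1]")
            if p_emg > p_par:
                raise ConfigError(
                    f"p_emergence > p_parasitism for ({age}, {mode}): a host "
                    "cannot yield a wasp without being parasitized"
                )
        if self.side_preference < 0 or self.choice_intensity < 0:
            raise ConfigError("choice intensities must be >= 0")
        for p in (self.p_oviposition_nh, self.p_oviposition_ph):
            if not 0 <= p <= 1:
                raise ConfigError("oviposition probabilities must lie in [0, 1]")

    # independent stream per output table, all derived from the master seed
    _STREAMS = ("expression", "proteins", "peptides", "domains", "annotation", "assays")

    def rng(self, stream: str) -> np.random.Generator:
        idx = self._STREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(idx,))
        )

    def gene_ids(self) -> list[str]:
        return default_gene_ids(self.n_genes)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to the data."""

    specialized: dict[str, tuple[str, float]]  # gene -> (focal tissue, fold)
    secreted: list[str]
    planted_domain: str
    assay_probs: dict

    def to_json(self) -> str:
        payload = {
            "specialized": {
                g: {"tissue": t, "fold": f} for g, (t, f) in sorted(self.specialized.items())
            },
            "secreted": sorted(self.secreted),
            "planted_domain": self.planted_domain,
            "assay_probs": {
                f"{age}:{mode}": {"p_parasitism": p1, "p_emergence": p2}
                for (age, mode), (p1, p2) in sorted(self.assay_probs.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        probs = {}
        for key, val in data["assay_probs"].items():
            age, mode = key.split(":")
            probs[(int(age), mode)] = (val["p_parasitism"], val["p_emergence"])
        return cls(
            specialized={
                g: (v["tissue"], v["fold"]) for g, v in data["specialized"].items()
            },
            secreted=list(data["secreted"]),
            planted_domain=data["planted_domain"],
            assay_probs=probs,
        )


def digest_tryptic(sequence: str) -> list[str]:
    """In-silico tryptic digest with zero missed cleavages.

    Cleaves C-terminal of every K or R that is not followed by P.  The
    peptides partition the input: their concatenation equals the sequence.
    """
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    # a cleavage site at the C-terminus yields a zero-width trailing split
    return [p for p in _TRYPTIC_RE.split(sequence) if p]


def eligible_peptides(sequence: str, min_length: int = 6) -> list[str]:
    """Tryptic peptides long enough to be observable by MS."""
    return [p for p in digest_tryptic(sequence) if len(p) >= min_length]


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for tissue, stage, sex, n_rep in config.sample_design:
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{tissue}_{stage}_{sex}_r{r}",
                    "tissue": tissue,
                    "stage": stage,
                    "sex": sex,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-normal baseline TPM with planted fold effects in focal tissues."""
    meta = _sample_table(config)
    genes = config.gene_ids()
    rng = config.rng("expression")
    log2_tpm = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=(len(genes), len(meta))
    )
    tpm = np.power(2.0, log2_tpm)
    values = pd.DataFrame(tpm, index=genes, columns=meta.index)
    specialized: dict[str, tuple[str, float]] = {}
    for gene, tissue, fold in config.planted_specialized:
        focal_cols = meta.index[meta["tissue"] == tissue]
        values.loc[gene, focal_cols] *= fold
        specialized[gene] = (tissue, fold)
    truth = SyntheticTruth(
        specialized=specialized,
        secreted=list(config.planted_secreted),
        planted_domain=config.planted_domain[0],
        assay_probs=dict(config.assay_probs),
    )
    return ExpressionMatrix(values, meta), truth


def simulate_proteins(config: SimulationConfig) -> list[ProteinRecord]:
    """One random protein per gene, proteome-like residue frequencies."""
    rng = config.rng("proteins")
    lo, hi = config.protein_length_range
    records = []
    for gene in config.gene_ids():
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length, p=_RESIDUE_FREQS))
        records.append(ProteinRecord(gene, seq))
    return records


def simulate_peptide_evidence(
    proteins: list[ProteinRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Peptide table (peptide, spectrum_count) from secreted proteins only.

    Every eligible tryptic peptide of a secreted protein is emitted
    independently with ``peptide_detection_prob``; spectral counts are
    1 + Poisson(2) per detected peptide.
    """
    by_id = {p.identifier: p for p in proteins}
    missing = [g for g in truth.secreted if g not in by_id]
    if missing:
        raise InputError(f"secreted genes missing from protein set: {missing}")
    rng = config.rng("peptides")
    rows = []
    for gene in sorted(truth.secreted):
        for pep in eligible_peptides(by_id[gene].sequence, config.min_peptide_length):
            if rng.random() < config.peptide_detection_prob:
                rows.append(
                    {"peptide": pep, "spectrum_count": 1 + int(rng.poisson(2.0))}
                )
    return pd.DataFrame(rows, columns=["peptide", "spectrum_count"])


def simulate_domain_counts(config: SimulationConfig):
    """Species × domain counts: i.i.d. Poisson plus one planted expansion."""
    from .expansion import DomainCountTable

    accession, focal_count, lam = config.planted_domain
    rng = config.rng("domains")
    species = [config.focal_species] + [
        f"comparator_{i:02d}" for i in range(1, config.n_other_species + 1)
    ]
    domains = [f"DOM{i:05d}" for i in range(1, config.n_domains)]
    domains.append(accession)
    domains = sorted(domains)
    counts = rng.poisson(lam, size=(len(species), len(domains)))
    table = pd.DataFrame(counts, index=species, columns=domains)
    table.loc[config.focal_species, accession] = focal_count
    return DomainCountTable(table)


def simulate_annotation(config: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-gene annotation: domain accessions plus free-text function.

    Planted teratocyte-specialized genes receive digestion-related text
    (trypsins and friends); planted secreted venom genes a metalloproteinase-
    inhibitor text; everything else draws from a generic pool.
    """
    rng = config.rng("annotation")
    accession, _, _ = config.planted_domain
    rows = []
    for gene in config.gene_ids():
        planted = truth.specialized.get(gene)
        if planted and planted[0] == "teratocyte":
            text = _DIGESTION_FUNCTIONS[int(rng.integers(len(_DIGESTION_FUNCTIONS)))]
            domains = f"PF{int(rng.integers(10000, 20000)):05d}"
        elif gene in truth.secreted:
            text = "tissue inhibitor of metalloproteinase"
            domains = accession
        else:
            text = _GENERIC_FUNCTIONS[int(rng.integers(len(_GENERIC_FUNCTIONS)))]
            domains = f"PF{int(rng.integers(10000, 20000)):05d}"
        rows.append({"gene_id": gene, "domain_accessions": domains, "function_text": text})
    return pd.DataFrame(rows, columns=["gene_id", "domain_accessions", "function_text"])


def simulate_assays(
    config: SimulationConfig,
) -> tuple[list[ParasitismAssayRecord], list[ChoiceAssayRecord], list[DissectionRecord]]:
    """Replicate-level parasitism, two-choice, and dissection records.

    Per host: parasitized with p_parasitism; a parasitized host yields an
    adult wasp with the conditional probability p_emergence / p_parasitism.
    This preserves the marginal Binomial(n, 1 − p_parasitism) emerged-adult
    and Binomial(n, p_emergence) emerged-wasp counts while guaranteeing
    adults + wasps <= hosts.  Choice sides draw Poisson egg totals with a
    left/right intensity ratio of ``side_preference``.
    """
    rng = config.rng("assays")
    n = config.n_hosts_per_replicate
    parasitism: list[ParasitismAssayRecord] = []
    for (age, mode), (p_par, p_emg) in sorted(config.assay_probs.items()):
        p_cond = p_emg / p_par if p_par > 0 else 0.0
        for rep in range(1, config.n_assay_replicates + 1):
            n_parasitized = int(rng.binomial(n, p_par))
            n_wasps = int(rng.binomial(n_parasitized, p_cond))
            parasitism.append(
                ParasitismAssayRecord(
                    replicate=f"{mode}_age{age}_r{rep}",
                    host_species=config.host_species,
                    host_age_days=age,
                    mode=mode,
                    n_hosts=n,
                    n_emerged_host_adults=n - n_parasitized,
                    n_emerged_wasps=n_wasps,
                )
            )
    choice: list[ChoiceAssayRecord] = []
    for age in config.choice_ages:
        for dur in config.choice_durations:
            scale = dur / config.choice_durations[0]
            for rep in range(1, config.n_choice_replicates + 1):
                lam_left = config.choice_intensity * config.side_preference * scale
                lam_right = config.choice_intensity * scale
                choice.append(
                    ChoiceAssayRecord(
                        replicate=f"age{age}_{dur:g}h_r{rep}",
                        age_x=age,
                        n1=int(rng.poisson(lam_left)),
                        nx=int(rng.poisson(lam_right)),
                        duration_h=dur,
                    )
                )
    dissection: list[DissectionRecord] = []
    for group, p in (("NH", config.p_oviposition_nh), ("PH", config.p_oviposition_ph)):
        for rep in range(1, config.n_dissection_replicates + 1):
            dissection.append(
                DissectionRecord(
                    replicate=f"{group}_r{rep}",
                    group=group,
                    n_dissected=config.n_dissected,
                    n_with_eggs=int(rng.binomial(config.n_dissected, p)),
                )
            )
    return parasitism, choice, dissection


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None):
    """Generate every pipeline input; optionally write them to ``outdir``.

    Returns a dict with the in-memory objects; when ``outdir`` is given the
    exact file dialects the readers consume are emitted alongside
    ``truth.json``.
    """
    from . import io as esio

    matrix, truth = simulate_expression(config)
    proteins = simulate_proteins(config)
    peptides = simulate_peptide_evidence(proteins, truth, config)
    domain_table = simulate_domain_counts(config)
    annotation = simulate_annotation(config, truth)
    parasitism, choice, dissection = simulate_assays(config)
    bundle = {
        "matrix": matrix,
        "truth": truth,
        "proteins": proteins,
        "peptides": peptides,
        "domain_table": domain_table,
        "annotation": annotation,
        "parasitism": parasitism,
        "choice": choice,
        "dissection": dissection,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        esio.write_expression_table(matrix, outdir / "expression.tsv", outdir / "metadata.tsv")
        esio.write_fasta(proteins, outdir / "proteins.fasta")
        esio.write_peptide_table(peptides, outdir / "peptides.tsv")
        esio.write_annotation_table(annotation, outdir / "annotation.tsv")
        esio.write_domain_count_table(domain_table, outdir / "domain_counts.tsv")
        esio.write_parasitism_records(parasitism, outdir / "parasitism.csv")
        esio.write_choice_records(choice, outdir / "choice.csv")
        esio.write_dissection_records(dissection, outdir / "dissection.csv")
        (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return bundle
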