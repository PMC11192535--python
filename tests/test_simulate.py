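"""Synthetic-data generator: digestion, planted effects, reproducibility."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from effectorscan.errors import ConfigError, InputError
from effectorscan.profiles import specialization_index
from effectorscan.simulate import (
    SimulationConfig,
    digest_tryptic,
    eligible_peptides,
    simulate_all,
    simulate_assays,
    simulate_domain_counts,
    simulate_expression,
    simulate_peptide_evidence,
    simulate_proteins,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestDigestTryptic:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MKRPGK", ["MK", "RPGK"]),
            ("AAAA", ["AAAA"]),
            ("KKK", ["K", "K", "K"]),
            ("MKPAR", ["MKPAR"]),  # K before P is protected
        ],
    )
    def test_cleavage_rule(self, seq, expected):
        assert digest_tryptic(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            digest_tryptic("")

    @settings(derandomize=True, max_examples=500)
    @given(st.text(alphabet=AA, min_size=1, max_size=120))
    def test_digest_is_a_partition(self, seq):
        peptides = digest_tryptic(seq)
        assert "".join(peptides) == seq
        # no internal cleavage site survives inside a peptide
        for pep in peptides:
            for i, ch in enumerate(pep[:-1]):
                if ch in "KR":
                    assert pep[i + 1] == "P"

    def test_eligibility_floor(self):
        seq = "AAAAAKGGK"  # peptides AAAAAK (6) and GGK (3)
        assert eligible_peptides(seq, 6) == ["AAAAAK"]


class TestSimulateExpression:
    def test_reproducible_and_planted_fold(self):
        cfg = SimulationConfig(
            seed=2,
            n_genes=50,
            planted_specialized=(("g00001", "venom_gland", 8.0),),
            planted_secreted=(),
        )
        m1, t1 = simulate_expression(cfg)
        m2, _ = simulate_expression(cfg)
        assert m1.values.equals(m2.values)
        assert t1.specialized == {"g00001": ("venom_gland", 8.0)}

    def test_absent_focal_tissue_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                n_genes=10,
                planted_specialized=(("g00001", "mars", 2.0),),
                planted_secreted=(),
            )

    def test_empty_gene_panel(self):
        cfg = SimulationConfig(n_genes=0, planted_specialized=(), planted_secreted=())
        m, truth = simulate_expression(cfg)
        assert m.values.shape[0] == 0
        assert truth.specialized == {} and truth.secreted == []

    def test_null_fold_shows_no_location_effect(self):
        """With fold 1 the 'planted' tissue is indistinguishable from the rest:
        the per-gene focal-vs-other t-test rejects at ~the nominal 1% level."""
        n_sig = n_tot = 0
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed,
                n_genes=25,
                planted_specialized=tuple(
                    (f"g{i:05d}", "venom_gland", 1.0) for i in range(1, 26)
                ),
                planted_secreted=(),
            )
            m, _ = simulate_expression(cfg)
            focal = m.samples_for_tissue("venom_gland")
            others = [s for s in m.samples if s not in focal]
            x = np.log2(m.values[focal])
            y = np.log2(m.values[others])
            t, p = stats.ttest_ind(x, y, axis=1)
            n_sig += int((p < 0.01).sum())
            n_tot += len(p)
        assert n_sig / n_tot < 0.02

    def test_planted_fold8_gives_high_specialization(self):
        """Monte-Carlo over seeds: a fold-8 gene with 3 focal replicates scores
        an index above 4 in ~92% of draws under the generator's noise model."""
        hits = 0
        n = 300
        for seed in range(n):
            cfg = SimulationConfig(
                seed=seed,
                n_genes=5,
                planted_specialized=(("g00001", "venom_gland", 8.0),),
                planted_secreted=(),
            )
            m, _ = simulate_expression(cfg)
            idx = specialization_index(
                m, "g00001", m.samples_for_tissue("venom_gland")
            ).index
            hits += idx > 4
        assert hits / n >= 0.88


class TestPeptideEvidence:
    def _setup(self, seed=0, detection=0.8):
        cfg = SimulationConfig(
            seed=seed,
            n_genes=30,
            planted_specialized=tuple(
                (f"g{i:05d}", "venom_gland", 8.0) for i in range(1, 6)
            ),
            planted_secreted=tuple(f"g{i:05d}" for i in range(1, 6)),
            peptide_detection_prob=detection,
        )
        matrix, truth = simulate_expression(cfg)
        proteins = simulate_proteins(cfg)
        return cfg, truth, proteins

    def test_detection_prob_one_emits_all_eligible(self):
        cfg, truth, proteins = self._setup(detection=1.0)
        table = simulate_peptide_evidence(proteins, truth, cfg)
        by_id = {p.identifier: p for p in proteins}
        expected = sorted(
            pep
            for g in truth.secreted
            for pep in eligible_peptides(by_id[g].sequence)
        )
        assert sorted(table["peptide"]) == expected

    def test_detection_prob_zero_empty(self):
        cfg, truth, proteins = self._setup(detection=0.0)
        assert len(simulate_peptide_evidence(proteins, truth, cfg)) == 0

    def test_missing_secreted_protein_rejected(self):
        cfg, truth, proteins = self._setup()
        with pytest.raises(InputError):
            simulate_peptide_evidence(proteins[:2], truth, cfg)

    def test_binomial_mean_detected_peptides(self):
        """A protein with 10 eligible peptides at p = 0.8 yields on average
        8 detected peptides (binomial mean), within 0.1 over many seeds."""
        from effectorscan.effectors import ProteinRecord
        from effectorscan.simulate import SyntheticTruth

        blocks = [f"AAA{a}{b}K" for a in "ACDEF" for b in "GH"]  # 10 distinct
        protein = ProteinRecord("gsec", "".join(blocks))
        assert len(eligible_peptides(protein.sequence)) == 10
        truth = SyntheticTruth({}, ["gsec"], "X", {})
        counts = []
        for seed in range(2000):
            cfg = SimulationConfig(
                seed=seed, n_genes=0, planted_specialized=(), planted_secreted=()
            )
            table = simulate_peptide_evidence([protein], truth, cfg)
            counts.append(table["peptide"].nunique())
        assert abs(np.mean(counts) - 8.0) < 0.1


class TestDomainCounts:
    def test_planted_focal_count_exact(self):
        cfg = SimulationConfig(seed=1)
        table = simulate_domain_counts(cfg)
        assert table.counts.loc["focal_sp", cfg.planted_domain[0]] == 29

    def test_zero_lambda_degenerate(self):
        cfg = SimulationConfig(seed=1, planted_domain=("IPR900001", 29, 0.0))
        table = simulate_domain_counts(cfg)
        non_planted = table.counts.drop(columns=[cfg.planted_domain[0]])
        assert (non_planted.to_numpy() == 0).all()

    def test_negative_focal_count_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(planted_domain=("IPR900001", -1, 2.0))


class TestAssays:
    def test_forced_outcomes(self):
        cfg = SimulationConfig(
            seed=0, assay_probs={(1, "mono"): (1.0, 1.0)}, n_assay_replicates=2
        )
        parasitism, _, _ = simulate_assays(cfg)
        for rec in parasitism:
            assert rec.n_emerged_host_adults == 0
            assert rec.n_emerged_wasps == 20

    def test_zero_parasitism_forced(self):
        cfg = SimulationConfig(
            seed=0, assay_probs={(1, "mono"): (0.0, 0.0)}, n_assay_replicates=3
        )
        parasitism, _, _ = simulate_assays(cfg)
        for rec in parasitism:
            assert rec.n_emerged_host_adults == 20 and rec.n_emerged_wasps == 0

    def test_emergence_exceeding_parasitism_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(assay_probs={(1, "mono"): (0.3, 0.5)})

    def test_unbiased_choice_mean_index_near_zero(self):
        """With no side preference the mean oviposition index over thousands
        of replicates sits within 2 points of 0 (generator symmetry)."""
        cfg = SimulationConfig(
            seed=9,
            choice_ages=(1,),
            choice_durations=(2.0,),
            n_choice_replicates=5000,
        )
        _, choice, _ = simulate_assays(cfg)
        idx = [
            (r.n1 - r.nx) / (r.n1 + r.nx) * 100 for r in choice if r.n1 + r.nx > 0
        ]
        assert abs(np.mean(idx)) < 2.0

    def test_record_invariant_always_holds(self):
        """Joint per-host draws guarantee adults + wasps <= hosts."""
        for seed in range(30):
            parasitism, _, _ = simulate_assays(SimulationConfig(seed=seed))
            for rec in parasitism:
                assert rec.n_emerged_host_adults + rec.n_emerged_wasps <= rec.n_hosts


class TestReproducibility:
    def test_identical_config_emits_identical_files(self, tmp_path):
        cfg = dict(
            seed=4,
            n_genes=60,
            planted_specialized=(("g00001", "venom_gland", 8.0),),
            planted_secreted=("g00001",),
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(SimulationConfig(**cfg), d1)
        simulate_all(SimulationConfig(**cfg), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_stream_independence(self):
        """Changing the assay design leaves the expression draw untouched."""
        base = SimulationConfig(seed=6, n_genes=40,
                                planted_specialized=(), planted_secreted=())
        alt = SimulationConfig(seed=6, n_genes=40,
                               planted_specialized=(), planted_secreted=(),
                               n_assay_replicates=12)
        m1, _ = simulate_expression(base)
        m2, _ = simulate_expression(alt)
        assert m1.values.equals(m2.values)

    def test_truth_consistency(self, small_sim_dir):
        outdir, config = small_sim_dir
        from effectorscan.io import read_expression_table, read_fasta
        from effectorscan.simulate import SyntheticTruth

        truth = SyntheticTruth.from_json((outdir / "truth.json").read_text())
        matrix = read_expression_table(outdir / "expression.tsv", outdir / "metadata.tsv")
        proteins = {p.identifier for p in read_fasta(outdir / "proteins.fasta")}
        tissues = set(matrix.metadata["tissue"])
        for gene, (tissue, _) in truth.specialized.items():
            assert tissue in tissues
        assert set(truth.secreted) <= proteins
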