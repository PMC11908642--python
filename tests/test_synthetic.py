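import numpy as np
import pytest
from scipy import stats

import tcrdyn as t
from tcrdyn.encoding import AMINO_ACIDS
from tcrdyn.synthetic import (
    NATURAL_FREQUENCIES,
    CapacityError,
    ConfigurationError,
    ParseError,
)


class TestGenerateRepertoire:
    def test_counts_and_determinism(self):
        spec = t.SyntheticDatasetSpec(n_cdr3=100, n_antigen=20, seed=7)
        a1, c1 = t.generate_repertoire(spec)
        a2, c2 = t.generate_repertoire(spec)
        assert len(a1) == 20 and len(c1) == 100
        assert a1 == a2 and c1 == c2

    def test_different_seeds_differ(self):
        a1, c1 = t.generate_repertoire(t.SyntheticDatasetSpec(seed=1))
        a2, c2 = t.generate_repertoire(t.SyntheticDatasetSpec(seed=2))
        assert c1 != c2

    def test_lengths_within_ranges(self, small_pools):
        spec, antigens, cdr3s = small_pools
        assert {len(a.residues) for a in antigens} <= set(range(8, 12))
        assert {len(c.residues) for c in cdr3s} <= set(range(8, 21))

    def test_canonical_cdr3_termini(self, small_pools):
        _, _, cdr3s = small_pools
        assert all(c.residues.startswith("C") and c.residues.endswith("F") for c in cdr3s)

    def test_zero_counts_rejected(self):
        with pytest.raises(ConfigurationError, match="n_cdr3"):
            t.SyntheticDatasetSpec(n_cdr3=0)

    def test_bad_frequencies_rejected(self):
        freqs = np.full(20, 0.05)
        freqs[0] = 0.5
        with pytest.raises(ConfigurationError, match="sum to 1"):
            t.SyntheticDatasetSpec(residue_frequencies=freqs)

    def test_iid_mode_residue_frequencies_chi2(self):
        """In iid mode (templates off) the non-terminal residues follow the
        configured background distribution (chi-square GOF, alpha=0.01)."""
        spec = t.SyntheticDatasetSpec(
            n_cdr3=7000, n_antigen=2000, seed=23,
            n_v_fragments=0, n_j_fragments=0, n_antigen_motifs=0, n_antigen_variable=0,
        )
        antigens, cdr3s = t.generate_repertoire(spec)
        pooled = "".join(a.residues for a in antigens)
        pooled += "".join(c.residues[1:-1] for c in cdr3s)
        assert len(pooled) >= 100_000
        counts = np.array([pooled.count(aa) for aa in AMINO_ACIDS])
        result = stats.chisquare(counts, f_exp=len(pooled) * NATURAL_FREQUENCIES)
        assert result.pvalue > 0.01


class TestPretrainCorpus:
    def test_repair_mode_uses_each_cdr3_once_per_epoch(self, small_pools):
        _, antigens, cdr3s = small_pools
        corpus = t.build_pretrain_corpus(antigens, cdr3s, "repair_per_epoch", seed=3)
        for epoch in (0, 1):
            pairs = corpus.pairs_for_epoch(epoch)
            assert sorted(c.id for _, c in pairs) == sorted(c.id for c in cdr3s)

    def test_repair_mode_pairings_differ_across_epochs(self, small_pools):
        _, antigens, cdr3s = small_pools
        corpus = t.build_pretrain_corpus(antigens, cdr3s[:50], "repair_per_epoch", seed=3)
        for e in range(10):
            a = [x.id for x, _ in corpus.pairs_for_epoch(e)]
            b = [x.id for x, _ in corpus.pairs_for_epoch(e + 1)]
            assert a != b

    def test_repair_mode_deterministic_per_epoch(self, small_pools):
        _, antigens, cdr3s = small_pools
        corpus = t.build_pretrain_corpus(antigens, cdr3s, "repair_per_epoch", seed=3)
        assert corpus.pairs_for_epoch(4) == corpus.pairs_for_epoch(4)

    def test_static_mode_reuses_one_pairing(self, small_pools):
        _, antigens, cdr3s = small_pools
        corpus = t.build_pretrain_corpus(antigens, cdr3s, "static_paired", seed=3)
        assert corpus.pairs_for_epoch(0) == corpus.pairs_for_epoch(17)

    def test_cdr3_only_mode_has_no_antigen_portion(self, small_pools):
        _, antigens, cdr3s = small_pools
        corpus = t.build_pretrain_corpus(antigens, cdr3s, "cdr3_only", seed=3)
        assert corpus.antigens == ()
        assert all(a is None for a, _ in corpus.pairs_for_epoch(0))

    def test_empty_pools_rejected(self, small_pools):
        _, antigens, cdr3s = small_pools
        with pytest.raises(ConfigurationError):
            t.build_pretrain_corpus(antigens, [], "static_paired", seed=0)
        with pytest.raises(ConfigurationError):
            t.build_pretrain_corpus([], cdr3s, "static_paired", seed=0)


@pytest.fixture(scope="module")
def dataset(small_pools):
    spec, antigens, cdr3s = small_pools
    return t.build_finetune_dataset(
        antigens, cdr3s, spec.binding_rule, n_positive=60, neg_ratio=1.0, seed=9
    )


class TestFinetuneDataset:
    def test_counts_and_balance(self, dataset):
        assert len(dataset) == 120
        assert sum(p.label for p in dataset) == 60

    def test_rule_holds_exhaustively(self, small_pools, dataset):
        """Every positive shares a length-3 substring between antigen and
        CDR3 interior; no negative does; pair sets are disjoint."""
        spec, _, _ = small_pools
        rule = spec.binding_rule
        for p in dataset:
            assert rule.evaluate(p.antigen, p.cdr3) == bool(p.label)
        pos = {(p.antigen.residues, p.cdr3.residues) for p in dataset if p.label == 1}
        neg = {(p.antigen.residues, p.cdr3.residues) for p in dataset if p.label == 0}
        assert not pos & neg

    def test_negatives_repair_positive_members(self, dataset):
        pos_antigens = {p.antigen.residues for p in dataset if p.label == 1}
        pos_cdr3s = {p.cdr3.residues for p in dataset if p.label == 1}
        for p in dataset:
            if p.label == 0:
                assert p.antigen.residues in pos_antigens
                assert p.cdr3.residues in pos_cdr3s

    def test_deterministic_given_seed(self, small_pools):
        spec, antigens, cdr3s = small_pools
        kw = dict(n_positive=30, neg_ratio=1.0, seed=4)
        d1 = t.build_finetune_dataset(antigens, cdr3s, spec.binding_rule, **kw)
        d2 = t.build_finetune_dataset(antigens, cdr3s, spec.binding_rule, **kw)
        assert d1 == d2

    def test_neg_ratio_scales_negatives(self, small_pools):
        spec, antigens, cdr3s = small_pools
        ds = t.build_finetune_dataset(
            antigens, cdr3s, spec.binding_rule, n_positive=40, neg_ratio=2.0, seed=4
        )
        assert sum(1 - p.label for p in ds) == 80

    def test_capacity_error_when_pools_too_small(self, small_pools):
        spec, antigens, cdr3s = small_pools
        with pytest.raises(CapacityError):
            t.build_finetune_dataset(
                antigens[:2], cdr3s[:2], spec.binding_rule, n_positive=500, seed=0
            )

    def test_random_rule_labels_independent_of_content(self, small_pools):
        """Under the no-signal rule the label is a seeded hash of the pair, so
        simple content covariates carry no information."""
        _, antigens, cdr3s = small_pools
        rule = t.BindingRule(kind=t.RuleKind.RANDOM, k=1, params={"p": 0.5})
        ds = t.build_finetune_dataset(antigens, cdr3s, rule, n_positive=100, seed=2)
        labels = np.array([p.label for p in ds])
        lengths = np.array([len(p.cdr3.residues) for p in ds])
        assert abs(np.corrcoef(labels, lengths)[0, 1]) < 0.2


class TestRoundTrips:
    def test_fasta_round_trip(self, small_pools, tmp_path):
        _, antigens, cdr3s = small_pools
        path = tmp_path / "pool.fasta"
        t.write_fasta(antigens + cdr3s, path)
        back = t.read_fasta(path)
        assert back == antigens + cdr3s

    def test_pairs_csv_round_trip(self, small_pools, tmp_path):
        spec, antigens, cdr3s = small_pools
        pairs = t.build_finetune_dataset(antigens, cdr3s, spec.binding_rule,
                                         n_positive=20, seed=1)
        path = tmp_path / "pairs.csv"
        t.write_pairs_csv(pairs, path)
        back = t.read_pairs_csv(path)
        assert [(p.antigen.residues, p.cdr3.residues, p.label) for p in back] == [
            (p.antigen.residues, p.cdr3.residues, p.label) for p in pairs
        ]

    def test_lowercase_fasta_uppercased(self, tmp_path):
        path = tmp_path / "lower.fasta"
        path.write_text(">seq1 role=cdr3\ncassf\n")
        (rec,) = t.read_fasta(path)
        assert rec.residues == "CASSF"

    def test_ambiguity_codes_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">seq1 role=antigen\nSIINXFEKL\n")
        with pytest.raises(ParseError, match="alphabet"):
            t.read_fasta(path)

    def test_invalid_csv_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("antigen,cdr3,label\nSIINFEKL,CASSF,2\n")
        with pytest.raises(ParseError, match="line 2"):
            t.read_pairs_csv(path)

    def test_csv_header_enforced(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\nSIINFEKL,CASSF,1\n")
        with pytest.raises(ParseError, match="line 1"):
            t.read_pairs_csv(path)
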