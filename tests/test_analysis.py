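import numpy as np
import pytest
from Bio.Align import substitution_matrices

import tcrdyn as t
from tcrdyn.analysis import AnalysisError
from tcrdyn.training import LossCurve, SweepResult


def make_sweep(epochs, aurocs, sds=None):
    sds = sds or [0.0] * len(epochs)
    return SweepResult(
        epochs=list(epochs),
        records=[{"epoch": e, "dataset": "d", "split": 0, "auroc": a, "auprc": a}
                 for e, a in zip(epochs, aurocs)],
        mean_auroc=dict(zip(epochs, aurocs)),
        sd_auroc=dict(zip(epochs, sds)),
        mean_auprc=dict(zip(epochs, aurocs)),
        sd_auprc=dict(zip(epochs, sds)),
        per_dataset_mean_auroc={e: {"d": a} for e, a in zip(epochs, aurocs)},
        manifest=[],
    )


def make_curve(losses):
    curve = LossCurve()
    for i, loss in enumerate(losses, start=1):
        curve.append(i, loss, loss)
    return curve


class TestThresholdReport:
    def test_hand_worked_example(self):
        """losses [2.0,1.5,0.9,0.8,0.7] with AUROCs [.60,.65,.70,.68,.72]:
        crossing at epoch 3; post mean 0.70, sample SD 0.02; best epoch 5
        sits +1.0 SD above the mean."""
        curve = make_curve([2.0, 1.5, 0.9, 0.8, 0.7])
        result = make_sweep([1, 2, 3, 4, 5], [0.60, 0.65, 0.70, 0.68, 0.72])
        report = t.threshold_report(curve, result, threshold=1.0, series="train")
        assert report.crossed and report.first_crossing_epoch == 3
        assert report.post_threshold_epochs == [3, 4, 5]
        assert report.post_mean_auroc == pytest.approx(0.70)
        assert report.post_sd_auroc == pytest.approx(0.02)
        assert report.best_epoch == 5
        assert report.best_deviation_in_sd == pytest.approx(1.0)
        assert report.exceeds_2sd is False

    def test_no_crossing_is_a_result_not_an_error(self):
        curve = make_curve([3.0, 2.5, 2.2])
        report = t.threshold_report(curve, make_sweep([1, 2, 3], [0.5, 0.6, 0.7]))
        assert not report.crossed
        assert report.first_crossing_epoch is None
        assert report.post_threshold_epochs == []
        assert report.best_epoch == 3  # best over swept checkpoints still reported

    def test_single_post_threshold_checkpoint_flags_sd_undefined(self):
        curve = make_curve([2.0, 1.5, 0.9])
        report = t.threshold_report(curve, make_sweep([1, 2, 3], [0.5, 0.6, 0.7]))
        assert report.crossed and not report.sd_defined
        assert report.post_sd_auroc is None and report.best_deviation_in_sd is None

    def test_zero_variance_leaves_deviation_undefined(self):
        curve = make_curve([2.0, 0.9, 0.8, 0.7])
        report = t.threshold_report(curve, make_sweep([1, 2, 3, 4], [0.5, 0.7, 0.7, 0.7]))
        assert report.post_sd_auroc == pytest.approx(0.0, abs=1e-12)
        assert report.best_deviation_in_sd is None

    def test_two_sd_flag_fires_on_outlier_best(self):
        # the best value is part of the post-threshold sample, so with n post
        # checkpoints its deviation is bounded by (n-1)/sqrt(n); eight post
        # epochs leave room for an outlier beyond 2 SD
        losses = [2.0] + [0.9 - 0.1 * i for i in range(8)]
        aurocs = [0.50] + [0.70] * 7 + [0.80]
        curve = make_curve(losses)
        report = t.threshold_report(curve, make_sweep(range(1, 10), aurocs))
        assert report.best_epoch == 9
        assert report.best_deviation_in_sd > 2
        assert report.exceeds_2sd is True

    def test_tie_prefers_earliest_epoch(self):
        curve = make_curve([0.9, 0.8, 0.7])
        report = t.threshold_report(curve, make_sweep([1, 2, 3], [0.7, 0.7, 0.6]))
        assert report.best_epoch == 1

    def test_stride_subset_of_loss_curve_accepted(self):
        curve = make_curve([2.0, 1.5, 0.9, 0.8, 0.7, 0.6])
        report = t.threshold_report(curve, make_sweep([2, 4, 6], [0.6, 0.7, 0.71]))
        assert report.post_threshold_epochs == [4, 6]

    def test_invariant_to_reordered_records(self):
        curve = make_curve([2.0, 0.9, 0.8])
        fwd = make_sweep([1, 2, 3], [0.5, 0.7, 0.6])
        rev = make_sweep([3, 2, 1], [0.6, 0.7, 0.5])
        a = t.threshold_report(curve, fwd)
        b = t.threshold_report(curve, rev)
        assert (a.post_mean_auroc, a.post_sd_auroc, a.best_epoch) == (
            b.post_mean_auroc, b.post_sd_auroc, b.best_epoch)


# -- global alignment -------------------------------------------------------


def enumerate_alignments(a, b):
    """Yield every global alignment as a pair of gapped strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(row_a, row_b, sub, gap_open, gap_extend):
    """Affine-gap score: each gap run costs open + (len-1) * extend."""
    score, prev = 0.0, None
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            state = "ga" if x == "-" else "gb"
            score += gap_extend if state == prev else gap_open
            prev = state
        else:
            score += sub[x][y]
            prev = "m"
    return score


def brute_force_nw(a, b, params):
    if params.matrix == "identity":
        sub = {x: {y: (1.0 if x == y else -1.0) for y in set(a + b)} for x in set(a + b)}
    else:
        m = substitution_matrices.load(params.matrix)
        sub = {x: {y: float(m[x, y]) for y in set(a + b)} for x in set(a + b)}
    return max(
        score_alignment(ra, rb, sub, params.gap_open, params.gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


class TestNeedlemanWunsch:
    def test_self_alignment_blosum_diagonal(self):
        seq = "CASSLGF"
        blosum = substitution_matrices.load("BLOSUM62")
        expected = sum(float(blosum[c, c]) for c in seq)
        score, identity = t.needleman_wunsch(seq, seq)
        assert score == pytest.approx(expected)
        assert identity == pytest.approx(100.0)

    def test_textbook_linear_gap_example(self):
        # 3x2 DP table: ACD vs AD aligns A-CD over A--D, one internal gap
        params = t.AlignmentParams(matrix="identity", gap_open=-1, gap_extend=-1)
        score, identity = t.needleman_wunsch("ACD", "AD", params)
        assert score == pytest.approx(1.0)
        assert identity == pytest.approx(100 * 2 / 3, abs=0.1)

    def test_empty_sequence_defined(self):
        score, identity = t.needleman_wunsch("", "ACD")
        assert identity == 0.0
        assert score == pytest.approx(-10.0 + 2 * -0.5)

    @pytest.mark.parametrize("matrix", ["identity", "BLOSUM62"])
    def test_matches_brute_force_enumeration(self, matrix):
        """The DP result equals exhaustive enumeration of all global
        alignments for short sequences (affine gap scoring)."""
        rng = np.random.default_rng(0)
        params = t.AlignmentParams(matrix=matrix, gap_open=-4, gap_extend=-1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = "".join(rng.choice(aas, rng.integers(1, 7)))
            b = "".join(rng.choice(aas, rng.integers(1, 7)))
            score, _ = t.needleman_wunsch(a, b, params)
            assert score == pytest.approx(brute_force_nw(a, b, params))

    def test_symmetric_for_symmetric_matrices(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, rng.integers(3, 10)))
            b = "".join(rng.choice(aas, rng.integers(3, 10)))
            assert t.needleman_wunsch(a, b)[0] == pytest.approx(t.needleman_wunsch(b, a)[0])


class TestSimilarityReport:
    def test_self_comparison_gives_full_identity(self):
        rec = t.SequenceRecord("x", "CASSLGELFF", t.Role.CDR3)
        report = t.similarity_report([rec], [rec], t.AlignmentParams(n_sampled_pairs=5))
        assert report.mean_percent_identity["cdr3"] == pytest.approx(100.0)

    def test_related_sets_more_similar_than_unrelated(self):
        spec_a = t.SyntheticDatasetSpec(n_cdr3=60, n_antigen=20, seed=100)
        ants_a, cdrs_a = t.generate_repertoire(spec_a)
        # same template pools -> related; new seed -> different templates
        ants_a2, cdrs_a2 = t.generate_repertoire(
            t.SyntheticDatasetSpec(n_cdr3=60, n_antigen=20, seed=100)
        )
        ants_b, cdrs_b = t.generate_repertoire(
            t.SyntheticDatasetSpec(n_cdr3=60, n_antigen=20, seed=200)
        )
        params = t.AlignmentParams(n_sampled_pairs=120, seed=5)
        related = t.similarity_report(ants_a + cdrs_a, ants_a2 + cdrs_a2, params)
        unrelated = t.similarity_report(ants_a + cdrs_a, ants_b + cdrs_b, params)
        for role in ("antigen", "cdr3"):
            assert related.mean_percent_identity[role] > unrelated.mean_percent_identity[role]

    def test_absent_role_skipped(self):
        cdr = t.SequenceRecord("x", "CASSLGELFF", t.Role.CDR3)
        report = t.similarity_report([cdr], [cdr], t.AlignmentParams(n_sampled_pairs=3))
        assert report.skipped_roles == ["antigen"]
        assert "antigen" not in report.mean_score

    def test_deterministic_given_seed(self, small_pools):
        _, antigens, cdr3s = small_pools
        params = t.AlignmentParams(n_sampled_pairs=30, seed=9)
        a = t.similarity_report(antigens + cdr3s, antigens + cdr3s, params)
        b = t.similarity_report(antigens + cdr3s, antigens + cdr3s, params)
        assert a.mean_score == b.mean_score

    def test_invalid_params_rejected(self):
        with pytest.raises(AnalysisError):
            t.AlignmentParams(n_sampled_pairs=0)
        with pytest.raises(AnalysisError):
            t.AlignmentParams(gap_open=2.0)
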