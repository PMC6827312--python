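"""Profile HMM estimation, scoring, the two-condition assignment rule, and PR counting."""

import math

import numpy as np
import pytest

from ssnfam import hmm
from ssnfam.alphabet import AA20, BACKGROUND
from ssnfam.hmm import (
    Assignment,
    HmmError,
    HMMLibrary,
    _assignment_from_ranked,
    assign_subfamily,
    background_model,
    build_library,
    build_profile_hmm,
    evaluate_library,
    score_sequence,
)
from ssnfam.msa import Msa
from ssnfam.seqio import SequenceRecord
from ssnfam.synth import SynthConfig, generate_families

BASE = (
    "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQTLSEQVQEELLS"
    "SQVTQELRALMDETMKELKAYKSELEEQLTPVAEETRARLSKELQAAQARLGADMEDVCGRLVQYRGEVQA"
)


def single_seq_model(residues=BASE, name="m", seed=0, draws=60):
    model = build_profile_hmm(Msa(ids=["x"], rows=[residues]), name=name)
    return model.calibrate(n_random=draws, seed=seed)


class TestBuildProfileHmm:
    def test_point_mass_emissions_without_pseudocounts(self):
        msa = Msa(ids=["a", "b", "c"], rows=["MKV", "MKV", "MKV"])
        model = build_profile_hmm(msa, pseudocount_weight=0.0)
        assert model.n_match == 3
        for j, aa in enumerate("MKV"):
            assert model.match_emissions[j, AA20.index(aa)] == pytest.approx(1.0)

    def test_probability_rows_normalized(self):
        records, _ = generate_families(
            SynthConfig(k=1, sizes=(8,), indel_rate=0.05, classes_per_subfamily=(1,), seed=2)
        )
        from ssnfam.msa import build_msa

        model = build_profile_hmm(build_msa(records))
        for rows in (model.match_emissions, model.tm, model.ti, model.td):
            assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
        assert model.begin.sum() == pytest.approx(1.0)

    def test_gap_majority_rule_excludes_heavy_gap_columns(self):
        rows = [
            "M-KV",
            "M-KV",
            "MAKV",
            "M-KV",
            "MAKV",
        ]  # column 1 has 60% gaps -> insert column
        model = build_profile_hmm(Msa(ids=list("abcde"), rows=rows))
        assert model.n_match == 3
        # exactly half gaps stays a match column
        rows50 = ["M-KV", "M-KV", "MAKV", "MAKV"]
        model50 = build_profile_hmm(Msa(ids=list("abcd"), rows=rows50))
        assert model50.n_match == 4

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(HmmError):
            build_profile_hmm(Msa(ids=["a", "b", "c"], rows=["M--", "-K-", "--V"]))


class TestScoring:
    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(5)
        model = single_seq_model()
        for _ in range(20):
            L = int(rng.integers(30, 300))
            seq = "".join(AA20[i] for i in rng.choice(20, size=L, p=BACKGROUND))
            assert model.forward_bits(seq) >= model.viterbi_bits(seq) - 1e-6

    def test_evalue_strictly_decreasing_in_bits(self):
        model = single_seq_model()
        log_es = [model.log10_evalue(b, search_space=100) for b in range(-50, 300, 25)]
        assert all(e1 > e2 for e1, e2 in zip(log_es, log_es[1:]))

    def test_consensus_beats_99pct_of_shuffles(self):
        model = single_seq_model(seed=3)
        own = model.forward_bits(BASE)
        rng = np.random.default_rng(17)
        residues = list(BASE)
        beaten = 0
        for _ in range(200):
            rng.shuffle(residues)
            if model.forward_bits("".join(residues)) < own:
                beaten += 1
        assert beaten >= 198

    def test_uncalibrated_model_cannot_score(self):
        model = build_profile_hmm(Msa(ids=["x"], rows=[BASE]))
        with pytest.raises(HmmError):
            score_sequence(BASE, model, search_space=10)

    def test_score_sequence_returns_floored_positive_evalue(self):
        model = single_seq_model()
        bits, evalue = score_sequence(BASE, model, search_space=10)
        assert bits > 100 and 0 < evalue <= 1e-30

    def test_x_residues_score_neutrally(self):
        model = single_seq_model()
        with_x = "XXX" + BASE[3:]
        assert model.forward_bits(with_x) < model.forward_bits(BASE)
        assert np.isfinite(model.forward_bits("X" * 50))


class TestAssignmentRule:
    def _ranked(self, pairs):
        return [(name, 0.0, log_e) for name, log_e in pairs]

    def test_clear_margin_assigned(self):
        a = _assignment_from_ranked(
            "p", self._ranked([("s1", -40.0), ("s2", -25.0)]), 1e-30, 1e10
        )
        assert a.predicted == "s1"

    def test_insufficient_fold_unassigned(self):
        a = _assignment_from_ranked(
            "p", self._ranked([("s1", -40.0), ("s2", -35.0)]), 1e-30, 1e10
        )
        assert a.predicted is None

    def test_weak_best_hit_unassigned_regardless_of_second(self):
        a = _assignment_from_ranked(
            "p", self._ranked([("s1", -20.0), ("s2", -1.0)]), 1e-30, 1e10
        )
        assert a.predicted is None

    def test_remainder_best_hit_never_predicts(self):
        a = _assignment_from_ranked(
            "p",
            self._ranked([(hmm.REMAINDER_NAME, -80.0), ("s1", -20.0)]),
            1e-30,
            1e10,
        )
        assert a.predicted is None and a.best_model == hmm.REMAINDER_NAME

    def test_single_model_second_evalue_infinite(self):
        a = _assignment_from_ranked("p", self._ranked([("s1", -40.0)]), 1e-30, 1e10)
        assert a.predicted == "s1" and math.isinf(a.evalue_second)

    def test_rule_monotone_in_ceiling_and_fold(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            log_best = -rng.uniform(0, 120)
            log_second = log_best + rng.uniform(0, 40)
            ranked = self._ranked([("s1", log_best), ("s2", log_second)])
            loose = _assignment_from_ranked("p", ranked, 1e-20, 1e10)
            tight = _assignment_from_ranked("p", ranked, 1e-40, 1e10)
            if tight.predicted:
                assert loose.predicted  # loosening the ceiling only adds
            low_fold = _assignment_from_ranked("p", ranked, 1e-30, 1e5)
            high_fold = _assignment_from_ranked("p", ranked, 1e-30, 1e15)
            if high_fold.predicted:
                assert low_fold.predicted  # raising the fold only removes


def _assignment(rid, predicted, log_e=-45.0):
    return Assignment(
        id=rid,
        predicted=predicted,
        best_model=predicted or hmm.REMAINDER_NAME,
        evalue_best=10.0**log_e,
        evalue_second=1.0,
        log10_evalue_best=log_e,
        log10_evalue_second=0.0,
    )


class TestEvaluateLibrary:
    REFERENCE = {"p1": "s1", "p2": "s1", "p3": "s2", "p4": None}

    def test_hand_enumerated_tp_fp_fn(self):
        predictions = [
            _assignment("p1", "s1"),
            _assignment("p2", "s2"),
            _assignment("p3", None),
            _assignment("p4", "s1"),
        ]
        (point,) = evaluate_library(predictions, self.REFERENCE, cutoffs=[1e-30])
        assert (point.tp, point.fp, point.fn) == (1, 2, 1)
        assert point.precision == pytest.approx(1 / 3)
        assert point.recall == pytest.approx(1 / 2)

    def test_perfect_predictions_give_unit_precision_recall(self):
        predictions = [
            _assignment("p1", "s1"),
            _assignment("p2", "s1"),
            _assignment("p3", "s2"),
            _assignment("p4", None),
        ]
        (point,) = evaluate_library(predictions, self.REFERENCE, cutoffs=[1e-30])
        assert point.precision == 1.0 and point.recall == 1.0

    def test_zero_predictions_convention(self):
        predictions = [_assignment(p, None) for p in self.REFERENCE]
        (point,) = evaluate_library(predictions, self.REFERENCE, cutoffs=[1e-30])
        assert point.recall == 0.0
        assert point.precision == 1.0 and point.zero_predictions

    def test_cutoff_deactivates_weak_predictions(self):
        predictions = [
            _assignment("p1", "s1", log_e=-35.0),
            _assignment("p2", "s1", log_e=-80.0),
            _assignment("p3", None),
            _assignment("p4", None),
        ]
        p30, p60 = evaluate_library(predictions, self.REFERENCE, cutoffs=[1e-30, 1e-60])
        assert (p30.tp, p60.tp) == (2, 1)
        assert p60.fn == 2

    def test_unknown_id_rejected(self):
        with pytest.raises(HmmError):
            evaluate_library([_assignment("zz", "s1")], self.REFERENCE, cutoffs=[1e-30])


class TestLibrary:
    def _tiny_library(self):
        rng = np.random.default_rng(31)
        seqs = {}
        for name in ("fam_a", "fam_b"):
            root = "".join(AA20[i] for i in rng.choice(20, size=120, p=BACKGROUND))
            seqs[name] = [
                SequenceRecord(id=f"{name}_{i}", residues=root) for i in range(3)
            ]
        return build_library(seqs, calibration_draws=40, seed=31)

    def test_s_plus_one_structure(self):
        lib = self._tiny_library()
        assert len(lib.models) == 3  # 2 subfamilies + remainder
        assert hmm.REMAINDER_NAME in [m.name for m in lib.models]
        assert lib.subfamily_names == ["fam_a", "fam_b"]

    def test_members_assigned_to_own_model(self):
        lib = self._tiny_library()
        rng = np.random.default_rng(31)
        for name in ("fam_a", "fam_b"):
            pass
        # rebuild the member sequences deterministically
        rng = np.random.default_rng(31)
        for name in ("fam_a", "fam_b"):
            root = "".join(AA20[i] for i in rng.choice(20, size=120, p=BACKGROUND))
            a = assign_subfamily(SequenceRecord(id="q", residues=root), lib)
            assert a.predicted == name

    def test_serialization_round_trip(self, tmp_path):
        lib = self._tiny_library()
        path = tmp_path / "lib.jsonl"
        lib.to_jsonl(path)
        back = HMMLibrary.from_jsonl(path)
        assert back.search_space == lib.search_space
        assert [m.name for m in back.models] == [m.name for m in lib.models]
        q = "".join(AA20[i] for i in np.random.default_rng(1).choice(20, size=100))
        for m1, m2 in zip(lib.models, back.models):
            assert m2.forward_bits(q) == pytest.approx(m1.forward_bits(q))
            assert m2.calibration.mu == pytest.approx(m1.calibration.mu)

    def test_background_remainder_is_insignificant(self):
        rem = background_model(120).calibrate(n_random=40, seed=1)
        rng = np.random.default_rng(2)
        seq = "".join(AA20[i] for i in rng.choice(20, size=120, p=BACKGROUND))
        assert rem.log10_evalue(rem.forward_bits(seq), search_space=100) > -5

    def test_empty_subfamily_rejected(self):
        with pytest.raises(HmmError):
            build_library({"s1": []})


class TestHmmerCrossCheck:
    def test_best_model_agreement_with_hmmer(self):
        """The simplified internal profiles rank families like HMMER's Plan7."""
        pyhmmer = pytest.importorskip("pyhmmer")
        from ssnfam import hmmer_backend

        config = SynthConfig(
            k=3,
            sizes=(10, 10, 10),
            within_divergence=0.12,
            classes_per_subfamily=(1, 1, 1),
            seed=41,
        )
        records, truth = generate_families(config)
        members: dict[str, list[SequenceRecord]] = {}
        for rec in records:
            members.setdefault(truth.partition[rec.id], []).append(rec)
        lib = build_library(members, calibration_draws=60, seed=41)
        internal = {
            a.id: a.predicted for a in hmm.scan(records, lib)
        }
        hmms = hmmer_backend.build_hmms(members)
        external = hmmer_backend.best_models(records, hmms)
        for rec in records:
            assert internal[rec.id] == external[rec.id] == truth.partition[rec.id]
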