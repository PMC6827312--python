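"""Per-subfamily profile-HMM library, assignment rule, and precision/recall.

For a candidate partition into S subfamilies, an S+1 model library is built:
one profile HMM per subfamily (members reduced to 75% identity, aligned, then
turned into a match/insert/delete profile) plus one remainder model for the
sequences outside any subfamily. Every sequence is scanned against the whole
library and assigned to the best-matching model's subfamily only if

    (i)  the best E-value is below the assignment ceiling (default 1e-30), and
    (ii) the second-best model's E-value is at least a fixed fold greater
         (default 1e10, i.e. ten orders of magnitude less significant).

Comparing these predictions with the partition that trained the library gives
TP/FP/FN counts and hence precision = TP/(TP+FP), recall = TP/(TP+FN): the
validation signal used to choose the delineation threshold.

The profile architecture is a simplified Plan7 (glocal, background-emitting
flanks, no entropy weighting or Dirichlet mixtures); E-values come from an
extreme-value (Gumbel) fit to the bit scores of random background sequences.
The model logic only needs correctly ranked E-values, not bit-exact HMMER
parity; a pyhmmer-based backend is available for cross-checking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .alphabet import AA20, BACKGROUND, encode
from .msa import Msa, build_msa, reduce_redundancy
from .seqio import SequenceRecord

REMAINDER_NAME = "remainder"
DEFAULT_BEST_CEILING = 1e-30
DEFAULT_FOLD = 1e10
DEFAULT_CALIBRATION_DRAWS = 200
DEFAULT_FLANK_LOOP = 0.9
#: Display floor for E-values; comparisons always use log10 E internally.
EVALUE_DISPLAY_FLOOR = 1e-300

#: Default grid of assignment ceilings for precision/recall tables.
DEFAULT_PR_CUTOFFS: tuple[float, ...] = tuple(10.0 ** (-e) for e in range(5, 65, 5))

_LN10 = math.log(10.0)
EULER_GAMMA = 0.5772156649015329
#: Floor on the fitted Gumbel scale (bits).
MIN_GUMBEL_SCALE = 0.5


class HmmError(ValueError):
    pass


@dataclass
class Calibration:
    """Gumbel (location, scale) fitted to random-sequence bit scores."""

    mu: float
    beta: float

    def log10_pvalue(self, bits: float) -> float:
        """log10 P(random bit score >= bits), stable far into the tail."""
        z = (bits - self.mu) / self.beta
        if z > 30.0:
            # sf = 1 - exp(-exp(-z)) ~ exp(-z)
            return -z / _LN10
        t = math.exp(-z)
        sf = -math.expm1(-t)
        return math.log10(max(sf, 1e-320))


@dataclass
class ProfileHMM:
    """Simplified Plan7-like profile: M match columns with I/D companions.

    Transition rows are probabilities over the destinations (next match or
    end, own insert, next delete); the last column's delete destination is
    structurally zero. Emissions are per-column distributions over the 20
    standard residues; inserts and flanks emit the background.
    """

    name: str
    match_emissions: np.ndarray      # (M, 20)
    insert_emissions: np.ndarray     # (20,)
    tm: np.ndarray                   # (M, 3): M -> M/E, I, D
    ti: np.ndarray                   # (M, 3)
    td: np.ndarray                   # (M, 3)
    begin: np.ndarray                # (2,): B -> M1, D1
    flank_loop: float = DEFAULT_FLANK_LOOP
    calibration: Calibration | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        M = self.match_emissions.shape[0]
        if M < 1:
            raise HmmError("model must have at least one match column")
        for label, rows in (
            ("match emission", self.match_emissions),
            ("tm", self.tm),
            ("ti", self.ti),
            ("td", self.td),
        ):
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise HmmError(f"{self.name}: {label} rows must sum to 1")
        if not math.isclose(self.insert_emissions.sum(), 1.0, abs_tol=1e-9):
            raise HmmError(f"{self.name}: insert emissions must sum to 1")
        if not math.isclose(self.begin.sum(), 1.0, abs_tol=1e-9):
            raise HmmError(f"{self.name}: begin row must sum to 1")
        if self.tm[-1, 2] != 0.0 or self.ti[-1, 2] != 0.0 or self.td[-1, 2] != 0.0:
            raise HmmError(f"{self.name}: last column cannot transition to a delete")
        if not 0.0 < self.flank_loop < 1.0:
            raise HmmError("flank_loop must be in (0, 1)")

    @property
    def n_match(self) -> int:
        return int(self.match_emissions.shape[0])

    def _kernel_args(self) -> tuple:
        if "args" not in self._cache:
            with np.errstate(divide="ignore"):
                lem20 = np.log(self.match_emissions) - np.log(BACKGROUND)[None, :]
                lem = np.full((self.n_match, 21), 0.0)
                lem[:, :20] = np.where(
                    self.match_emissions > 0, lem20, _kernels.NEG_INF
                )
                # column 20: unknown residue (X) scores zero odds
                log = lambda a: np.where(a > 0, np.log(np.maximum(a, 1e-320)), _kernels.NEG_INF)
                self._cache["args"] = (
                    lem,
                    log(self.tm),
                    log(self.ti),
                    log(self.td),
                    float(np.log(self.begin[0])),
                    float(np.log(self.begin[1])) if self.begin[1] > 0 else _kernels.NEG_INF,
                    math.log(self.flank_loop),
                )
        return self._cache["args"]

    def forward_bits(self, residues: str) -> float:
        """Forward log2-odds (bit score) of a sequence against this model."""
        xs = encode(residues)
        lem, ltm, lti, ltd, lbm, lbd, lq = self._kernel_args()
        return _kernels.forward(xs, lem, ltm, lti, ltd, lbm, lbd, lq) / math.log(2.0)

    def viterbi_bits(self, residues: str) -> float:
        xs = encode(residues)
        lem, ltm, lti, ltd, lbm, lbd, lq = self._kernel_args()
        return _kernels.viterbi(xs, lem, ltm, lti, ltd, lbm, lbd, lq) / math.log(2.0)

    def calibrate(
        self,
        n_random: int = DEFAULT_CALIBRATION_DRAWS,
        length: int | None = None,
        seed: int = 0,
    ) -> "ProfileHMM":
        """Fit the E-value null by scoring random background sequences.

        Draws ``n_random`` i.i.d. background-composition sequences (length
        defaults to the model's match length) and fits a Gumbel distribution
        to their bit scores.
        """
        if n_random < 10:
            raise HmmError("calibration needs at least 10 draws")
        rng = np.random.default_rng(seed)
        L = length or self.n_match
        scores = np.empty(n_random)
        for i in range(n_random):
            idx = rng.choice(20, size=L, p=BACKGROUND)
            scores[i] = self.forward_bits("".join(AA20[j] for j in idx))
        # Method-of-moments Gumbel fit; the scale is floored so that models
        # with (near-)constant null scores — e.g. the flat remainder model —
        # cannot claim unbounded significance for scores barely above the null.
        beta = max(float(scores.std(ddof=1)) * math.sqrt(6.0) / math.pi, MIN_GUMBEL_SCALE)
        mu = float(scores.mean()) - EULER_GAMMA * beta
        self.calibration = Calibration(mu=mu, beta=beta)
        return self

    def log10_evalue(self, bits: float, search_space: int) -> float:
        if self.calibration is None:
            raise HmmError(f"model {self.name!r} is not calibrated")
        if search_space < 1:
            raise HmmError("search_space must be >= 1")
        return math.log10(search_space) + self.calibration.log10_pvalue(bits)


def score_sequence(
    seq: SequenceRecord | str, model: ProfileHMM, search_space: int
) -> tuple[float, float]:
    """(bit score, E-value) of one sequence against one calibrated model."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    bits = model.forward_bits(residues)
    log10_e = model.log10_evalue(bits, search_space)
    return bits, max(10.0 ** max(log10_e, -320.0), EVALUE_DISPLAY_FLOOR)


def build_profile_hmm(
    msa: Msa,
    pseudocount_weight: float = 1.0,
    background: np.ndarray = BACKGROUND,
    max_gap_fraction: float = 0.5,
    transition_pseudocount: float = 1.0,
    name: str = "model",
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Columns with at most ``max_gap_fraction`` gaps become match states.
    Match emissions are (counts + pseudocount_weight * background) normalized;
    transitions are counted from each row's implied state path with a uniform
    pseudocount. Insert runs before the first or after the last match column
    belong to the flanks and are not counted.
    """
    n_cols = msa.n_columns
    gap_frac = [
        sum(row[c] == "-" for row in msa.rows) / msa.n_rows for c in range(n_cols)
    ]
    match_cols = [c for c in range(n_cols) if gap_frac[c] <= max_gap_fraction]
    if not match_cols:
        raise HmmError("alignment has no match columns under the gap-majority rule")
    M = len(match_cols)
    aa_index = {a: i for i, a in enumerate(AA20)}

    counts = np.zeros((M, 20))
    for row in msa.rows:
        for j, c in enumerate(match_cols):
            ch = row[c]
            if ch in aa_index:
                counts[j, aa_index[ch]] += 1.0
    emissions = counts + pseudocount_weight * background[None, :]
    emissions /= emissions.sum(axis=1, keepdims=True)

    # transition counts; destination order: next-match/end, insert, next-delete
    cm = np.zeros((M, 3))
    ci = np.zeros((M, 3))
    cd = np.zeros((M, 3))
    cb = np.zeros(2)
    match_set = set(match_cols)
    for row in msa.rows:
        states = ["M" if row[c] != "-" else "D" for c in match_cols]
        inserts = []  # residues in insert columns between match columns j and j+1
        for j in range(M - 1):
            lo, hi = match_cols[j] + 1, match_cols[j + 1]
            inserts.append(
                sum(1 for c in range(lo, hi) if c not in match_set and row[c] != "-")
            )
        cb[0 if states[0] == "M" else 1] += 1.0
        for j in range(M - 1):
            src = cm if states[j] == "M" else cd
            dst_idx = 0 if states[j + 1] == "M" else 2
            if inserts[j] == 0:
                src[j, dst_idx] += 1.0
            else:
                src[j, 1] += 1.0
                ci[j, 1] += inserts[j] - 1.0
                ci[j, dst_idx] += 1.0
        # last column exits to E (destination 0), possibly via C-flank inserts
        (cm if states[-1] == "M" else cd)[M - 1, 0] += 1.0

    for c in (cm, ci, cd):
        c += transition_pseudocount
        c[M - 1, 2] = 0.0  # no delete beyond the last column
        c /= c.sum(axis=1, keepdims=True)
    cb += transition_pseudocount
    cb /= cb.sum()

    return ProfileHMM(
        name=name,
        match_emissions=emissions,
        insert_emissions=background.copy(),
        tm=cm,
        ti=ci,
        td=cd,
        begin=cb,
    )


def background_model(n_match: int, name: str = REMAINDER_NAME) -> ProfileHMM:
    """A flat model emitting background everywhere (zero log-odds).

    Used as the remainder ("+1") model when no sequences fall outside the
    candidate subfamilies; it never outranks a real subfamily model.
    """
    M = max(int(n_match), 1)
    uniform3 = np.tile(np.array([[0.4, 0.3, 0.3]]), (M, 1))
    uniform3[M - 1] = [0.7, 0.3, 0.0]
    return ProfileHMM(
        name=name,
        match_emissions=np.tile(BACKGROUND, (M, 1)),
        insert_emissions=BACKGROUND.copy(),
        tm=uniform3.copy(),
        ti=uniform3.copy(),
        td=uniform3.copy(),
        begin=np.array([0.9, 0.1]),
    )


@dataclass
class HMMLibrary:
    """S subfamily models plus one remainder model, with a search-space size."""

    models: list[ProfileHMM]
    search_space: int

    def __post_init__(self) -> None:
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise HmmError("duplicate model names in library")
        if REMAINDER_NAME not in names:
            raise HmmError(f"library must include the {REMAINDER_NAME!r} model")
        if any(m.calibration is None for m in self.models):
            raise HmmError("all library models must be calibrated")

    @property
    def subfamily_names(self) -> list[str]:
        return [m.name for m in self.models if m.name != REMAINDER_NAME]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"search_space": self.search_space}) + "\n")
            for m in self.models:
                fh.write(json.dumps(_model_to_dict(m)) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "HMMLibrary":
        with open(path) as fh:
            header = json.loads(fh.readline())
            models = [_model_from_dict(json.loads(line)) for line in fh if line.strip()]
        return cls(models=models, search_space=int(header["search_space"]))


def _model_to_dict(m: ProfileHMM) -> dict:
    return {
        "name": m.name,
        "match_emissions": m.match_emissions.tolist(),
        "insert_emissions": m.insert_emissions.tolist(),
        "tm": m.tm.tolist(),
        "ti": m.ti.tolist(),
        "td": m.td.tolist(),
        "begin": m.begin.tolist(),
        "flank_loop": m.flank_loop,
        "calibration": [m.calibration.mu, m.calibration.beta] if m.calibration else None,
    }


def _model_from_dict(d: dict) -> ProfileHMM:
    cal = d.get("calibration")
    return ProfileHMM(
        name=d["name"],
        match_emissions=np.asarray(d["match_emissions"]),
        insert_emissions=np.asarray(d["insert_emissions"]),
        tm=np.asarray(d["tm"]),
        ti=np.asarray(d["ti"]),
        td=np.asarray(d["td"]),
        begin=np.asarray(d["begin"]),
        flank_loop=d["flank_loop"],
        calibration=Calibration(*cal) if cal else None,
    )


def build_library(
    subfamily_members: Mapping[str, Sequence[SequenceRecord]],
    remainder: Sequence[SequenceRecord] = (),
    redundancy_identity: float = 0.75,
    pseudocount_weight: float = 1.0,
    calibration_draws: int = DEFAULT_CALIBRATION_DRAWS,
    seed: int = 0,
    search_space: int | None = None,
    aligner=None,
) -> HMMLibrary:
    """Build the S+1 library from a candidate partition.

    Each subfamily's members are reduced to ``redundancy_identity``, aligned,
    modeled, and calibrated (per-model calibration seeds derive
    deterministically from ``seed``). An empty remainder set yields a flat
    background remainder model. ``search_space`` defaults to the total number
    of input sequences.
    """
    if not subfamily_members:
        raise HmmError("no subfamilies to model")
    total = sum(len(v) for v in subfamily_members.values()) + len(remainder)
    models: list[ProfileHMM] = []
    names = sorted(subfamily_members)
    child_seeds = np.random.SeedSequence(seed).spawn(len(names) + 1)
    for name, ss in zip(names, child_seeds):
        members = subfamily_members[name]
        if not members:
            raise HmmError(f"subfamily {name!r} has no members")
        reps = reduce_redundancy(members, identity=redundancy_identity)
        model = build_profile_hmm(
            build_msa(reps, aligner=aligner),
            pseudocount_weight=pseudocount_weight,
            name=str(name),
        )
        model.calibrate(n_random=calibration_draws, seed=int(ss.generate_state(1)[0] % 2**31))
        models.append(model)
    if remainder:
        reps = reduce_redundancy(remainder, identity=redundancy_identity)
        rem = build_profile_hmm(
            build_msa(reps, aligner=aligner),
            pseudocount_weight=pseudocount_weight,
            name=REMAINDER_NAME,
        )
    else:
        median_m = int(np.median([m.n_match for m in models]))
        rem = background_model(median_m)
    rem.calibrate(
        n_random=calibration_draws,
        seed=int(child_seeds[-1].generate_state(1)[0] % 2**31),
    )
    models.append(rem)
    return HMMLibrary(models=models, search_space=search_space or total)


@dataclass(frozen=True)
class Assignment:
    """One sequence's library result under the two-condition rule."""

    id: str
    predicted: str | None
    best_model: str
    evalue_best: float
    evalue_second: float
    log10_evalue_best: float
    log10_evalue_second: float


def _rank_models(
    residues: str, library: HMMLibrary
) -> list[tuple[str, float, float]]:
    """(name, bits, log10 E) for every model, most significant first."""
    scored = []
    for m in library.models:
        bits = m.forward_bits(residues)
        scored.append((m.name, bits, m.log10_evalue(bits, library.search_space)))
    scored.sort(key=lambda t: (t[2], t[0]))
    return scored


def _assignment_from_ranked(
    rid: str,
    ranked: Sequence[tuple[str, float, float]],
    best_ceiling: float,
    fold: float,
) -> Assignment:
    name, _, log10_best = ranked[0]
    log10_second = ranked[1][2] if len(ranked) > 1 else math.inf
    passes = log10_best < math.log10(best_ceiling) and (
        log10_second - log10_best >= math.log10(fold)
    )
    predicted = name if passes and name != REMAINDER_NAME else None
    to_e = lambda l: (
        math.inf if math.isinf(l) else max(10.0 ** max(l, -320.0), EVALUE_DISPLAY_FLOOR)
    )
    return Assignment(
        id=rid,
        predicted=predicted,
        best_model=name,
        evalue_best=to_e(log10_best),
        evalue_second=to_e(log10_second),
        log10_evalue_best=log10_best,
        log10_evalue_second=log10_second,
    )


def assign_subfamily(
    seq: SequenceRecord,
    library: HMMLibrary,
    best_ceiling: float = DEFAULT_BEST_CEILING,
    fold: float = DEFAULT_FOLD,
) -> Assignment:
    """Apply the two-condition assignment rule to one sequence.

    A hit whose best-matching model is the remainder model yields no
    subfamily prediction regardless of its E-values.
    """
    ranked = _rank_models(seq.residues, library)
    return _assignment_from_ranked(seq.id, ranked, best_ceiling, fold)


def scan(
    records: Sequence[SequenceRecord],
    library: HMMLibrary,
    best_ceiling: float = DEFAULT_BEST_CEILING,
    fold: float = DEFAULT_FOLD,
) -> list[Assignment]:
    """Assign every record against the library (deterministic order)."""
    return [
        assign_subfamily(rec, library, best_ceiling=best_ceiling, fold=fold)
        for rec in sorted(records, key=lambda r: r.id)
    ]


@dataclass(frozen=True)
class PRPoint:
    cutoff: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    zero_predictions: bool = False


def evaluate_library(
    predictions: Sequence[Assignment],
    reference: Mapping[str, str | None],
    cutoffs: Sequence[float] = DEFAULT_PR_CUTOFFS,
) -> list[PRPoint]:
    """Precision/recall of the predictions against reference assignments.

    At each cutoff, a prediction is in force iff the assignment passed the
    two-condition rule and its best E-value is below the cutoff. A prediction
    matching the reference subfamily is a TP; a prediction that contradicts
    the reference (or targets a reference-unassigned protein) is an FP; a
    reference-assigned protein with no prediction is an FN — a wrong
    prediction therefore counts once, as an FP. Precision is 1 by convention
    when there are no predictions (flagged on the point).
    """
    for a in predictions:
        if a.id not in reference:
            raise HmmError(f"prediction for unknown id {a.id!r}")
    points = []
    for cutoff in cutoffs:
        log_cut = math.log10(cutoff)
        tp = fp = fn = 0
        for a in predictions:
            ref = reference[a.id]
            pred = (
                a.predicted
                if a.predicted is not None and a.log10_evalue_best < log_cut
                else None
            )
            if pred is not None:
                if ref is not None and pred == ref:
                    tp += 1
                else:
                    fp += 1
            elif ref is not None:
                fn += 1
        zero = (tp + fp) == 0
        precision = 1.0 if zero else tp / (tp + fp)
        recall = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
        points.append(
            PRPoint(
                cutoff=cutoff, tp=tp, fp=fp, fn=fn,
                precision=precision, recall=recall, zero_predictions=zero,
            )
        )
    return points


def pr_table(points: Sequence[PRPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cutoff": p.cutoff, "TP": p.tp, "FP": p.fp, "FN": p.fn,
                "precision": p.precision, "recall": p.recall,
                "zero_predictions": p.zero_predictions,
            }
            for p in points
        ],
        columns=["cutoff", "TP", "FP", "FN", "precision", "recall", "zero_predictions"],
    )


def assignment_table(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": a.id,
                "predicted": a.predicted or "",
                "E_best": a.evalue_best,
                "E_second": a.evalue_second,
            }
            for a in assignments
        ],
        columns=["id", "predicted", "E_best", "E_second"],
    )
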