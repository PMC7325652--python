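"""Clonotype identification and trackability assessment.

An ID (diagnostic, high-burden) sample is screened for candidate clonotypes;
each candidate is then judged against five trackability criteria before it is
admitted to a patient's tracking profile:

1. locus share — at least 3% of all receptor sequences at its locus;
2. cell fraction — at least 0.2% of all nucleated cells in the sample;
3. separation — no more than 5 other less-abundant same-locus sequences with
   repertoire frequencies within a factor of 10;
4. evidence — at least 40 gDNA templates;
5. uniqueness — a uniqueness score high enough that a coincidentally
   identical rearrangement in an unrelated healthy repertoire is unlikely.

Sequences passing all five become tracked sequences, each with an allowed
Hamming-mutation budget N that grows with sequence complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .mrd import TrackedSequence, total_nucleated_cells
from .synthetic import ContrivedSample

CRITERIA = ("locus_share", "cell_fraction", "separation", "templates", "uniqueness")


@dataclass(frozen=True)
class TrackabilityCriteria:
    """Thresholds of the five trackability criteria."""

    min_locus_share: float = 0.03
    min_cell_fraction: float = 0.002
    max_near_neighbors: int = 5
    neighbor_ratio: float = 10.0
    min_templates: int = 40
    min_uniqueness: float = 2.0

    def __post_init__(self) -> None:
        if min(self.min_locus_share, self.min_cell_fraction, self.min_templates,
               self.min_uniqueness) <= 0 or self.max_near_neighbors < 0:
            raise InvalidParameterError("criteria thresholds must be positive")
        if self.neighbor_ratio <= 1:
            raise InvalidParameterError("neighbor_ratio must exceed 1")


@dataclass
class UniquenessDatabase:
    """Incidence of clonotype sequences across previously observed repertoires."""

    incidence: dict[str, int] = field(default_factory=dict)
    total_repertoires: int = 1_000_000

    def __post_init__(self) -> None:
        if self.total_repertoires < 1:
            raise InvalidParameterError("total_repertoires must be >= 1")
        if any(v < 0 for v in self.incidence.values()):
            raise InvalidParameterError("incidences must be >= 0")

    def lookup(self, sequence: str) -> int:
        return self.incidence.get(sequence, 0)


EMPTY_DATABASE = UniquenessDatabase()


@dataclass
class CandidateClonotype:
    sequence: str
    locus: str
    template_count: int
    locus_share: float
    cell_fraction: float
    uniqueness_score: float = float("nan")
    #: criterion name -> (passed, reason) once evaluated
    pass_flags: dict[str, tuple[bool, str]] = field(default_factory=dict)


@dataclass
class TrackingProfile:
    """The set of sequences tracked for one patient; all passed every criterion."""

    patient_id: str
    tracked: list[TrackedSequence] = field(default_factory=list)
    rejected: list[CandidateClonotype] = field(default_factory=list)


def uniqueness_score(sequence: str, db: UniquenessDatabase) -> float:
    """Uniqueness of a clonotype: add-one smoothed -log10 incidence rate.

    ``-log10((incidence + 1) / (total_repertoires + 1))``; higher means the
    sequence is less likely to arise independently in a healthy repertoire.
    A never-observed sequence in a database of 10^6 repertoires scores ~6;
    a sequence seen in every repertoire scores 0.
    """
    inc = db.lookup(sequence)
    return float(-np.log10((inc + 1) / (db.total_repertoires + 1)))


@dataclass(frozen=True)
class MutationTolerance:
    """Tiered mapping from uniqueness score to allowed Hamming mutations.

    Sequences below ``thresholds[0]`` get N = 0 (no tolerance: a non-unique
    sequence must match exactly so healthy look-alikes are not absorbed).
    Above each successive threshold the allowed fraction of mismatched
    nucleotides rises; N = min(cap, floor(length * fraction)).
    """

    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    fractions: tuple[float, ...] = (1 / 45, 2 / 45, 1 / 15)
    cap: int = 3


DEFAULT_TOLERANCE = MutationTolerance()


def allowed_mutations(
    sequence: str, score: float, tolerance: MutationTolerance = DEFAULT_TOLERANCE
) -> int:
    """Allowed-mutation budget N for a tracked sequence."""
    if not sequence:
        raise InvalidParameterError("sequence must be non-empty")
    frac = 0.0
    for thr, f in zip(tolerance.thresholds, tolerance.fractions):
        if score >= thr:
            frac = f
    if frac == 0.0:
        return 0
    return min(tolerance.cap, int(len(sequence) * frac))


def call_candidates(id_sample: ContrivedSample) -> list[CandidateClonotype]:
    """Enumerate candidate clonotypes in an ID sample.

    One candidate per distinct sequence, with its locus share
    (templates / locus total) and cell fraction (templates / total nucleated
    cells, quantified from the diploid reference amplicons). Uses reads when
    present, otherwise the per-sequence template table (locus unknown, tagged
    "IGH" by convention).
    """
    counts: dict[tuple[str, str], int] = {}
    if id_sample.reads:
        for r in id_sample.reads:
            key = (r.locus, r.sequence)
            counts[key] = counts.get(key, 0) + r.abundance
    elif id_sample.per_sequence_templates:
        for s, c in id_sample.per_sequence_templates.items():
            counts[("IGH", s)] = c
    else:
        return []

    locus_totals: dict[str, int] = {}
    for (locus, _), c in counts.items():
        locus_totals[locus] = locus_totals.get(locus, 0) + c
    cells = total_nucleated_cells(id_sample)

    out = []
    for (locus, seq), c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        lt = locus_totals[locus]
        out.append(
            CandidateClonotype(
                sequence=seq,
                locus=locus,
                template_count=c,
                locus_share=c / lt if lt else 0.0,
                cell_fraction=c / cells if cells else 0.0,
            )
        )
    return out


def _separation_count(
    cand: CandidateClonotype, candidates: list[CandidateClonotype], ratio: float
) -> int:
    """Same-locus, less-abundant sequences within a factor ``ratio`` in frequency.

    Ties in abundance count toward rejection (a tied sequence is treated as
    "less abundant but within range").
    """
    n = 0
    for other in candidates:
        if other is cand or other.locus != cand.locus:
            continue
        if other.template_count <= cand.template_count and (
            other.locus_share * ratio >= cand.locus_share
        ):
            n += 1
    return n


def select_trackable(
    candidates: list[CandidateClonotype],
    criteria: TrackabilityCriteria = TrackabilityCriteria(),
    db: UniquenessDatabase = EMPTY_DATABASE,
    *,
    patient_id: str = "patient-0",
    tolerance: MutationTolerance = DEFAULT_TOLERANCE,
) -> TrackingProfile:
    """Apply the five trackability criteria and build a tracking profile.

    Every rejected candidate records which criteria failed and why; an empty
    profile is a legitimate outcome (some diagnostic samples yield no
    trackable clonotype).
    """
    tracked: list[TrackedSequence] = []
    rejected: list[CandidateClonotype] = []
    for cand in candidates:
        score = uniqueness_score(cand.sequence, db)
        cand.uniqueness_score = score
        near = _separation_count(cand, candidates, criteria.neighbor_ratio)
        checks = {
            "locus_share": (
                cand.locus_share >= criteria.min_locus_share,
                f"locus share {cand.locus_share:.4f} vs >= {criteria.min_locus_share}",
            ),
            "cell_fraction": (
                cand.cell_fraction >= criteria.min_cell_fraction,
                f"cell fraction {cand.cell_fraction:.5f} vs >= {criteria.min_cell_fraction}",
            ),
            "separation": (
                near <= criteria.max_near_neighbors,
                f"{near} near neighbors vs <= {criteria.max_near_neighbors}",
            ),
            "templates": (
                cand.template_count >= criteria.min_templates,
                f"{cand.template_count} templates vs >= {criteria.min_templates}",
            ),
            "uniqueness": (
                score >= criteria.min_uniqueness,
                f"uniqueness {score:.2f} vs >= {criteria.min_uniqueness}",
            ),
        }
        cand.pass_flags = checks
        if all(ok for ok, _ in checks.values()):
            tracked.append(
                TrackedSequence(
                    sequence=cand.sequence,
                    locus=cand.locus,
                    allowed_mutations=allowed_mutations(cand.sequence, score, tolerance),
                    uniqueness_score=score,
                )
            )
        else:
            rejected.append(cand)
    return TrackingProfile(patient_id=patient_id, tracked=tracked, rejected=rejected)
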