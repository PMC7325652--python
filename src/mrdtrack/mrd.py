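"""MRD quantification: sequence tracking, consensus cell counts, and OPA.

Tracked ID sequences are matched against the sequences observed in an MRD
sample with a Hamming tolerance of at most N mismatches per tracked sequence
(equal lengths required, no indels), absorbing somatic variants of the
malignant lineage. Matched template abundances give a per-rearrangement
malignant-cell estimate (one gDNA template per rearrangement per cell); the
consensus across a patient's tracked rearrangements, divided by the total
nucleated-cell count from the diploid reference amplicons, is the MRD
frequency.

Sequence accuracy is summarised as overall percent agreement (OPA):
abundance-weighted percent of matching nucleotides across all observed
sequences within the allowed-mutation budget, restated as a Phred score
(-10 log10 of the disagreement rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .constants import DEFAULT_CONSTANTS, AssayConstants
from .errors import InvalidParameterError, MissingDataError, UndefinedStatisticError

#: Phred score reported when the observed disagreement rate is exactly zero.
PHRED_CAP = 60.0


@dataclass(frozen=True)
class TrackedSequence:
    sequence: str
    locus: str
    allowed_mutations: int
    uniqueness_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.allowed_mutations < 0:
            raise InvalidParameterError("allowed_mutations must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    """One observed sequence aligned to its tracked ID clonotype."""

    length: int
    mismatches: int
    allowed: int
    abundance: int

    def __post_init__(self) -> None:
        if not 0 <= self.mismatches <= self.length:
            raise InvalidParameterError("mismatches must lie in [0, length]")
        if self.abundance < 0:
            raise InvalidParameterError("abundance must be >= 0")


@dataclass
class MRDResult:
    sample_id: str
    per_sequence_cells: dict[str, float]
    consensus_malignant_cells: float
    total_nucleated_cells: float
    mrd_frequency: float
    detected: bool


@dataclass
class OPAReport:
    nucleotides_assessed: int
    positive_agreement: int
    negative_agreement: int
    opa: float
    phred: float
    ci: tuple[float, float]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise InvalidParameterError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_tracked(sample, profile) -> dict[str, list[AlignmentRecord]]:
    """Assign observed sequences to tracked sequences within Hamming budget N.

    An observed sequence matches a tracked sequence iff the lengths are equal
    and the Hamming distance is <= that tracked sequence's N; each observed
    sequence is assigned to at most one tracked sequence (the nearest; ties
    go to the lowest-index tracked sequence). Length mismatches are simply
    non-matches. Returns alignment records keyed by tracked sequence.

    When the sample carries no reads, the per-sequence template table is used
    and only exact entries match (mismatches = 0).
    """
    if not profile.tracked:
        raise MissingDataError("tracking profile is empty")
    records: dict[str, list[AlignmentRecord]] = {t.sequence: [] for t in profile.tracked}
    if sample.reads:
        observed: Iterable[tuple[str, int]] = (
            (r.sequence, r.abundance) for r in sample.reads
        )
    else:
        observed = sample.per_sequence_templates.items()
    for seq, abundance in observed:
        best: tuple[int, int] | None = None  # (distance, tracked index)
        for i, t in enumerate(profile.tracked):
            if len(seq) != len(t.sequence):
                continue
            d = hamming(seq, t.sequence)
            if d <= t.allowed_mutations and (best is None or d < best[0]):
                best = (d, i)
        if best is not None:
            d, i = best
            t = profile.tracked[i]
            records[t.sequence].append(
                AlignmentRecord(
                    length=len(t.sequence), mismatches=d, allowed=t.allowed_mutations,
                    abundance=int(abundance),
                )
            )
    return records


def total_nucleated_cells(sample, constants: AssayConstants = DEFAULT_CONSTANTS) -> float:
    """Total nucleated cells in a sample.

    Quantified from the diploid reference amplicons (two templates per cell);
    when reference counts are absent, falls back to DNA mass at
    ``pg_per_diploid_cell`` per cell.
    """
    if sample.reference_templates:
        return sample.reference_templates / 2.0
    if getattr(sample, "dna_mass_pg", 0) > 0:
        return sample.dna_mass_pg / constants.pg_per_diploid_cell
    raise MissingDataError("neither reference templates nor DNA mass available")


def consensus_malignant_cells(
    per_sequence_cells: dict[str, float], mode: str = "mean"
) -> float:
    """Consensus sample-level malignant-cell count across tracked sequences.

    The default is the unweighted mean over all tracked sequences (zero
    counts included): with one template per rearrangement per cell each
    rearrangement is an independent Poisson draw of the same cell count, and
    the mean is its unbiased combination. ``mode`` may also be "max" or
    "sum" (abundance-weighted alternatives kept for sensitivity analyses).
    """
    if not per_sequence_cells:
        raise MissingDataError("no tracked sequences to form a consensus")
    values = np.array(list(per_sequence_cells.values()), dtype=float)
    if mode == "mean":
        return float(values.mean())
    if mode == "max":
        return float(values.max())
    if mode == "sum":
        return float(values.sum())
    raise InvalidParameterError(f"unknown consensus mode {mode!r}")


def mrd_frequency(consensus_cells: float, total_cells: float) -> float:
    """MRD frequency = consensus malignant cells / total nucleated cells."""
    if total_cells <= 0:
        raise InvalidParameterError("total nucleated cells must be > 0")
    if consensus_cells == 0:
        return 0.0
    return consensus_cells / total_cells


def quantify(
    sample,
    profile,
    *,
    constants: AssayConstants = DEFAULT_CONSTANTS,
    consensus_mode: str = "mean",
) -> MRDResult:
    """Full MRD call for one sample: track, count, and form the frequency."""
    records = match_tracked(sample, profile)
    per_seq = {
        seq: float(sum(r.abundance for r in recs)) for seq, recs in records.items()
    }
    consensus = consensus_malignant_cells(per_seq, mode=consensus_mode)
    total = total_nucleated_cells(sample, constants)
    detected = any(v >= 1 for v in per_seq.values())
    return MRDResult(
        sample_id=sample.sample_id,
        per_sequence_cells=per_seq,
        consensus_malignant_cells=consensus,
        total_nucleated_cells=total,
        mrd_frequency=mrd_frequency(consensus, total),
        detected=detected,
    )


def compute_opa(records: list[AlignmentRecord]) -> OPAReport:
    """Overall percent agreement across alignment records.

    For each record with mismatches <= allowed (records beyond the budget are
    excluded upstream by the matcher):

        positive agreement = (length - mismatches) * abundance
        negative agreement = mismatches * abundance

    OPA = 100 * PA / (PA + NA), accumulated in exact integer arithmetic
    before the final division. The CI is a Clopper-Pearson interval on the
    per-nucleotide agreement proportion.
    """
    pa = 0
    na = 0
    for r in records:
        if r.mismatches > r.allowed:
            raise InvalidParameterError(
                "record exceeds its allowed-mutation budget; exclude upstream"
            )
        pa += (r.length - r.mismatches) * r.abundance
        na += r.mismatches * r.abundance
    total = pa + na
    if total == 0:
        raise UndefinedStatisticError("OPA undefined with zero assessed nucleotides")
    lo, hi = proportion_confint(pa, total, alpha=0.05, method="beta")
    rate = na / total
    return OPAReport(
        nucleotides_assessed=total,
        positive_agreement=pa,
        negative_agreement=na,
        opa=100.0 * pa / total,
        phred=phred_score(rate),
        ci=(100.0 * lo, 100.0 * hi),
    )


def phred_score(disagreement_rate: float, cap: float = PHRED_CAP) -> float:
    """Phred restatement of a disagreement rate: -10 * log10(rate).

    A rate of 3.5e-5 maps to ~44.6; a rate of zero returns ``cap``.
    """
    if not 0.0 <= disagreement_rate <= 1.0:
        raise InvalidParameterError("disagreement_rate must lie in [0, 1]")
    if disagreement_rate == 0.0:
        return cap
    return float(-10.0 * np.log10(disagreement_rate))
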