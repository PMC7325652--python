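"""Synthetic immune-repertoire and contrived-sample generation.

Everything the analysis stages consume can be generated here: healthy
multi-locus B-cell repertoires, malignant clones carrying 1-5 trackable
rearrangements, contrived dilution samples in which tracked-sequence template
counts are Poisson-sampled at a prescribed expected malignant-cell number,
blank (healthy-only) panels, and factorial validation grids with injected
multiplicative factor effects.

The core sampling model: one gDNA template per rearrangement per cell
(diploid loci carry one productive rearrangement), so at an expected input of
``c`` malignant cells each tracked rearrangement contributes
``Poisson(c)`` templates, independently per rearrangement. Total nucleated
cells follow DNA mass at 6.53 pg per diploid cell, and the reference
(diploid-region) amplicon count is two templates per cell.

Randomness is derived per ``(sample_id, sequence)`` from the master seed via
``numpy.random.SeedSequence`` so that subsetting a study never shifts the
draws of other samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, AssayConstants
from .errors import InvalidParameterError

#: Receptor loci modelled by the generator. Translocation amplicons
#: (BCL1-IGH, BCL2-IGH) are treated abstractly as additional tracked loci.
LOCI = ("IGH", "IGK", "IGL", "BCL1-IGH", "BCL2-IGH")

DEFAULT_LOCUS_WEIGHTS = {"IGH": 0.5, "IGK": 0.3, "IGL": 0.2}

#: Default length of simulated CDR3-like rearrangement sequences (nt).
DEFAULT_SEQ_LENGTH = 45

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")

UNIQUENESS_TIERS = ("unique", "intermediate", "common")


def _substream(seed: int, *tags) -> np.random.Generator:
    """Independent RNG stream keyed by the master seed plus string/int tags."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, int):
            words.append(t & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(t).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_ALPHABET, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RepertoireClone:
    locus: str
    sequence: str
    frequency: float


@dataclass
class HealthyRepertoire:
    """A healthy donor's polyclonal B-cell repertoire."""

    donor_id: str
    clones: list[RepertoireClone]

    def __post_init__(self) -> None:
        total = sum(c.frequency for c in self.clones)
        if self.clones and abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"repertoire frequencies sum to {total}, not 1")
        for c in self.clones:
            if not c.sequence or set(c.sequence) - set("ACGT"):
                raise InvalidParameterError("sequences must be non-empty over ACGT")


@dataclass
class MalignantClone:
    """A patient's disease clone with its trackable rearrangements."""

    patient_id: str
    sequences: list[tuple[str, str]]  # (locus, sequence); one copy per cell
    uniqueness_tier: str = "unique"

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequences) <= 5:
            raise InvalidParameterError("a clone carries 1-5 trackable sequences")
        if len({s for _, s in self.sequences}) != len(self.sequences):
            raise InvalidParameterError("tracked sequences must be distinct")
        if self.uniqueness_tier not in UNIQUENESS_TIERS:
            raise InvalidParameterError(f"unknown tier {self.uniqueness_tier!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied on top of Poisson template sampling.

    ``per_base_error_rate`` is the probability of a substitution per
    nucleotide in generated reads; ``extra_cv`` is the coefficient of
    variation of multiplicative lognormal assay noise applied to template
    counts (0 disables it, leaving pure Poisson sampling).
    """

    per_base_error_rate: float = 0.0
    extra_cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise InvalidParameterError("per_base_error_rate must lie in [0, 1)")
        if self.extra_cv < 0:
            raise InvalidParameterError("extra_cv must be >= 0")


NO_NOISE = NoiseModel()


@dataclass
class Read:
    locus: str
    sequence: str
    abundance: int


@dataclass
class ContrivedSample:
    """A simulated (or imported) MRD sample.

    ``per_sequence_templates`` maps each tracked rearrangement sequence to
    its sampled template count; ``reference_templates`` counts the diploid
    reference amplicons used to quantify total nucleated cells;
    ``expected_malignant_cells`` is the dilution ground truth.
    """

    sample_id: str
    dna_mass_pg: float
    expected_malignant_cells: float
    per_sequence_templates: dict[str, int] = field(default_factory=dict)
    reference_templates: int = 0
    reads: list[Read] | None = None

    def __post_init__(self) -> None:
        if self.dna_mass_pg <= 0:
            raise InvalidParameterError("dna_mass_pg must be > 0")
        if self.expected_malignant_cells < 0:
            raise InvalidParameterError("expected_malignant_cells must be >= 0")
        if self.reference_templates < 0 or any(
            v < 0 for v in self.per_sequence_templates.values()
        ):
            raise InvalidParameterError("template counts must be >= 0")


#: Default expected-cell abundances of the precision grid.
DEFAULT_GRID_ABUNDANCES = (2.14, 6.13, 21.44, 61.26, 214.46, 612.56)

#: Default total DNA inputs (pg): 500 ng, 2 ug, 20 ug.
DEFAULT_GRID_DNA_INPUTS = (5e5, 2e6, 2e7)

#: Factor names and level counts of the precision main-effects design.
GRID_FACTORS = {
    "operator_set": 3,
    "instrument_set": 2,
    "reagent_lot": 4,
    "day": 21,
    "run_within_day": 10,
}


@dataclass
class ValidationGrid:
    """Replicate measurements annotated with design-factor levels.

    ``data`` holds one row per replicate with columns ``sample_id``,
    ``expected_cells``, ``dna_input_pg``, one column per factor in
    ``GRID_FACTORS``, ``replicate`` and ``measurement`` (estimated malignant
    cells).
    """

    data: "object"  # pandas.DataFrame; annotated loosely to keep import light
    factor_cvs: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def gen_healthy_repertoire(
    n_clones: int,
    locus_weights: dict[str, float] | None = None,
    seed: int = 0,
    *,
    power_exponent: float = 2.0,
    seq_length: int = DEFAULT_SEQ_LENGTH,
    donor_id: str = "donor-0",
) -> HealthyRepertoire:
    """Generate a polyclonal repertoire with power-law clone frequencies.

    Clone ``r`` (rank, 1-based) receives relative frequency proportional to
    ``r ** -power_exponent``; sequences are i.i.d. uniform over {A,C,G,T}.
    The default exponent of 2 matches the steep clone-size distributions of
    healthy repertoires, where even the largest clone stays small.
    Deterministic for a fixed seed.
    """
    if n_clones < 1:
        raise InvalidParameterError("n_clones must be >= 1")
    weights = dict(locus_weights) if locus_weights else dict(DEFAULT_LOCUS_WEIGHTS)
    total_w = sum(weights.values())
    if total_w <= 0 or any(w < 0 for w in weights.values()):
        raise InvalidParameterError("locus weights must be >= 0 with positive sum")
    loci = list(weights)
    p = np.array([weights[l] for l in loci]) / total_w

    rng = _substream(seed, "repertoire", donor_id)
    freqs = np.arange(1, n_clones + 1, dtype=float) ** -power_exponent
    freqs /= freqs.sum()
    # renormalise exactly so the invariant holds at float precision
    freqs[-1] = 1.0 - freqs[:-1].sum()
    locus_idx = rng.choice(len(loci), size=n_clones, p=p)
    clones = [
        RepertoireClone(loci[locus_idx[i]], _random_sequence(rng, seq_length), freqs[i])
        for i in range(n_clones)
    ]
    return HealthyRepertoire(donor_id=donor_id, clones=clones)


def gen_malignant_clone(
    k_sequences: int,
    uniqueness_tier: str = "unique",
    seed: int = 0,
    *,
    seq_length: int = DEFAULT_SEQ_LENGTH,
    patient_id: str = "patient-0",
) -> MalignantClone:
    """Generate a disease clone with ``k_sequences`` distinct rearrangements.

    Loci are assigned in the fixed order IGH, IGK, IGL, BCL1-IGH, BCL2-IGH.
    The uniqueness tier is carried on the clone; ``seed_uniqueness_database``
    turns it into database incidence (tier "common" plants the sequences at
    high incidence, which drives the uniqueness score below any sensible
    tracking cutoff downstream).
    """
    if not 1 <= k_sequences <= 5:
        raise InvalidParameterError("k_sequences must lie in 1..5")
    rng = _substream(seed, "clone", patient_id)
    seqs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i in range(k_sequences):
        s = _random_sequence(rng, seq_length)
        while s in seen:  # vanishingly rare at 45 nt, but keep the invariant hard
            s = _random_sequence(rng, seq_length)
        seen.add(s)
        seqs.append((LOCI[i], s))
    return MalignantClone(patient_id=patient_id, sequences=seqs, uniqueness_tier=uniqueness_tier)


def seed_uniqueness_database(
    clones: list[MalignantClone],
    total_repertoires: int = 1_000_000,
    *,
    healthy_repertoires: list[HealthyRepertoire] = (),
    tier_incidence: dict[str, int] | None = None,
):
    """Build a clonotype-incidence database reflecting each clone's tier.

    Tier "unique" sequences are absent from the database, "intermediate" ones
    appear at moderate incidence, and "common" ones at incidence comparable to
    the database size itself (uniqueness score near zero). Clones of any
    ``healthy_repertoires`` are recorded as previously observed healthy
    rearrangements (incidence total/10, uniqueness score 1), which is what
    lets the downstream uniqueness screen exclude them from tracking.
    Returns a :class:`mrdtrack.clonotypes.UniquenessDatabase`.
    """
    from .clonotypes import UniquenessDatabase

    incidence = tier_incidence or {
        "unique": 0,
        "intermediate": max(1, total_repertoires // 10_000),
        "common": max(1, total_repertoires // 2),
    }
    counts: dict[str, int] = {}
    for rep in healthy_repertoires:
        for c in rep.clones:
            counts[c.sequence] = max(1, total_repertoires // 10)
    for clone in clones:
        for _, s in clone.sequences:
            counts[s] = incidence[clone.uniqueness_tier]
    return UniquenessDatabase(incidence=counts, total_repertoires=total_repertoires)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _mutate_reads(rng: np.random.Generator, sequence: str, count: int, rate: float) -> dict[str, int]:
    """Split ``count`` templates of ``sequence`` into error-bearing variants."""
    if count == 0:
        return {}
    if rate == 0:
        return {sequence: count}
    L = len(sequence)
    out: dict[str, int] = {}
    n_errors = rng.binomial(L, rate, size=count)
    n_clean = int((n_errors == 0).sum())
    if n_clean:
        out[sequence] = n_clean
    base = np.frombuffer(sequence.encode(), dtype="S1")
    for k in n_errors[n_errors > 0]:
        arr = base.copy()
        pos = rng.choice(L, size=int(k), replace=False)
        for pidx in pos:
            cur = arr[pidx]
            choices = _ALPHABET[_ALPHABET != cur]
            arr[pidx] = rng.choice(choices)
        mut = arr.tobytes().decode()
        out[mut] = out.get(mut, 0) + 1
    return out


def reference_templates_for_mass(
    dna_mass_pg: float, constants: AssayConstants = DEFAULT_CONSTANTS
) -> int:
    """Diploid reference-amplicon count for a DNA mass: 2 templates/cell."""
    if dna_mass_pg <= 0:
        raise InvalidParameterError("dna_mass_pg must be > 0")
    return 2 * round(dna_mass_pg / constants.pg_per_diploid_cell)


def contrive_sample(
    clone: MalignantClone,
    background: HealthyRepertoire | None,
    dna_mass_pg: float,
    expected_cells: float,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    sample_id: str = "sample-0",
    constants: AssayConstants = DEFAULT_CONSTANTS,
    with_reads: bool = False,
) -> ContrivedSample:
    """Simulate a contrived dilution sample.

    Each tracked rearrangement contributes ``Poisson(expected_cells)``
    templates, independently per sequence, then multiplicative lognormal
    noise with CV ``noise.extra_cv`` is applied and the count re-rounded
    (floor 0). Reference templates are ``2 * round(mass / pg_per_cell)``.
    With ``with_reads`` the tracked templates are emitted as reads carrying
    substitution errors at ``noise.per_base_error_rate``.
    """
    if expected_cells < 0:
        raise InvalidParameterError("expected_cells must be >= 0")
    counts: dict[str, int] = {}
    reads: list[Read] = []
    for locus, seqstr in clone.sequences:
        rng = _substream(seed, sample_id, seqstr)
        n = int(rng.poisson(expected_cells)) if expected_cells > 0 else 0
        if noise.extra_cv > 0 and n > 0:
            n = max(0, round(n * float(_lognormal_factor(rng, noise.extra_cv))))
        counts[seqstr] = n
        if with_reads:
            for variant, c in _mutate_reads(rng, seqstr, n, noise.per_base_error_rate).items():
                reads.append(Read(locus, variant, c))
    return ContrivedSample(
        sample_id=sample_id,
        dna_mass_pg=dna_mass_pg,
        expected_malignant_cells=expected_cells,
        per_sequence_templates=counts,
        reference_templates=reference_templates_for_mass(dna_mass_pg, constants),
        reads=reads if with_reads else None,
    )


def contrive_id_sample(
    clone: MalignantClone,
    background: HealthyRepertoire,
    dna_mass_pg: float,
    disease_load: float,
    n_templates: int = 20_000,
    noise: NoiseModel = NO_NOISE,
    seed: int = 0,
    *,
    sample_id: str = "id-sample-0",
    constants: AssayConstants = DEFAULT_CONSTANTS,
) -> ContrivedSample:
    """Simulate a high-burden diagnostic (ID) sample with background reads.

    ``disease_load`` is the malignant fraction of nucleated cells. Template
    counts are multinomial over the clone's rearrangements (equal shares of
    the disease mass, one rearrangement per cell each) and the background
    repertoire's clones.
    """
    if not 0.0 < disease_load <= 1.0:
        raise InvalidParameterError("disease_load must lie in (0, 1]")
    rng = _substream(seed, sample_id, "id")
    k = len(clone.sequences)
    probs = [disease_load / k] * k + [
        (1.0 - disease_load) * c.frequency for c in background.clones
    ]
    probs = np.asarray(probs)
    probs = probs / probs.sum()
    draws = rng.multinomial(n_templates, probs)
    reads: list[Read] = []
    counts: dict[str, int] = {}
    for (locus, seqstr), c in zip(clone.sequences, draws[:k]):
        counts[seqstr] = int(c)
        for variant, n in _mutate_reads(rng, seqstr, int(c), noise.per_base_error_rate).items():
            reads.append(Read(locus, variant, n))
    for bclone, c in zip(background.clones, draws[k:]):
        if c > 0:
            reads.append(Read(bclone.locus, bclone.sequence, int(c)))
    true_cells = disease_load * n_templates / max(k, 1)
    return ContrivedSample(
        sample_id=sample_id,
        dna_mass_pg=dna_mass_pg,
        expected_malignant_cells=true_cells,
        per_sequence_templates=counts,
        reference_templates=reference_templates_for_mass(dna_mass_pg, constants),
        reads=reads,
    )


def gen_validation_grid(
    abundances=DEFAULT_GRID_ABUNDANCES,
    dna_inputs=DEFAULT_GRID_DNA_INPUTS,
    factor_cvs: dict[str, float] | None = None,
    seed: int = 0,
    *,
    n_replicates: int = 60,
) -> ValidationGrid:
    """Simulate the factorial precision study.

    For every (abundance, DNA input) stratum, ``n_replicates`` measurements
    are drawn as ``Poisson(abundance)`` and perturbed by multiplicative
    lognormal factor effects. Each effect is drawn once per factor level
    (with the CV given in ``factor_cvs``) and shared across strata, mirroring
    a random-effects model on the log scale. Factor levels are assigned by
    balanced permutation so every level of every factor appears at every
    abundance and no two factors are confounded.
    """
    import pandas as pd

    if len(abundances) == 0:
        raise InvalidParameterError("abundances must be non-empty")
    cvs = {f: 0.0 for f in GRID_FACTORS}
    if factor_cvs:
        unknown = set(factor_cvs) - set(GRID_FACTORS)
        if unknown:
            raise InvalidParameterError(f"unknown factors: {sorted(unknown)}")
        if any(v < 0 for v in factor_cvs.values()):
            raise InvalidParameterError("factor CVs must be >= 0")
        cvs.update(factor_cvs)

    eff_rng = _substream(seed, "grid", "effects")
    effects = {
        f: _lognormal_factor(eff_rng, cvs[f], size=n_levels)
        for f, n_levels in GRID_FACTORS.items()
    }

    rows = []
    for a_i, abundance in enumerate(abundances):
        for d_i, dna in enumerate(dna_inputs):
            rng = _substream(seed, "grid", a_i, d_i)
            levels = {}
            for f, n_levels in GRID_FACTORS.items():
                tiled = np.tile(np.arange(n_levels), n_replicates // n_levels + 1)[:n_replicates]
                levels[f] = rng.permutation(tiled)
            base = rng.poisson(abundance, size=n_replicates).astype(float)
            mult = np.ones(n_replicates)
            for f in GRID_FACTORS:
                mult *= effects[f][levels[f]]
            for r in range(n_replicates):
                rows.append(
                    {
                        "sample_id": f"grid-a{a_i}-d{d_i}-r{r}",
                        "expected_cells": abundance,
                        "dna_input_pg": dna,
                        **{f: int(levels[f][r]) for f in GRID_FACTORS},
                        "replicate": r,
                        "measurement": base[r] * mult[r],
                    }
                )
    return ValidationGrid(data=pd.DataFrame(rows), factor_cvs=cvs)


def gen_blank_panel(
    n_donors: int,
    dna_masses,
    profile,
    collision_rate: float = 0.0,
    seed: int = 0,
    *,
    constants: AssayConstants = DEFAULT_CONSTANTS,
) -> list[ContrivedSample]:
    """Simulate healthy-only (blank) samples for limit-of-blank estimation.

    Blanks carry no malignant templates. With probability ``collision_rate``
    per tracked sequence, a coincidentally matching healthy clone is planted
    (1 + Poisson(1) templates), modelling intermediate-uniqueness collisions.
    """
    if not 0.0 <= collision_rate <= 1.0:
        raise InvalidParameterError("collision_rate must lie in [0, 1]")
    if n_donors < 1:
        raise InvalidParameterError("n_donors must be >= 1")
    sequences = [t.sequence for t in profile.tracked]
    samples = []
    for d in range(n_donors):
        for m_i, mass in enumerate(dna_masses):
            sid = f"blank-donor{d}-mass{m_i}"
            counts: dict[str, int] = {}
            for s in sequences:
                rng = _substream(seed, sid, s)
                if collision_rate > 0 and rng.random() < collision_rate:
                    counts[s] = 1 + int(rng.poisson(1.0))
                else:
                    counts[s] = 0
            samples.append(
                ContrivedSample(
                    sample_id=sid,
                    dna_mass_pg=float(mass),
                    expected_malignant_cells=0.0,
                    per_sequence_templates=counts,
                    reference_templates=reference_templates_for_mass(mass, constants),
                )
            )
    return samples
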