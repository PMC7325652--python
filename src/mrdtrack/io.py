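"""Readers, writers, configuration, and the simulate-to-validate pipeline.

Tables are tab-separated (sequence fields make comma quoting a hazard);
repertoires and clone sequences are written as FASTA with key=value metadata
in the header; tracking profiles and statistical reports are JSON.

Sample-sheet column dictionary (one row per tracked sequence per sample):

====================  ======================================================
column                meaning
====================  ======================================================
sample_id             sample identifier
dna_mass_pg           total DNA input mass (pg)
expected_cells        ground-truth expected malignant cells (simulations)
reference_templates   diploid reference-amplicon count (2 per cell)
sequence              tracked rearrangement sequence ("." when none)
templates             gDNA template count for that sequence
====================  ======================================================
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clonotypes import (
    TrackabilityCriteria,
    call_candidates,
    select_trackable,
)
from .errors import InvalidParameterError, SchemaError
from .mrd import TrackedSequence, quantify
from .synthetic import (
    DEFAULT_GRID_ABUNDANCES,
    DEFAULT_GRID_DNA_INPUTS,
    ContrivedSample,
    HealthyRepertoire,
    MalignantClone,
    NoiseModel,
    RepertoireClone,
    contrive_id_sample,
    contrive_sample,
    gen_blank_panel,
    gen_healthy_repertoire,
    gen_malignant_clone,
    gen_validation_grid,
    seed_uniqueness_database,
)
from . import validation as vstats

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "dna_mass_pg",
    "expected_cells",
    "reference_templates",
    "sequence",
    "templates",
]


# ---------------------------------------------------------------------------
# sample sheets


def write_sample_sheet(samples: list[ContrivedSample], path) -> None:
    rows = []
    for s in samples:
        items = s.per_sequence_templates.items() or [(".", 0)]
        for seq, c in items:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "dna_mass_pg": s.dna_mass_pg,
                    "expected_cells": s.expected_malignant_cells,
                    "reference_templates": s.reference_templates,
                    "sequence": seq,
                    "templates": c,
                }
            )
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[ContrivedSample]:
    """Read a TSV sample sheet back into typed samples.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers; a missing required column raises a schema error naming it.
    """
    df = pd.read_csv(path, sep="\t")
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}", column=col)
    if df.empty:
        import warnings

        warnings.warn(f"sample sheet {path} contains no rows", stacklevel=2)
    samples: dict[str, ContrivedSample] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            templates = int(row["templates"])
            if templates < 0:
                raise ValueError("negative template count")
            sid = str(row["sample_id"])
            if sid not in samples:
                samples[sid] = ContrivedSample(
                    sample_id=sid,
                    dna_mass_pg=float(row["dna_mass_pg"]),
                    expected_malignant_cells=float(row["expected_cells"]),
                    reference_templates=int(row["reference_templates"]),
                )
            if str(row["sequence"]) != ".":
                samples[sid].per_sequence_templates[str(row["sequence"])] = templates
        except (ValueError, InvalidParameterError) as exc:
            raise SchemaError(f"line {line}: {exc}", line=line) from exc
    return list(samples.values())


# ---------------------------------------------------------------------------
# FASTA


def write_repertoire_fasta(rep: HealthyRepertoire, path) -> None:
    records = [
        SeqRecord(
            Seq(c.sequence),
            id=f"{rep.donor_id}|clone{i}",
            description=f"locus={c.locus} freq={c.frequency:.6g}",
        )
        for i, c in enumerate(rep.clones)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_clone_fasta(clone: MalignantClone, path) -> None:
    records = [
        SeqRecord(
            Seq(s),
            id=f"{clone.patient_id}|seq{i}",
            description=f"locus={locus} tier={clone.uniqueness_tier}",
        )
        for i, (locus, s) in enumerate(clone.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_clone_fasta(path, patient_id: str = "patient-0") -> MalignantClone:
    seqs = []
    tier = "unique"
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        seqs.append((meta.get("locus", "IGH"), str(rec.seq)))
        tier = meta.get("tier", tier)
    return MalignantClone(patient_id=patient_id, sequences=seqs, uniqueness_tier=tier)


# ---------------------------------------------------------------------------
# tracking profiles


def write_profile(profile, path) -> None:
    payload = {
        "patient_id": profile.patient_id,
        "tracked": [
            {
                "sequence": t.sequence,
                "locus": t.locus,
                "allowed_mutations": t.allowed_mutations,
                "uniqueness_score": t.uniqueness_score,
            }
            for t in profile.tracked
        ],
        "rejected": [
            {
                "sequence": c.sequence,
                "locus": c.locus,
                "failed": [k for k, (ok, _) in c.pass_flags.items() if not ok],
                "reasons": {k: why for k, (ok, why) in c.pass_flags.items() if not ok},
            }
            for c in profile.rejected
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_profile(path):
    from .clonotypes import TrackingProfile

    payload = json.loads(Path(path).read_text())
    return TrackingProfile(
        patient_id=payload["patient_id"],
        tracked=[TrackedSequence(**t) for t in payload["tracked"]],
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Full configuration of a simulated validation study.

    Round-trips losslessly through JSON; unknown keys are rejected on load.
    """

    seed: int = 0
    # simulation
    n_background_clones: int = 300
    k_sequences: int = 2
    disease_load: float = 0.10
    per_base_error_rate: float = 0.0
    extra_cv: float = 0.0
    # LoD study
    lod_doses: tuple = (1.0, 2.0, 3.0, 4.0, 6.0, 9.0)
    lod_replicates: int = 400
    lod_bootstrap: int = 200
    # LoQ study; the panel must bracket the 70% relative-total-error level
    loq_levels: tuple = (0.25, 0.5, 1.0, 2.14, 4.0, 8.0, 16.0, 32.0)
    loq_replicates: int = 400
    # LoB study
    lob_donors: int = 7
    lob_dna_masses: tuple = (5e5, 2e7, 4e7)
    collision_rate: float = 0.0
    # precision grid
    grid_abundances: tuple = DEFAULT_GRID_ABUNDANCES
    grid_dna_inputs: tuple = DEFAULT_GRID_DNA_INPUTS
    grid_replicates: int = 60
    factor_cvs: dict = field(default_factory=dict)
    vca_mode: str = "moments"
    # linearity
    linearity_cells: tuple = (2.0, 6.1, 21.4, 61.3, 214.5, 612.6, 3062.8, 30627.9)
    linearity_dna_mass_pg: float = 2e7
    linearity_replicates: int = 8
    # bias
    bias_cells: tuple = (10.0, 30.0, 100.0, 300.0)
    bias_samples: int = 20
    bias_replicates: int = 2
    bias_bootstrap: int = 2000
    # stage toggles
    run_lod: bool = True
    run_loq: bool = True
    run_lob: bool = True
    run_precision: bool = True
    run_linearity: bool = True
    run_bias: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(getattr(cls, f.name, None), tuple):
                data[f.name] = tuple(data[f.name])
        cfg = cls(**data)
        # normalise list fields coming back from JSON
        for f in dataclasses.fields(cls):
            v = getattr(cfg, f.name)
            if isinstance(v, list):
                object.__setattr__(cfg, f.name, tuple(v))
        return cfg


@dataclass
class RunLog:
    events: list = field(default_factory=list)

    def log(self, stage: str, message: str, severity: str = "INFO", **counts):
        self.events.append(
            {
                "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "severity": severity,
                "stage": stage,
                "message": message,
                **counts,
            }
        )


# ---------------------------------------------------------------------------
# reports


def write_reports(results: dict, out_dir) -> list:
    """Write machine-readable JSON reports plus human-readable TSV tables.

    The summary table mirrors the assay's headline validation outputs: LoD
    and LoQ with CIs, LoB, and the per-abundance %CV decomposition (abundance
    columns ascending). Empty results produce explicit "no data" markers.
    Re-serialisation is idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _jsonable(v) for k, v in asdict(obj).items()}
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, dict):
            return {str(k): _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if hasattr(obj, "item"):
            return obj.item()
        return obj

    report_path = out / "reports.json"
    report_path.write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True))
    written.append(report_path)

    summary_rows = []
    for name in ("lod", "loq"):
        r = results.get(name)
        if r is None:
            summary_rows.append({"measure": name.upper(), "cells": "no data",
                                 "ci_low": "", "ci_high": ""})
        elif name == "lod":
            ci = r.ci or (float("nan"), float("nan"))
            summary_rows.append({"measure": "LoD", "cells": f"{r.lod:.3f}",
                                 "ci_low": f"{ci[0]:.3f}", "ci_high": f"{ci[1]:.3f}"})
        else:
            summary_rows.append({"measure": "LoQ", "cells": f"{r:.3f}",
                                 "ci_low": "", "ci_high": ""})
    lob = results.get("lob")
    summary_rows.append(
        {"measure": "LoB",
         "cells": "no data" if lob is None else f"{lob.value:.3g}",
         "ci_low": "", "ci_high": ""}
    )
    summary_path = out / "summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
    written.append(summary_path)

    vca = results.get("precision")
    if vca is not None:
        t = vca.table.sort_values("expected_cells")
        # abundance as columns, factors as rows, mirroring a %CV-by-input table
        cv_cols = [c for c in t.columns if c.endswith("_cv")]
        wide = t.set_index("expected_cells")[cv_cols].T.round(1)
        vca_path = out / "precision_cv.tsv"
        wide.to_csv(vca_path, sep="\t")
        written.append(vca_path)

    bias = results.get("bias")
    if bias is not None:
        p = out / "bias.tsv"
        bias.table.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: StudyConfig, out_dir) -> RunLog:
    """Simulate, identify, track, and validate in one deterministic run.

    A fixed (config, seed) pair reproduces all artifacts bit-for-bit. Stage
    failures abort with the stage name; artifacts written before the failure
    are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    noise = NoiseModel(per_base_error_rate=config.per_base_error_rate,
                       extra_cv=config.extra_cv)
    results: dict = {}
    stage = "simulate"
    try:
        background = gen_healthy_repertoire(
            config.n_background_clones, seed=config.seed
        )
        clone = gen_malignant_clone(config.k_sequences, seed=config.seed)
        db = seed_uniqueness_database([clone], healthy_repertoires=[background])
        id_sample = contrive_id_sample(
            clone, background, dna_mass_pg=2e6,
            disease_load=config.disease_load, noise=noise, seed=config.seed,
        )
        write_clone_fasta(clone, out / "clone.fasta")
        write_repertoire_fasta(background, out / "background.fasta")
        log.log(stage, "simulated ID sample and background",
                n_background=len(background.clones), n_tracked=config.k_sequences)

        stage = "identify"
        candidates = call_candidates(id_sample)
        profile = select_trackable(
            candidates, TrackabilityCriteria(), db, patient_id=clone.patient_id
        )
        write_profile(profile, out / "profile.json")
        log.log(stage, "selected trackable sequences",
                n_candidates=len(candidates), n_tracked=len(profile.tracked))
        if not profile.tracked:
            raise InvalidParameterError("no trackable sequences identified")

        stage = "track"
        dilution = [
            contrive_sample(
                clone, background, dna_mass_pg=2e6, expected_cells=c,
                noise=noise, seed=config.seed, sample_id=f"dil-{c}-{r}",
            )
            for c in config.loq_levels
            for r in range(config.loq_replicates)
        ]
        mrd_results = [quantify(s, profile) for s in dilution]
        pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "consensus_cells": r.consensus_malignant_cells,
                    "total_cells": r.total_nucleated_cells,
                    "mrd_frequency": r.mrd_frequency,
                    "detected": r.detected,
                }
                for r in mrd_results
            ]
        ).to_csv(out / "mrd_results.tsv", sep="\t", index=False)
        log.log(stage, "tracked dilution series", n_samples=len(mrd_results))

        stage = "validate"
        if config.run_lod:
            doses, dets = [], []
            for c in config.lod_doses:
                for r in range(config.lod_replicates):
                    s = contrive_sample(
                        clone, background, 2e6, c, noise=noise,
                        seed=config.seed, sample_id=f"lod-{c}-{r}",
                    )
                    doses.append(c)
                    dets.append(quantify(s, profile).detected)
            results["lod"] = vstats.fit_probit(
                doses, dets, n_boot=config.lod_bootstrap, seed=config.seed
            )
            log.log(stage, f"LoD {results['lod'].lod:.3f} cells", n=len(doses))
        if config.run_loq:
            by_level = {
                c: [r.consensus_malignant_cells for s, r in zip(dilution, mrd_results)
                    if s.expected_malignant_cells == c]
                for c in config.loq_levels
            }
            import numpy as np

            x, y = vstats.precision_profile(
                {c: np.asarray(v) for c, v in by_level.items()}
            )
            fit = vstats.fit_sadler(x, y)
            results["loq"] = vstats.loq_from_profile(fit, 0.70)
            results["sadler"] = fit
            log.log(stage, f"LoQ {results['loq']:.3f} cells", n_levels=len(x))
        if config.run_lob:
            blanks = gen_blank_panel(
                config.lob_donors, config.lob_dna_masses, profile,
                collision_rate=config.collision_rate, seed=config.seed,
            )
            values, levels = [], []
            for s in blanks:
                r = quantify(s, profile)
                for seq, cells in r.per_sequence_cells.items():
                    values.append(cells / r.total_nucleated_cells)
                    levels.append(s.dna_mass_pg)
            results["lob"] = vstats.estimate_lob(values, levels=levels)
            log.log(stage, f"LoB {results['lob'].value:.3g}", n_blanks=len(blanks))
        if config.run_precision:
            grid = gen_validation_grid(
                config.grid_abundances, config.grid_dna_inputs,
                config.factor_cvs, seed=config.seed,
                n_replicates=config.grid_replicates,
            )
            results["precision"] = vstats.variance_components(
                grid, mode=config.vca_mode
            )
            log.log(stage, "variance components estimated",
                    n=int(len(grid.data)))
        if config.run_linearity:
            import numpy as np

            total_cells = config.linearity_dna_mass_pg / 6.53
            obs, expd = [], []
            for c in config.linearity_cells:
                for r in range(config.linearity_replicates):
                    s = contrive_sample(
                        clone, background, config.linearity_dna_mass_pg, c,
                        noise=noise, seed=config.seed, sample_id=f"lin-{c}-{r}",
                    )
                    m = quantify(s, profile)
                    if m.consensus_malignant_cells > 0:
                        obs.append(m.mrd_frequency)
                        expd.append(c / total_cells)
            results["linearity"] = vstats.assess_linearity(obs, expd)
            log.log(stage, f"linearity verdict {results['linearity'].verdict}",
                    n=len(obs))
        if config.run_bias:
            rows = []
            for c in config.bias_cells:
                for s_i in range(config.bias_samples):
                    for r in range(config.bias_replicates):
                        s = contrive_sample(
                            clone, background, 2e6, c, noise=noise,
                            seed=config.seed, sample_id=f"bias-{c}-{s_i}-{r}",
                        )
                        m = quantify(s, profile)
                        rows.append(
                            {"stratum": c, "sample_id": f"{c}-{s_i}",
                             "observed": m.consensus_malignant_cells,
                             "expected": c}
                        )
            results["bias"] = vstats.bootstrap_bias(
                pd.DataFrame(rows), n_boot=config.bias_bootstrap, seed=config.seed
            )
            log.log(stage, "bias bootstrap complete", n=len(rows))

        stage = "report"
        write_reports(results, out)
        (out / "run_log.json").write_text(json.dumps(log.events, indent=2))
        (out / "config.json").write_text(config.to_json())
    except Exception as exc:
        log.log(stage, f"stage failed: {exc}", severity="ERROR")
        (out / "run_log.json").write_text(json.dumps(log.events, indent=2))
        raise
    return log
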