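"""End-to-end orchestration: cohort -> references -> predictors -> report.

A :class:`RunConfig` (typically loaded from YAML) drives one reproducible
run: synthesize or ingest inputs, build the chosen reference variant,
apply the structure-derived predictors (DSSPp, tpLD, pLDn with an
MCC-selected or fixed threshold) plus any emulated/external predictor
files, evaluate everything, and write a manifest sufficient to reproduce
the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import EvaluationReport, evaluate_predictor, \
    predictor_correlation
from .predictors import DisorderScoreProfile, dsspp_predict, pldn_predict, \
    select_threshold_mcc, tpld_predict
from .reference import ReferenceLabels, build_disprot_pdb_reference, \
    build_disprot_reference, masked_fraction
from .ssc import codons, plddt_by_class, plddt_by_codon
from .synthetic import Cohort, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    reference_mode: str = "disprot-pdb"      # {"disprot", "disprot-pdb"}
    pldn_threshold: int | None = None        # None -> select by MCC
    predictor_aucs: dict = field(default_factory=dict)  # emulated externals
    bootstrap_samples: int = 10_000
    bootstrap_size: int = 60
    class_high_cut: float = 0.90
    class_low_cut: float = 0.10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    config: RunConfig
    cohort: Cohort
    references: dict[str, ReferenceLabels]
    reports: dict[str, EvaluationReport]
    selected_threshold: int | None
    ssc_summary: dict
    manifest: dict

    def report_table(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.reports.values()]
        return pd.DataFrame(rows).set_index("predictor")


def build_references(cohort: Cohort, mode: str) -> dict[str, ReferenceLabels]:
    """Per-protein reference labels in the requested variant."""
    refs = {}
    dropped = 0
    for acc, lab in zip(cohort.accessions, cohort.labels):
        n = len(lab)
        disorder = cohort.disorder_intervals.get(acc, [])
        if mode == "disprot":
            ref = build_disprot_reference(disorder, n, acc)
        elif mode == "disprot-pdb":
            coverage = cohort.coverage_intervals.get(acc, [])
            ref = build_disprot_pdb_reference(disorder, coverage, n, acc)
        else:
            raise ValueError(f"unknown reference mode: {mode}")
        if ref.n_evaluated == 0:
            dropped += 1
            logger.warning("%s: zero evaluated residues; dropped", acc)
            continue
        refs[acc] = ref
    if dropped:
        logger.warning("dropped %d proteins with no evaluated residues",
                       dropped)
    return refs


def run(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute a full benchmark run; optionally write artifacts to disk."""
    cohort = generate_cohort(config.generator,
                             predictor_aucs=config.predictor_aucs)
    if len(cohort) == 0:
        raise ValueError("empty protein set")
    references = build_references(cohort, config.reference_mode)
    if not references:
        raise ValueError("no proteins with evaluated residues")
    plddt = {acc: p for acc, p in zip(cohort.accessions, cohort.plddt)}
    ss8 = {acc: s for acc, s in zip(cohort.accessions, cohort.ss8)}

    # threshold for the binary confidence predictor
    if config.pldn_threshold is None:
        search = select_threshold_mcc(
            {a: plddt[a] for a in references}, references,
            dataset=config.reference_mode)
        threshold = search.best_n
    else:
        threshold = int(config.pldn_threshold)

    profiles: dict[str, dict[str, DisorderScoreProfile]] = {
        "DSSPp": {a: dsspp_predict(ss8[a], a) for a in references},
        "tpLD": {a: tpld_predict(plddt[a], a) for a in references},
        f"pLD{threshold}": {a: pldn_predict(plddt[a], threshold, a)
                            for a in references},
    }
    for name, files in cohort.predictor_files.items():
        profiles[name] = {
            f.accession: DisorderScoreProfile(
                accession=f.accession, source=name, scores=f.scores,
                calls=f.labels)
            for f in files if f.accession in references}

    reports = {
        name: evaluate_predictor(references, profs, name,
                                 dataset=config.reference_mode,
                                 class_high_cut=config.class_high_cut,
                                 class_low_cut=config.class_low_cut)
        for name, profs in profiles.items()}

    # confidence-vs-structure summary over the whole cohort
    reduced_all = "".join(cohort.reduced)
    plddt_all = np.concatenate(cohort.plddt)
    by_class = plddt_by_class(reduced_all, plddt_all,
                              bootstrap_spec=None)
    codon_all = []
    offset = 0
    for red in cohort.reduced:
        for c in codons(red) if len(red) >= 3 else []:
            codon_all.append(type(c)(c.triplet, c.center_index + offset))
        offset += len(red)
    by_codon = plddt_by_codon(codon_all, plddt_all)
    ssc_summary = {
        "class_means": {k: v.mean for k, v in by_class.items()},
        "class_counts": {k: v.count for k, v in by_class.items()},
        "codon_means": {k: v.mean for k, v in sorted(by_codon.items())
                        if not v.low_support},
    }

    manifest = {
        "software_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True,
                       default=str).encode()).hexdigest(),
        "seed": config.seed,
        "n_proteins": len(references),
        "n_residues": int(sum(r.n_evaluated for r in references.values())),
        "selected_threshold": threshold,
        "masked_fraction": masked_fraction(list(references.values()))
        if config.reference_mode == "disprot-pdb" else 0.0,
    }

    result = RunResult(config=config, cohort=cohort, references=references,
                       reports=reports, selected_threshold=threshold,
                       ssc_summary=ssc_summary, manifest=manifest)
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    with open(outdir / "report.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in result.reports.items()},
                  fh, indent=2, default=str)
    result.report_table().to_csv(outdir / "report.tsv", sep="\t")
    with open(outdir / "ssc_summary.json", "w") as fh:
        json.dump(result.ssc_summary, fh, indent=2, default=str)
    rows = []
    for acc, ref in result.references.items():
        for i in range(len(ref)):
            rows.append((acc, i + 1, int(ref.labels[i]),
                         int(ref.mask[i]), ref.provenance[i]))
    pd.DataFrame(rows, columns=["accession", "position", "reference_label",
                                "mask", "provenance"]).to_csv(
        outdir / "residues.tsv", sep="\t", index=False)


def compare(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Cross-predictor table sorted by AUC, with shared-protein RMSD
    correlations attached as a second frame in ``.attrs``."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    datasets = {r.dataset for r in reports.values()}
    if len(datasets) > 1:
        raise ValueError(f"reports computed on different references: "
                         f"{sorted(datasets)}")
    rows = []
    for name, r in reports.items():
        d = r.to_dict()
        d["predictor"] = name
        rows.append(d)
    table = pd.DataFrame(rows)
    table = table.sort_values("auc", ascending=False,
                              na_position="last").set_index("predictor")
    rmsd = pd.DataFrame({name: pd.Series(r.rmsd_per_protein)
                         for name, r in reports.items()})
    table.attrs["rmsd_correlation"] = predictor_correlation(rmsd)
    return table
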