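"""End-to-end orchestration of the analysis stages.

``run_pipeline`` wires the stages together — read and filter variants,
classify pathogenicity, build per-sample driver profiles, compute spectra,
optionally extract and match mutational signatures, and run the between-
group statistics — and writes every table plus a JSON run manifest (seed,
config hash, per-stage row counts, output checksums) to the output
directory. Runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .drivers import (build_profile, classify_combinations, pathway_scan,
                      recurrence_table)
from .knowledge import load_knowledge
from .pathogenicity import classify_all
from .reference import load_reference_matrix, reference_path
from .signatures import assign_samples, extract_signatures, match_cosmic
from .spectra import build_context_matrix, six_class_fractions
from .stats import build_summary
from .variants import filter_coding_nonsilent, read_groups, read_variants

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_ALL_STAGES = ("classify", "profile", "spectra", "signatures", "compare")


class PipelineError(RuntimeError):
    """A stage failed after inputs were read successfully."""


@dataclass
class RunConfig:
    variants: Path
    groups: Path
    out_dir: Path
    knowledge_dir: Path | None = None  # default: bundled snapshot
    cosmic: Path | None = None  # default: bundled synthetic reference
    dialect: str = "native"
    exception_genes: tuple[str, ...] = ()
    stages: tuple[str, ...] = _ALL_STAGES
    k_range: tuple[int, ...] = (2, 3, 4)
    n_restarts: int = 10
    cosine_floor: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("variants", "groups", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Input problems (missing/invalid files) raise their native errors before
    any stage runs; a failure inside a stage raises :class:`PipelineError`
    after writing a ``FAILED`` marker, retaining partial outputs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "somamut",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "counts": {},
        "outputs": {},
    }

    kb_dir = config.knowledge_dir or reference_path().parent
    kb = load_knowledge(kb_dir)
    records = read_variants(config.variants, dialect=config.dialect)
    groups = read_groups(config.groups)
    manifest["counts"]["variants_read"] = len(records)

    missing = {r.sample_id for r in records} - set(groups)
    if missing:
        raise ValueError(f"samples without group assignment: {sorted(missing)[:5]}")

    stage = "setup"
    try:
        stage = "classify"
        coding = filter_coding_nonsilent(records)
        manifest["counts"]["variants_coding_nonsilent"] = len(coding)
        classified = classify_all(coding, kb)
        by_group: dict[str, list] = {}
        for rec, call in classified:
            by_group.setdefault(groups[rec.sample_id].label, []).append((rec, call))
        if "classify" in config.stages:
            rows = []
            for rec, call in classified:
                rows.append({
                    "sample_id": rec.sample_id, "gene": rec.gene,
                    "variant_class": rec.variant_class.value,
                    "protein_change": rec.protein_change,
                    "verdict": call.verdict.value, "rule": call.rule_fired.value,
                    "votes_pathogenic": call.votes_pathogenic,
                    "votes_available": call.votes_available,
                })
            pd.DataFrame(rows).to_csv(out / "variants_classified.tsv",
                                      sep="\t", index=False)

        stage = "profile"
        profiles_by_group: dict[str, list] = {}
        if "profile" in config.stages:
            samples_by_group: dict[str, dict[str, list]] = {}
            for rec, call in classified:
                label = groups[rec.sample_id].label
                samples_by_group.setdefault(label, {}).setdefault(
                    rec.sample_id, []).append((rec, call))
            # samples with zero coding variants still belong to their cohort
            for sid, grp in groups.items():
                samples_by_group.setdefault(grp.label, {}).setdefault(sid, [])
            for label, per_sample in samples_by_group.items():
                profiles_by_group[label] = [
                    build_profile(sid, pairs, kb,
                                  exception_genes=config.exception_genes)
                    for sid, pairs in sorted(per_sample.items())
                ]
            rows = []
            for label, profiles in profiles_by_group.items():
                for p in profiles:
                    rows.append({
                        "sample_id": p.sample_id, "group": label,
                        "og": ",".join(sorted(p.og_genes)),
                        "tsg": ",".join(sorted(p.tsg_genes)),
                        "dual": ",".join(sorted(p.dual_genes)),
                        "putative": ",".join(sorted(p.putative_drivers)),
                        "category": p.combination_category.value,
                        "ras_pik3ca": p.ras_pik3ca_hit,
                        "dna_repair": ",".join(sorted(p.dna_repair_genes)),
                    })
            pd.DataFrame(rows).to_csv(out / "profiles.tsv", sep="\t", index=False)
            classify_combinations(profiles_by_group).to_csv(
                out / "combinations.tsv", sep="\t")
            pathway_scan(profiles_by_group).to_csv(out / "pathways.tsv", sep="\t")
            recurrence_table(by_group, kb, mode="pathogenic").to_csv(
                out / "recurrence_pathogenic.tsv", sep="\t")
            recurrence_table(by_group, kb, mode="all").to_csv(
                out / "recurrence_all.tsv", sep="\t")

        stage = "spectra"
        spectra_table = None
        matrix = None
        if "spectra" in config.stages:
            records_by_group = {
                label: [rec for rec, _ in pairs] for label, pairs in by_group.items()
            }
            spectra_table = six_class_fractions(records_by_group)
            spectra_table.to_csv(out / "spectra_six_class.tsv", sep="\t")
            matrix = build_context_matrix(coding)
            matrix.context_counts.T.to_csv(out / "context_matrix.tsv", sep="\t")
            manifest["counts"]["snv_without_context"] = matrix.n_dropped_no_context

        stage = "signatures"
        signature_freq = None
        if "signatures" in config.stages:
            if matrix is None:
                matrix = build_context_matrix(coding)
            reference = load_reference_matrix(config.cosmic)
            sigset = extract_signatures(
                matrix, k_range=config.k_range, n_restarts=config.n_restarts,
                seed=config.seed)
            sigset.cosmic_match = match_cosmic(sigset.W, reference,
                                               cosine_floor=config.cosine_floor)
            calls, signature_freq = assign_samples(
                sigset, {sid: g.label for sid, g in groups.items()})
            sigset.W.to_csv(out / "signatures_W.tsv", sep="\t")
            sigset.H.to_csv(out / "signatures_H.tsv", sep="\t")
            sigset.cosmic_match.to_csv(out / "signature_matches.tsv", sep="\t")
            sigset.rank_diagnostics.to_csv(out / "signature_rank_diagnostics.tsv",
                                           sep="\t")
            signature_freq.to_csv(out / "signature_frequencies.tsv", sep="\t")

        stage = "compare"
        if "compare" in config.stages and profiles_by_group:
            summary, comparisons = build_summary(
                by_group, profiles_by_group, spectra_table, signature_freq)
            summary.to_csv(out / "summary.tsv", sep="\t")
            comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
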