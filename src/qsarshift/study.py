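"""Named, scripted end-to-end studies on synthetic two-domain data.

Each study reproduces the shape of one analysis from the cross-source
evaluation workflow: within-domain nested CV, cross-domain transfer with
bias diagnosis, chemical-space diagnostics against transfer performance,
and mixed-training-set compilation. Studies are configuration: a
:class:`StudyManifest` (loadable from YAML) names the study kind, the
generator conditions, the seeds, and the model settings. The runner
executes the stages in order, writes every stage product to disk, and
collates the summary strictly from those stage outputs.

The shipped manifests use the support-vector classifier with its full
hyperparameter grid: at synthetic-study sample sizes it is by far the
cheapest of the three families, and the study conclusions are about data
sets, not classifiers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .config import RunConfig, logger
from .curation import ClassifiedDataset, build_target_dataset
from .cross_domain import cross_domain_transfer
from .chemspace import nn_mean_tanimoto
from .descriptors import compute_descriptor_matrix, fingerprints_for
from .io import write_report
from .mixing import evaluate_mixing
from .nested_cv import run_nested_cv, retrain_final
from .synthetic import GeneratorSpec, generate_study, spec_with, write_study

STUDY_KINDS = (
    "within_domain",
    "domain_shift",
    "bias",
    "diagnostics_decoupling",
    "mixing",
)


@dataclass
class StudyManifest:
    name: str
    kind: str
    seeds: list[int] = field(default_factory=lambda: [0])
    generator: dict[str, Any] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)
    algorithm_tag: str = "svm"
    provider_tag: str = "estate_like"
    scaffold_overlaps: list[float] = field(default_factory=lambda: [0.1, 0.5, 0.9])
    write_tables: bool = False

    def __post_init__(self) -> None:
        if self.kind not in STUDY_KINDS:
            raise ValueError(f"unknown study kind {self.kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def shipped_manifest(kind: str, seeds: Sequence[int] = (0,)) -> StudyManifest:
    """The packaged study conditions for each experiment.

    Simulation studies run at 300 compounds per domain — large enough to
    pass the curation eligibility rules with margin, small enough that a
    multi-seed study stays cheap.
    """
    base = {"n_per_domain": 300}
    if kind == "within_domain":
        # ten scaffolds per domain so cluster-based splitting always has
        # comfortably more Butina clusters than outer folds
        gen = dict(base, n_scaffolds=10, scaffold_overlap=0.4)
    elif kind == "domain_shift":
        # balanced classes so the transfer gap isolates chemistry overlap
        gen = dict(base, active_fraction_public=0.5,
                   active_fraction_proprietary=0.5, identity_overlap=0.0)
    elif kind == "bias":
        gen = dict(base, identity_overlap=0.0)
    elif kind == "diagnostics_decoupling":
        gen = dict(base, scaffold_overlap=0.9, identity_overlap=0.0,
                   active_fraction_public=0.5, active_fraction_proprietary=0.5,
                   flip_effect_proprietary=True)
    elif kind == "mixing":
        gen = dict(base, scaffold_overlap=1.0, identity_overlap=0.0,
                   active_fraction_public=0.5, active_fraction_proprietary=0.5,
                   noisy_assay_format="cell_free", format_flip_prob=0.6)
    else:
        raise ValueError(f"unknown study kind {kind!r}")
    return StudyManifest(name=kind.replace("_", "-"), kind=kind,
                         seeds=list(seeds), generator=gen)


def _prepare(
    manifest: StudyManifest, seed: int, overrides: dict[str, Any] | None = None
) -> tuple[GeneratorSpec, RunConfig]:
    gen = dict(manifest.generator)
    if overrides:
        gen.update(overrides)
    spec = GeneratorSpec(**gen, seed=seed) if "seed" not in gen else GeneratorSpec(**gen)
    config = RunConfig(**{"seed": seed, **manifest.config})
    return spec, config


def _curate_both(
    spec: GeneratorSpec, config: RunConfig
) -> tuple[ClassifiedDataset, ClassifiedDataset]:
    study = generate_study(spec)
    public = build_target_dataset(study.public_rows, spec.target_id,
                                  "public_like", config)
    proprietary = build_target_dataset(study.proprietary_rows, spec.target_id,
                                       "proprietary_like", config)
    for ds, name in ((public, "public_like"), (proprietary, "proprietary_like")):
        if isinstance(ds, ClassifiedDataset):
            continue
        raise RuntimeError(
            f"stage curate[{name}]: dataset failed eligibility ({ds.reason}); "
            "study aborted"
        )
    return public, proprietary


def _featurize(dataset: ClassifiedDataset, manifest: StudyManifest):
    return compute_descriptor_matrix(dataset, manifest.provider_tag)


def _within_domain_seed(manifest: StudyManifest, seed: int) -> dict[str, Any]:
    spec, config = _prepare(manifest, seed)
    public, proprietary = _curate_both(spec, config)
    out: dict[str, Any] = {"seed": seed}
    for ds in (public, proprietary):
        matrix = _featurize(ds, manifest)
        fps = fingerprints_for(ds, config.fingerprint_radius, config.fingerprint_bits)
        for scheme in ("random", "cluster"):
            result = run_nested_cv(ds, matrix, manifest.algorithm_tag, scheme,
                                   config=config, fps=fps)
            out[f"{ds.domain}_{scheme}_mean_mcc"] = result.mean_outer_mcc()
            out[f"{ds.domain}_{scheme}_final_hyperparams"] = result.final_hyperparams
    return out


def _transfer_seed(
    manifest: StudyManifest, seed: int, overrides: dict[str, Any] | None = None
) -> dict[str, Any]:
    """Shared core of the bias / domain-shift / decoupling studies."""
    spec, config = _prepare(manifest, seed, overrides)
    public, proprietary = _curate_both(spec, config)
    out: dict[str, Any] = {"seed": seed}

    fps_pub = fingerprints_for(public, config.fingerprint_radius,
                               config.fingerprint_bits)
    fps_prop = fingerprints_for(proprietary, config.fingerprint_radius,
                                config.fingerprint_bits)
    nn = nn_mean_tanimoto(fps_prop, fps_pub)
    out["nn_mean_tanimoto_prop_to_pub"] = nn.mean_nn_similarity

    for train_ds, test_ds in ((public, proprietary), (proprietary, public)):
        matrix = _featurize(train_ds, manifest)
        cv = run_nested_cv(train_ds, matrix, manifest.algorithm_tag, "random",
                           config=config)
        bundle = retrain_final(train_ds, matrix, manifest.algorithm_tag,
                               cv.final_hyperparams, seed=config.seed,
                               config=config)
        report = cross_domain_transfer(
            bundle, train_ds, test_ds, lambda ds: _featurize(ds, manifest)
        )
        tag = f"train_{train_ds.domain}"
        out[f"{tag}_within_mcc"] = cv.mean_outer_mcc()
        out[f"{tag}_cross_mcc"] = report.report.mcc
        out[f"{tag}_fp"] = report.report.counts.fp
        out[f"{tag}_fn"] = report.report.counts.fn
        out[f"{tag}_bias"] = report.bias_direction
        out[f"{tag}_n_removed_leakage"] = report.n_removed_leakage
    return out


def _domain_shift_seed(manifest: StudyManifest, seed: int) -> dict[str, Any]:
    out: dict[str, Any] = {"seed": seed, "overlaps": {}}
    for overlap in manifest.scaffold_overlaps:
        res = _transfer_seed(manifest, seed, {"scaffold_overlap": overlap})
        gap = (
            res["train_public_like_within_mcc"] - res["train_public_like_cross_mcc"]
        )
        out["overlaps"][str(overlap)] = {
            "nn_mean_tanimoto": res["nn_mean_tanimoto_prop_to_pub"],
            "within_mcc": res["train_public_like_within_mcc"],
            "cross_mcc": res["train_public_like_cross_mcc"],
            "gap": gap,
        }
    return out


def _mixing_seed(manifest: StudyManifest, seed: int) -> dict[str, Any]:
    spec, config = _prepare(manifest, seed)
    from .mixing import curate_mixing_inputs
    from .synthetic import generate_study as _gen

    study = _gen(spec)
    base, public, _excluded = curate_mixing_inputs(
        study.proprietary_rows, study.public_rows, spec.target_id, config
    )
    records = evaluate_mixing(
        base, public, assay_format="cell_based", config=config,
        algorithm_tag=manifest.algorithm_tag,
        provider_tag=manifest.provider_tag,
        schemes=("random",),
    )
    out: dict[str, Any] = {"seed": seed, "records": records}
    for approach in ("a_target_only", "b_plus_assay_format", "c_plus_similarity"):
        mccs = [r["mcc"] for r in records if r["approach"] == approach]
        out[f"mean_mcc_{approach}"] = float(np.mean(mccs)) if mccs else None
    return out


_SEED_RUNNERS = {
    "within_domain": _within_domain_seed,
    "bias": _transfer_seed,
    "diagnostics_decoupling": _transfer_seed,
    "domain_shift": _domain_shift_seed,
    "mixing": _mixing_seed,
}


def run_study(manifest: StudyManifest, outdir: str | Path) -> dict[str, Any]:
    """Execute a study manifest and write its report bundle.

    Per-seed stage outputs are written as JSON under the study directory;
    the summary is collated from those files (the reporter never
    recomputes a stage quantity).
    """
    outdir = Path(outdir) / manifest.name
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _SEED_RUNNERS[manifest.kind]

    seed_paths = []
    for seed in manifest.seeds:
        logger.info("study %s: seed %d", manifest.name, seed)
        result = runner(manifest, seed)
        path = outdir / f"seed_{seed}.json"
        write_report(result, path, format="json")
        seed_paths.append(path)
        if manifest.write_tables:
            spec, _ = _prepare(manifest, seed)
            write_study(generate_study(spec), outdir / f"tables_seed_{seed}")

    per_seed = [json.loads(p.read_text()) for p in seed_paths]
    summary: dict[str, Any] = {
        "study": manifest.name,
        "kind": manifest.kind,
        "manifest": manifest.to_dict(),
        "n_seeds": len(per_seed),
        "per_seed_files": [p.name for p in seed_paths],
    }
    numeric: dict[str, list[float]] = {}
    for rec in per_seed:
        for key, value in rec.items():
            if isinstance(value, (int, float)) and key != "seed":
                numeric.setdefault(key, []).append(float(value))
    summary["means"] = {k: float(np.mean(v)) for k, v in numeric.items()}
    summary["per_seed"] = per_seed
    write_report(summary, outdir / "summary.json", format="json")
    return summary
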