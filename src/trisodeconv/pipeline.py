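"""Run configuration, manifest and the end-to-end pipeline.

The pipeline ties the stages together in dependency order: simulate (or
ingest) -> signature construction -> deconvolution -> differential
expression -> proportion and size tests -> amyloid-beta quantification. A
single integer seed drives every stage; a manifest of SHA-256 checksums over
all written outputs makes reruns verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abeta as abeta_mod
from . import deconvolution, diffexpr, group_tests, io, simulate
from .design import DesignConfig, make_design

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "basis", "deconvolve", "de", "proportions_test", "size_test", "abeta")


def _check_keys(d: dict, allowed, context: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Strict, serializable configuration for one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: bool = True
    # input paths, used when simulate is off
    counts_path: str | None = None
    annotation_path: str | None = None
    meta_path: str | None = None
    sizes_path: str | None = None
    elisa_calibration_path: str | None = None
    elisa_samples_path: str | None = None
    # per-stage parameter overrides
    design: dict = field(default_factory=dict)
    reference: dict = field(default_factory=dict)
    bulk: dict = field(default_factory=dict)
    size: dict = field(default_factory=dict)
    elisa: dict = field(default_factory=dict)
    basis: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    abeta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)
        _check_keys(self.design, [f.name for f in dataclasses.fields(DesignConfig)], "design")
        _check_keys(self.bulk, [f.name for f in dataclasses.fields(simulate.BulkParams)], "bulk")
        _check_keys(self.size, [f.name for f in dataclasses.fields(simulate.SizeParams)], "size")
        _check_keys(self.elisa, [f.name for f in dataclasses.fields(simulate.ElisaParams)], "elisa")
        _check_keys(self.reference, ["n_genes", "n_clusters", "n_celltypes",
                                     "markers_per_cluster", "dataset_noise_sd"], "reference")
        _check_keys(self.basis, ["n_markers", "n_per_cluster_multicluster", "exclude_chr",
                                 "scale_cpm_by_100"], "basis")
        _check_keys(self.de, ["collapse", "covariate", "min_cpm", "min_fraction",
                              "prior_count", "dispersion_shrink", "fdr_threshold"], "de")
        _check_keys(self.abeta, ["clamp_upper", "dilution_factor", "censored"], "abeta")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, [f.name for f in dataclasses.fields(cls)], "run config")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict[str, str]
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages, writing outputs and a checksum manifest."""
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        design_cfg = DesignConfig(**{"seed": config.seed, **config.design})
        design = make_design(design_cfg)
        meta = pd.DataFrame([dataclasses.asdict(s) for s in design.samples]).set_index("sample_id")

        counts = sizes = elisa_cal = elisa_samples = None
        reference = truth = None
        if "simulate" in config.stages and config.simulate:
            stage = "simulate"
            reference = simulate.simulate_reference(seed=config.seed, **config.reference)
            counts, truth = simulate.simulate_bulk_counts(
                design, reference, simulate.BulkParams(**config.bulk), seed=config.seed
            )
            sizes = simulate.simulate_organoid_sizes(
                design, simulate.SizeParams(**config.size), seed=config.seed
            )
            es = simulate.simulate_elisa(
                design, simulate.ElisaParams(**config.elisa), seed=config.seed
            )
            elisa_cal, elisa_samples = es.calibration, es.samples
            emit("counts.tsv", lambda p: io.write_counts(counts, p))
            emit("annotation.tsv", lambda p: io.write_annotation(counts.annotation, p))
            emit("meta.csv", lambda p: io.write_meta(meta, p))
            emit("sizes.csv", lambda p: sizes.to_csv(p, index=False))
            emit("elisa_calibration.csv", lambda p: elisa_cal.to_csv(p, index=False))
            emit("elisa_samples.csv", lambda p: elisa_samples.to_csv(p, index=False))
            emit("marker_table.tsv", lambda p: reference.marker_table.to_csv(p, sep="\t", index=False))
            emit("profiles_A.tsv", lambda p: reference.profiles_A.rename_axis("gene_id").to_csv(p, sep="\t"))
            emit("profiles_B.tsv", lambda p: reference.profiles_B.rename_axis("gene_id").to_csv(p, sep="\t"))
            emit("cluster_map.json", lambda p: io.write_json(reference.cluster_to_celltype, p))
            emit("truth.json", lambda p: io.write_json(
                {
                    "true_proportions": truth.true_proportions,
                    "line_propensity": truth.line_propensity,
                    "abeta_fold": es.abeta_fold,
                    "dosage_chr21": float(simulate.BulkParams(**config.bulk).dosage),
                },
                p,
            ))
            logger.info("simulate: %d genes x %d samples", *counts.counts.shape)
        else:
            stage = "ingest"
            if config.counts_path:
                counts = io.read_counts(config.counts_path, config.annotation_path)
            if config.meta_path:
                meta = io.read_meta(config.meta_path)
            if config.sizes_path:
                sizes = pd.read_csv(config.sizes_path)
            if config.elisa_calibration_path:
                elisa_cal = pd.read_csv(config.elisa_calibration_path)
            if config.elisa_samples_path:
                elisa_samples = pd.read_csv(config.elisa_samples_path)

        basis = None
        if "basis" in config.stages:
            stage = "basis"
            if reference is None:
                raise ValueError("basis stage requires simulated reference data")
            basis = deconvolution.build_basis(
                reference.marker_table,
                reference.profiles_A,
                reference.profiles_B,
                reference.cluster_to_celltype,
                reference.annotation,
                **config.basis,
            )
            emit("basis.tsv", lambda p: basis.S.to_csv(p, sep="\t"))
            emit("basis_provenance.json", lambda p: io.write_json(
                basis.provenance.to_dict(orient="records"), p))
            logger.info("basis: %d markers x %d cell-types", *basis.S.shape)

        line_props = None
        if "deconvolve" in config.stages:
            stage = "deconvolve"
            if counts is None or basis is None:
                raise ValueError("deconvolve stage requires counts and a basis")
            res = deconvolution.deconvolve_samples(counts, basis)
            emit("proportions.csv", lambda p: res.proportions.to_csv(p))
            emit("deconvolution_diagnostics.csv", lambda p: res.diagnostics.to_csv(p, index=False))
            collapsed, cmeta = diffexpr.collapse_replicates(counts, meta)
            line_res = deconvolution.deconvolve_samples(collapsed, basis)
            line_props = line_res.proportions
            emit("line_proportions.csv", lambda p: line_props.to_csv(p))
            logger.info("deconvolve: %d samples, %d failures", len(res.proportions), len(res.failures))

        if "de" in config.stages:
            stage = "de"
            if counts is None:
                raise ValueError("de stage requires counts")
            de_opts = dict(config.de)
            covariate = de_opts.pop("covariate", "none")
            cov = line_props if (covariate == "auto" and line_props is not None) else None
            de_res = diffexpr.run_de(counts, meta, covariate_proportions=cov, **de_opts)
            emit("de_results.tsv", lambda p: de_res.table.rename_axis("gene_id").to_csv(p, sep="\t"))
            emit("de_cutoffs.json", lambda p: io.write_json(
                {**de_res.p_cutoffs, "covariate": de_res.covariate_used,
                 "prior_df": de_res.prior_df}, p))
            logger.info(
                "de: %d genes tested, chr21 hits at FDR_chr21<0.1: %d",
                len(de_res.table),
                int((de_res.table["FDR_chr21"] < 0.1).sum()),
            )

        if "proportions_test" in config.stages:
            stage = "proportions_test"
            if line_props is None:
                raise ValueError("proportions_test stage requires deconvolution output")
            tri = meta.groupby("line_id")["trisomic"].first()
            prop_tests = group_tests.test_proportions(line_props, tri)
            emit("proportion_tests.csv", lambda p: prop_tests.to_csv(p))

        if "size_test" in config.stages:
            stage = "size_test"
            if sizes is None:
                raise ValueError("size_test stage requires a size table")
            size_res = group_tests.size_analysis(sizes)
            emit("size_batch_medians.csv", lambda p: size_res.batch_medians.to_csv(p, index=False))
            emit("size_summary.json", lambda p: io.write_json(
                {"line_means": size_res.line_means, "t": size_res.welch.t,
                 "df": size_res.welch.df, "p": size_res.welch.p}, p))

        if "abeta" in config.stages:
            stage = "abeta"
            if elisa_cal is None or elisa_samples is None:
                raise ValueError("abeta stage requires calibration and sample ODs")
            curve, ab = abeta_mod.quantify(elisa_cal, elisa_samples, **config.abeta)
            emit("abeta_pools.csv", lambda p: ab.pools.to_csv(p, index=False))
            emit("abeta_summary.json", lambda p: io.write_json(
                {
                    "fold_change": ab.fold_change,
                    "ci_low": ab.ci_low,
                    "ci_high": ab.ci_high,
                    "p_value": ab.p_value,
                    "rna_coefficient": ab.rna_coefficient,
                    "rna_coefficient_p": ab.rna_coefficient_p,
                    "curve": {"slope": curve.slope, "lower": curve.lower,
                              "upper": curve.upper, "midpoint": curve.midpoint,
                              "clamp_upper": curve.clamp_upper},
                }, p))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.digest(),
        seed=config.seed,
        version=__version__,
        checksums={p.name: _sha256(p) for p in written},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
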