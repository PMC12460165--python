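"""End-to-end pipeline: simulate/load -> DE -> signatures -> TPM -> scores.

One directory per run. Stage outputs are plain TSV/JSON so each stage can
be re-run individually; a ``manifest.json`` records the configuration
snapshot, package version, seed and a SHA-256 checksum of every file the
run wrote, so re-validation detects any mutation of an intermediate file.
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

from . import __version__, de, io, scoring, signatures, simdata
from .errors import ConfigError, DegenerateInputError, StatScoreError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``counts``/``lengths``/``samples`` paths) or ``sim``
    must be provided; the latter generates the inputs with
    :func:`statscore.simdata.simulate_experiment`.
    """

    out_dir: Path
    counts: Path | None = None
    lengths: Path | None = None
    samples: Path | None = None
    sim: simdata.SimConfig | None = None
    alpha: float = de.DEFAULT_ALPHA
    min_size: int = signatures.DEFAULT_MIN_SIZE
    sign_mode: str = "concordant"
    tpm_transform: bool = True  # correlate log2(TPM+1); False = raw TPM
    epsilon: float = scoring.DEFAULT_EPSILON
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        have_paths = any(p is not None for p in (self.counts, self.lengths, self.samples))
        if have_paths and self.sim is not None:
            raise ConfigError("provide input paths or a sim block, not both")
        if not have_paths and self.sim is None:
            raise ConfigError("provide input paths (counts/lengths/samples) or a sim block")
        if have_paths and None in (self.counts, self.lengths, self.samples):
            raise ConfigError("counts, lengths and samples paths must all be given")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.sign_mode not in signatures.SIGN_MODES:
            raise ConfigError(f"sign_mode must be one of {signatures.SIGN_MODES}")
        if self.sim is not None:
            self.sim.validate()


def _sim_config_from_obj(obj: dict) -> simdata.SimConfig:
    obj = dict(obj)
    conds = obj.pop("conditions", None)
    kwargs = {}
    for f in dataclasses.fields(simdata.SimConfig):
        if f.name in obj:
            val = obj.pop(f.name)
            if f.name in ("baseline_log2_mean_sd", "library_size_range", "gene_length_range"):
                val = tuple(val)
            kwargs[f.name] = val
    if obj:
        raise ConfigError(f"unknown sim config keys: {sorted(obj)}")
    if conds is not None:
        specs = []
        for c in conds:
            specs.append(
                simdata.ConditionSpec(
                    name=c["name"],
                    role=c["role"],
                    activation={k: float(v) for k, v in c.get("activation", {}).items()},
                    reference_stat=c.get("reference_stat"),
                )
            )
        kwargs["conditions"] = tuple(specs)
    return simdata.SimConfig(**kwargs)


def load_config(path: Path) -> PipelineConfig:
    """Load a YAML pipeline configuration file."""
    path = Path(path)
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    sim = obj.pop("sim", None)
    cfg = PipelineConfig(
        out_dir=Path(obj.pop("out_dir", "statscore_run")),
        counts=Path(obj["counts"]) if "counts" in obj else None,
        lengths=Path(obj["lengths"]) if "lengths" in obj else None,
        samples=Path(obj["samples"]) if "samples" in obj else None,
        sim=_sim_config_from_obj(sim) if sim is not None else None,
        alpha=float(obj.pop("alpha", de.DEFAULT_ALPHA)),
        min_size=int(obj.pop("min_size", signatures.DEFAULT_MIN_SIZE)),
        sign_mode=obj.pop("sign_mode", "concordant"),
        tpm_transform=bool(obj.pop("tpm_transform", True)),
        epsilon=float(obj.pop("epsilon", scoring.DEFAULT_EPSILON)),
        seed=obj.pop("seed", None),
        log_level=obj.pop("log_level", "INFO"),
    )
    for k in ("counts", "lengths", "samples"):
        obj.pop(k, None)
    if obj:
        raise ConfigError(f"{path}: unknown config keys: {sorted(obj)}")
    cfg.validate()
    return cfg


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = {
        "alpha": config.alpha,
        "min_size": config.min_size,
        "sign_mode": config.sign_mode,
        "tpm_transform": config.tpm_transform,
        "epsilon": config.epsilon,
        "seed": config.seed,
    }
    if config.sim is not None:
        sim = dataclasses.asdict(config.sim)
        sim["conditions"] = [dataclasses.asdict(c) for c in config.sim.conditions]
        snap["sim"] = sim
    else:
        snap["inputs"] = {
            "counts": str(config.counts),
            "lengths": str(config.lengths),
            "samples": str(config.samples),
        }
    return snap


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one completed run: config snapshot, version, file checksums."""

    config: dict
    version: str
    seed: int | None
    checksums: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json_obj(self) -> dict:
        return dataclasses.asdict(self)


def verify_manifest(run_dir: Path) -> list[str]:
    """Re-checksum a run directory; returns the files that changed."""
    run_dir = Path(run_dir)
    manifest = io.read_json(run_dir / "manifest.json")
    bad = []
    for rel, digest in manifest["checksums"].items():
        path = run_dir / rel
        if not path.exists() or _sha256(path) != digest:
            bad.append(rel)
    return bad


#: files every successful run writes at the top level of the run directory
RUN_OUTPUTS = (
    "signatures/summary.tsv",
    "scores.tsv",
    "condition_scores.tsv",
    "pca.tsv",
    "pca_variance.tsv",
    "manifest.json",
    "report.txt",
)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Stages: (optional) simulate -> DE per reference condition -> signatures
    -> TPM -> scores -> fold changes -> PCA -> report. Writes all interface
    files under ``config.out_dir`` and returns the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    written: list[Path] = []

    def _register(path: Path) -> Path:
        written.append(path)
        return path

    stage = "load"
    try:
        if config.sim is not None:
            stage = "simulate"
            sim_cfg = config.sim
            if config.seed is not None:
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
            matrix, lengths, truth = simdata.simulate_experiment(sim_cfg)
            paths = simdata.write_fixture(matrix, lengths, truth, out / "inputs")
            written.extend(paths.values())
        else:
            matrix = io.read_count_matrix(config.counts, config.samples)
            lengths = io.read_lengths(config.lengths)
            missing = matrix.counts.index.difference(lengths.index)
            if len(missing):
                raise ValidationError(
                    f"genes without length annotation: {list(missing[:5])}"
                )
        io.check_nonzero_columns(matrix.counts)
        logger.info("loaded %d genes x %d samples, %d conditions",
                    len(matrix.gene_ids), len(matrix.sample_ids),
                    len(matrix.conditions))

        stage = "de"
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        ref_conditions = [
            c for c in matrix.conditions if matrix.condition_role(c) == "reference"
        ]
        de_results: dict[str, dict[str, int]] = {}
        for cond in ref_conditions:
            table = de.de_table(matrix, cond, alpha=config.alpha)
            table.to_csv(_register(de_dir / f"de_{cond}.tsv"), sep="\t",
                         index_label="gene")
            sig_rows = table[table["significant"]]
            de_results[cond] = dict(zip(sig_rows.index, sig_rows["sign"].astype(int)))
            logger.info("DE %s vs %s: %d/%d genes at padj < %g",
                        cond, matrix.control_condition, len(de_results[cond]),
                        len(table), config.alpha)

        stage = "signatures"
        sigs = signatures.build_signatures(
            de_results, matrix.samples, sign_mode=config.sign_mode,
            min_size=config.min_size,
        )
        sig_dir = out / "signatures"
        sig_dir.mkdir(exist_ok=True)
        per_stat, summary = signatures.signatures_to_frames(sigs)
        for stat, df in per_stat.items():
            df.to_csv(_register(sig_dir / f"signature_{stat}.tsv"), sep="\t",
                      index=False)
        summary.to_csv(_register(sig_dir / "summary.tsv"), sep="\t", index=False)
        report_rows = signatures.validate_signatures(sigs, min_size=config.min_size)
        for row in report_rows:
            logger.warning("signature below floor: %s", row)

        stage = "tpm"
        tpm_matrix = scoring.tpm(matrix.counts, lengths)
        if config.tpm_transform:
            tpm_matrix = scoring.log_transform(tpm_matrix)

        stage = "score"
        table = scoring.score_all(
            tpm_matrix, sigs, matrix.samples, min_size=config.min_size
        )
        table.per_sample.to_csv(_register(out / "scores.tsv"), sep="\t", index=False,
                                float_format="%.10g")

        stage = "fold_change"
        fc = scoring.score_fold_change(table, epsilon=config.epsilon)
        fc.to_csv(_register(out / "condition_scores.tsv"), sep="\t", index=False,
                  float_format="%.10g")

        stage = "pca"
        wide = table.per_sample.pivot(index="sample", columns="stat", values="score")
        wide = wide.reindex(index=matrix.sample_ids)
        try:
            coords, frac = scoring.pca_scores(wide)
        except DegenerateInputError as exc:
            # all-missing or constant scores: emit empty tables, keep the run
            logger.warning("PCA skipped: %s", exc)
            coords = pd.DataFrame(columns=[f"PC{i + 1}" for i in range(wide.shape[1])])
            frac = pd.Series(dtype=float)
        coords.to_csv(_register(out / "pca.tsv"), sep="\t", index_label="sample",
                      float_format="%.10g")
        frac.rename("variance_fraction").to_csv(
            _register(out / "pca_variance.tsv"), sep="\t", index_label="component",
            float_format="%.10g",
        )

        stage = "report"
        body = _report_body(summary, report_rows, table, fc, frac, config)
        (out / "report.txt").write_text(body)
        written.append(out / "report.txt")
    except StatScoreError as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise

    manifest = RunManifest(
        config=_config_snapshot(config),
        version=__version__,
        seed=config.seed if config.seed is not None
        else (config.sim.seed if config.sim else None),
        checksums={
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
        },
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    io.write_json(manifest.to_json_obj(), out / "manifest.json")
    return manifest


def _fmt(v: float) -> str:
    return "NA" if pd.isna(v) else f"{v:.4f}"


def _report_body(summary, flagged, table, fc, frac, config) -> str:
    """Plain-text run summary; deterministic (no timestamps)."""
    lines = ["# statscore run report", ""]
    lines.append("## Signature sizes")
    lines.append(summary.to_string(index=False))
    if flagged:
        lines.append("")
        for row in flagged:
            lines.append(
                f"flagged: {row['stat']} exclusive set of size {row['n_exclusive']} "
                f"is below min_size={row['min_size']}; scores reported missing"
            )
    lines.append("")
    lines.append(f"## Condition mean STAT scores (control: {table.control_condition})")
    lines.append(table.condition_means.to_string(float_format=_fmt, na_rep="NA"))
    lines.append("")
    lines.append("## Fold change vs control (NA where control mean <= epsilon "
                 f"= {config.epsilon} or score missing)")
    fc_wide = fc.pivot(index="condition", columns="stat", values="fold_change")
    fc_wide = fc_wide.reindex(index=table.condition_means.index)
    lines.append(fc_wide.to_string(float_format=_fmt, na_rep="NA"))
    lines.append("")
    lines.append("## PCA variance explained")
    lines.append(frac.to_string(float_format=_fmt))
    lines.append("")
    return "\n".join(lines)


def report(run_dir: Path) -> str:
    """Return the report of a completed run, checking outputs exist."""
    run_dir = Path(run_dir)
    missing = [f for f in RUN_OUTPUTS if not (run_dir / f).exists()]
    if missing:
        raise ValidationError(f"run directory missing outputs: {missing}")
    return (run_dir / "report.txt").read_text()
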