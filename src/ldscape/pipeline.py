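"""End-to-end orchestration: QC -> LD -> blocks -> phase -> Ne.

A :class:`RunConfig` (buildable from YAML) names the input cohorts and all
stage parameters; :func:`run_pipeline` executes the stages and writes
tab-separated artifacts into the output directory, every file carrying a
header comment naming the producing stage and a hash of the configuration.
Randomised stages derive their seed deterministically from the single
top-level seed and the stage name, so adding stages never perturbs earlier
stages' randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeMatrix, read_plink, read_vcf
from .qc import apply_qc, chromosome_summary
from .ld import (
    adjacent_r2_summary,
    ld_decay,
    maf_threshold_sweep,
    pairwise_ld,
    proportion_above,
    subsample_ld_curves,
)
from .blocks import block_summary, blocks_to_frame, find_blocks
from .phase import phase_correlation, shared_ld
from .ne import NeConfig, estimate_ne
from .simulate import paper_shaped_fixture

logger = logging.getLogger(__name__)

STAGES = ("qc", "ld", "blocks", "phase", "ne")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full-run settings; see the YAML examples under examples/."""

    inputs: dict = field(default_factory=dict)  # population -> path/prefix
    input_format: str = "plink"  # "plink" or "vcf"
    out_dir: str = "ldscape_out"
    seed: int = 0
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    ld_max_dist_bp: int = 1_000_000
    ld_bin_bp: int = 10_000
    r2_thresholds: tuple = (0.2, 0.3)
    maf_sweep: tuple = (0.05, 0.1, 0.2)
    subsample_sizes: tuple = ()
    subsample_reps: int = 1000
    block_window_bp: int = 200_000
    phase_bin_bp: int = 100_000
    ne_alpha: float = 1.0
    ne_beta: int = 1
    ne_map_function: str = "linear"
    ne_cm_per_mb: float = 1.0
    ne_generations: tuple = (13, 20, 30, 50, 100, 200, 500, 1000)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self, need_two_populations: bool = False) -> None:
        if not self.inputs:
            raise ConfigError("no input cohorts configured")
        if self.input_format not in ("plink", "vcf"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        if need_two_populations and len(self.inputs) < 2:
            raise ConfigError(
                "the phase stage compares two populations; configure two inputs"
            )
        for name, value in (
            ("call_rate_min", self.call_rate_min),
            ("maf_min", self.maf_min),
            ("hwe_p_min", self.hwe_p_min),
        ):
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} out of range [0, 1]: {value}")
        for pop, path in self.inputs.items():
            probe = (
                Path(str(path) + ".bed")
                if self.input_format == "plink"
                else Path(path)
            )
            if not probe.exists():
                raise ConfigError(f"input for population {pop!r} not found: {probe}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by the stage name (< 2**31)."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={cfg_hash} ldscape={__version__}\n")
        fh.write("# sd columns are population (divide-by-n) standard deviations\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def load_cohort(config: RunConfig, population: str) -> GenotypeMatrix:
    path = config.inputs[population]
    if config.input_format == "plink":
        return read_plink(path, population=population)
    return read_vcf(path, population=population)


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages for every configured cohort.

    Returns a result bundle (per-population QC'd matrices, LD records and
    summaries, blocks, phase bins, Ne trajectories) and writes the TSV
    artifacts plus a machine-readable run manifest.  A stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate(need_two_populations="phase" in stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    bundle: dict = {"config": config, "populations": {}}
    artifacts: list[str] = []

    def emit(df, name, stage):
        _write_tsv(df, out / name, stage, cfg_hash)
        artifacts.append(name)

    records_by_pop: dict[str, pd.DataFrame] = {}
    qc_by_pop: dict[str, GenotypeMatrix] = {}

    for pop in config.inputs:
        pres: dict = {}
        bundle["populations"][pop] = pres
        try:
            G = load_cohort(config, pop)
        except Exception as exc:  # noqa: BLE001
            raise StageError("load", exc) from exc

        if "qc" in stages:
            try:
                Gq, report = apply_qc(
                    G, config.call_rate_min, config.maf_min, config.hwe_p_min
                )
                emit(report.to_frame(), f"{pop}.qc_report.tsv", "qc")
                (out / f"{pop}.retained_variants.txt").write_text(
                    "\n".join(report.retained_ids) + "\n"
                )
                pres["qc_report"] = report
            except Exception as exc:  # noqa: BLE001
                raise StageError("qc", exc) from exc
        else:
            Gq = G
        qc_by_pop[pop] = Gq
        pres["genotypes"] = Gq

        if "ld" in stages:
            try:
                records = pairwise_ld(Gq, config.ld_max_dist_bp)
                records_by_pop[pop] = records
                pres["ld_records"] = records
                adjacent = adjacent_r2_summary(Gq)
                pres["adjacent_r2"] = adjacent
                emit(adjacent, f"{pop}.adjacent_r2.tsv", "ld")
                chrom = chromosome_summary(Gq, adjacent)
                pres["chromosome_summary"] = chrom
                emit(chrom, f"{pop}.chromosome_summary.tsv", "ld")
                decay = ld_decay(records, config.ld_bin_bp, config.ld_max_dist_bp)
                pres["decay"] = decay
                emit(decay, f"{pop}.ld_decay.tsv", "ld")
                props = pd.DataFrame(
                    {
                        "threshold": list(config.r2_thresholds),
                        "proportion_adjacent": [
                            proportion_above(_adjacent_r2_values(Gq), t)
                            for t in config.r2_thresholds
                        ],
                        "proportion_all_pairs": [
                            proportion_above(records, t)
                            for t in config.r2_thresholds
                        ],
                    }
                )
                pres["proportions"] = props
                emit(props, f"{pop}.r2_proportions.tsv", "ld")
                sweep = maf_threshold_sweep(
                    Gq, config.maf_sweep, config.ld_bin_bp, config.ld_max_dist_bp
                )
                pres["maf_sweep"] = sweep
                for t, curve in sweep.items():
                    emit(curve, f"{pop}.ld_decay_maf{t}.tsv", "ld")
                sizes = tuple(
                    s for s in config.subsample_sizes if s <= Gq.n_samples
                )
                if sizes:
                    curves = subsample_ld_curves(
                        Gq,
                        sizes,
                        reps=config.subsample_reps,
                        seed=stage_seed(config.seed, "ld.subsample"),
                        bin_bp=config.ld_bin_bp,
                        max_bp=config.ld_max_dist_bp,
                    )
                    pres["subsample_curves"] = curves
                    for s, curve in curves.items():
                        emit(curve, f"{pop}.ld_decay_n{s}.tsv", "ld")
            except Exception as exc:  # noqa: BLE001
                raise StageError("ld", exc) from exc

        if "blocks" in stages:
            try:
                blocks = find_blocks(Gq, window_bp=config.block_window_bp)
                summary = block_summary(blocks, Gq)
                pres["blocks"] = blocks
                pres["block_summary"] = summary
                emit(blocks_to_frame(blocks), f"{pop}.blocks.det.tsv", "blocks")
                emit(summary.to_frame(), f"{pop}.block_summary.tsv", "blocks")
            except Exception as exc:  # noqa: BLE001
                raise StageError("blocks", exc) from exc

        if "ne" in stages:
            try:
                if "ld" not in stages:
                    records = pairwise_ld(Gq, config.ld_max_dist_bp)
                else:
                    records = records_by_pop[pop]
                ne_cfg = NeConfig(
                    n=Gq.n_samples,
                    alpha=config.ne_alpha,
                    beta=config.ne_beta,
                    map_function=config.ne_map_function,
                    cm_per_mb=config.ne_cm_per_mb,
                )
                traj = estimate_ne(records, ne_cfg, list(config.ne_generations))
                pres["ne_trajectory"] = traj
                emit(traj, f"{pop}.ne_trajectory.tsv", "ne")
            except Exception as exc:  # noqa: BLE001
                raise StageError("ne", exc) from exc

    if "phase" in stages:
        try:
            pops = list(config.inputs)
            P, C = pops[0], pops[1]
            rec_P = records_by_pop.get(P)
            rec_C = records_by_pop.get(C)
            if rec_P is None:
                rec_P = pairwise_ld(qc_by_pop[P], config.ld_max_dist_bp)
            if rec_C is None:
                rec_C = pairwise_ld(qc_by_pop[C], config.ld_max_dist_bp)
            paired = shared_ld(
                rec_P, rec_C, qc_by_pop[P].variants, qc_by_pop[C].variants
            )
            bins = phase_correlation(
                paired, config.phase_bin_bp, config.ld_max_dist_bp
            )
            bundle["phase_bins"] = bins
            emit(bins, f"phase.{P}_vs_{C}.tsv", "phase")
        except Exception as exc:  # noqa: BLE001
            raise StageError("phase", exc) from exc

    manifest = {
        "ldscape_version": __version__,
        "config": asdict(config),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": list(stages),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _adjacent_r2_values(G: GenotypeMatrix) -> np.ndarray:
    """Pooled adjacent-pair r2 values over all chromosomes."""
    from .ld import _em_from_counts, _pair_counts, _signed_r

    vals = []
    for _, sub in G.variants.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            continue
        em = _em_from_counts(_pair_counts(G.dosage, idx[:-1], idx[1:]))
        _, r2, defined = _signed_r(em)
        vals.append(r2[defined])
    return np.concatenate(vals) if vals else np.empty(0)


def write_fixture(out_prefix, seed: int = 0, n_chrom: int = 24) -> dict:
    """Generate and write the study-shaped two-population fixture as PLINK."""
    from .genotype_io import write_plink

    fx = paper_shaped_fixture(seed=seed, n_chrom=n_chrom)
    paths = {}
    for pop in ("purebred", "crossbred"):
        prefix = f"{out_prefix}.{pop}"
        write_plink(fx[pop], prefix)
        paths[pop] = prefix
    return {"paths": paths, **fx}
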