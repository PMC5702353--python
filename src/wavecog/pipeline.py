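"""End-to-end orchestration: simulate/load -> extract -> select -> evaluate.

A :class:`PipelineConfig` (typically loaded from YAML) names the input
source and every methodological knob — boundary mode, FDR variant,
leakage mode, variance target, fold count, seeds — and the run log and
report echo all of them, so no run is silently ambiguous about the
choices it made.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .dwt import BoundaryMode, band_labels, subband_ranges
from .evaluation import (
    LeakageMode,
    PerformanceReport,
    default_classifier_specs,
    evaluate,
    kfold_assign,
)
from .features import EXCLUDED_BY_DEFAULT, FeatureMatrix, build_feature_matrices
from .io import read_epoch_csv_dir, write_epochs
from .selection import FDRVariant
from .synth import EpochSet, SynthConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_feature_dir", "write_feature_dir"]

log = logging.getLogger("wavecog")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with defaults matching the library's."""

    simulate: dict | None = None          # SynthConfig fields
    epoch_dir: str | None = None          # alternative input: CSV epoch dir
    levels: int = 5
    boundary_mode: BoundaryMode = "periodic"
    variance_target: float = 0.95
    fdr_variant: FDRVariant = "canonical"
    k: int = 10
    fold_seed: int = 0
    stratified: bool = True
    leakage_mode: LeakageMode = "foldwise"
    classifier_seed: int = 0
    bands: list[str] | None = None        # None = all except D1
    output_dir: str = "wavecog_out"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.epoch_dir is None):
            raise ValueError("exactly one of 'simulate' or 'epoch_dir' required")
        if self.boundary_mode not in ("periodic", "symmetric"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")
        if self.fdr_variant not in ("canonical", "as_printed"):
            raise ValueError(f"unknown fdr variant {self.fdr_variant!r}")
        if self.leakage_mode not in ("foldwise", "paper_global"):
            raise ValueError(f"unknown leakage mode {self.leakage_mode!r}")
        if not 0.0 < self.variance_target <= 1.0:
            raise ValueError("variance_target must be in (0, 1]")
        if self.bands is not None:
            known = set(band_labels(self.levels))
            unknown = set(self.bands) - known
            if unknown:
                raise ValueError(f"unknown bands: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(**(self.simulate or {}))


def write_feature_dir(
    matrices: dict[str, FeatureMatrix], outdir: str | Path
) -> None:
    """One CSV per band (label + epoch_id + one column per channel)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for band, m in matrices.items():
        df = m.to_frame()
        df.insert(0, "epoch_id", range(m.n_instances))
        df.to_csv(outdir / f"features_{band}.csv", index=False)


def load_feature_dir(path: str | Path) -> dict[str, FeatureMatrix]:
    path = Path(path)
    out: dict[str, FeatureMatrix] = {}
    for f in sorted(path.glob("features_*.csv")):
        band = f.stem.removeprefix("features_")
        out[band] = FeatureMatrix.from_frame(pd.read_csv(f), band=band)
    if not out:
        raise FileNotFoundError(f"no features_*.csv files under {path}")
    return out


def _band_summary(
    matrices: dict[str, FeatureMatrix], fs: float, levels: int
) -> pd.DataFrame:
    """Mean relative energy (%) per band with its frequency range."""
    ranges = {label: pretty for label, _, _, pretty in subband_ranges(fs, levels)}
    level_of = lambda b: levels if b.startswith("A") else int(b[1:])
    rows = [
        {
            "level": level_of(band),
            "wavelet_energy_pct": 100.0 * m.values.mean(),
            "coefficients": band,
            "frequency_band_hz": ranges[band],
        }
        for band, m in matrices.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["level", "coefficients"], ascending=[True, True]
    )


def run_pipeline(config: PipelineConfig) -> PerformanceReport:
    """Execute the full scheme and write artifacts under ``output_dir``.

    Writes: the simulated epochs' manifest (when simulating), per-band
    feature CSVs, a band energy summary, ``report.json`` and
    ``report.csv``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.simulate is not None:
        epochs: EpochSet = generate_dataset(config.synth_config())
        write_epochs(epochs, outdir / "epochs")
        source = f"simulated(seed={config.synth_config().seed})"
    else:
        epochs = read_epoch_csv_dir(config.epoch_dir)
        source = f"epoch_dir({config.epoch_dir})"
    log.info(
        "stage=input source=%s epochs=%d channels=%d fs=%g len=%d elapsed=%.2fs",
        source, len(epochs.epochs), epochs.n_channels, epochs.fs,
        epochs.epoch_len, time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    matrices = build_feature_matrices(epochs, config.levels, config.boundary_mode)
    write_feature_dir(matrices, outdir / "features")
    _band_summary(matrices, epochs.fs, config.levels).to_csv(
        outdir / "band_summary.csv", index=False
    )
    log.info(
        "stage=extract bands=%d shape=%dx%d mode=%s elapsed=%.2fs",
        len(matrices), len(epochs.epochs), epochs.n_channels,
        config.boundary_mode, time.perf_counter() - t0,
    )

    if config.bands is not None:
        matrices = {b: matrices[b] for b in config.bands}
        exclude: tuple[str, ...] = ()
    else:
        exclude = EXCLUDED_BY_DEFAULT

    t0 = time.perf_counter()
    folds = kfold_assign(
        epochs.labels, k=config.k, seed=config.fold_seed,
        stratified=config.stratified,
    )
    report = evaluate(
        matrices,
        specs=default_classifier_specs(config.classifier_seed),
        folds=folds,
        leakage_mode=config.leakage_mode,
        variance_target=config.variance_target,
        fdr_variant=config.fdr_variant,
        exclude_bands=exclude,
    )
    log.info(
        "stage=evaluate rows=%d leakage=%s fdr=%s variance_target=%g "
        "k=%d fold_seed=%d classifier_seed=%d elapsed=%.2fs",
        len(report.results), config.leakage_mode, config.fdr_variant,
        config.variance_target, config.k, config.fold_seed,
        config.classifier_seed, time.perf_counter() - t0,
    )

    report.config["pipeline"] = asdict(config)
    (outdir / "report.json").write_text(report.to_json())
    report.to_table().to_csv(outdir / "report.csv", index=False)
    return report
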