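"""Relative wavelet sub-band energy features.

For each epoch and channel the 5-level db4 pyramid yields coefficient
arrays D1..D5 and A5; the energy of a band is its sum of squared
coefficients and the *relative* energy is that energy divided by the total
over all six bands.  One feature matrix is assembled per band: rows are
epochs, columns are channels, entries are that band's relative energy —
so across the six matrices every (epoch, channel) cell sums to one.

D1 (the top half of the spectrum) is conventionally dominated by EMG and
line noise; it is computed and reported here but flagged for exclusion
from classification, which downstream honours by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwt import BoundaryMode, WaveletDecomposition, band_labels, decompose
from .synth import EpochSet

__all__ = [
    "SubbandEnergy",
    "RelativeEnergyVector",
    "FeatureMatrix",
    "subband_energies",
    "relative_energies",
    "build_feature_matrices",
    "EXCLUDED_BY_DEFAULT",
]

# high-frequency band treated as noise and left out of classification
EXCLUDED_BY_DEFAULT = ("D1",)


@dataclass
class SubbandEnergy:
    """Per-band energies E_Di, E_A and their total, in squared-amplitude units."""

    e_detail: dict[int, float]
    e_approx: float
    e_total: float


@dataclass
class RelativeEnergyVector:
    """Unit-sum energy fractions keyed by band label."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        s = sum(self.fractions.values())
        if not np.isclose(s, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {s}")


@dataclass
class FeatureMatrix:
    """Instances x features table with per-instance class labels.

    ``band`` records which sub-band the values belong to (or a stage tag
    such as ``"PC"`` after selection).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    band: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (instances x features)")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("row count must equal label count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal feature-name count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, band: str = "") -> "FeatureMatrix":
        cols = [c for c in df.columns if c not in ("label", "epoch_id")]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            feature_names=list(cols),
            band=band,
        )


def subband_energies(decomp: WaveletDecomposition) -> SubbandEnergy:
    """Sum of squared coefficients per band, plus the grand total."""
    e_detail = {
        i + 1: float(np.sum(np.square(d))) for i, d in enumerate(decomp.details)
    }
    e_approx = float(np.sum(np.square(decomp.approximation)))
    return SubbandEnergy(
        e_detail=e_detail,
        e_approx=e_approx,
        e_total=sum(e_detail.values()) + e_approx,
    )


def relative_energies(energy: SubbandEnergy) -> RelativeEnergyVector:
    """Normalize band energies to unit-sum fractions.

    Raises
    ------
    ValueError
        If the total energy is zero (a flat epoch); never returns NaN.
    """
    if energy.e_total <= 0.0:
        raise ValueError("zero total energy: relative energies undefined")
    levels = len(energy.e_detail)
    fractions = {
        f"D{i}": energy.e_detail[i] / energy.e_total for i in energy.e_detail
    }
    fractions[f"A{levels}"] = energy.e_approx / energy.e_total
    return RelativeEnergyVector(fractions=fractions)


def build_feature_matrices(
    epochs: EpochSet, levels: int = 5, mode: BoundaryMode = "periodic"
) -> dict[str, FeatureMatrix]:
    """Relative-energy feature matrix for every sub-band.

    Returns all ``levels + 1`` band matrices (including the default-excluded
    D1) keyed by band label; row order follows the EpochSet, one column per
    channel.
    """
    n = len(epochs.epochs)
    bands = band_labels(levels)
    values = {b: np.empty((n, epochs.n_channels)) for b in bands}
    for e_idx, epoch in enumerate(epochs.epochs):
        for c_idx in range(epochs.n_channels):
            decomp = decompose(epoch.samples[c_idx], levels, mode, fs=epochs.fs)
            try:
                rel = relative_energies(subband_energies(decomp))
            except ValueError as err:
                raise ValueError(
                    f"epoch {e_idx}, channel {epochs.channel_names[c_idx]!r}: {err}"
                ) from err
            for b in bands:
                values[b][e_idx, c_idx] = rel.fractions[b]
    labels = epochs.labels
    return {
        b: FeatureMatrix(
            values=values[b],
            labels=labels,
            feature_names=list(epochs.channel_names),
            band=b,
        )
        for b in bands
    }
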