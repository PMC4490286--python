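"""In-memory containers shared across the pipeline.

Conventions
-----------
* Dosages are additive minor-allele counts coded 0/1/2 (AA=0, AB=1,
  BB=2 with B the minor allele), stored as float with ``nan`` marking a
  missing call.
* Subject metadata always carries ``subject_id``, ``group`` (``control``,
  ``case1``, ``case2``), ``age``, ``sex``, ``site`` and ``ethnicity``;
  clinical score columns are optional and may hold ``nan``.
* Spectral features are laid out channel-major: column ``c * k + j`` is
  channel ``c``, frequency component ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "SpectralFeatureMatrix", "EpochSpectra"]

GROUPS = ("control", "case1", "case2")


@dataclass
class GenotypeTable:
    """Subjects × SNPs additive dosage matrix with metadata.

    Attributes
    ----------
    dosages
        ``(n_subjects, n_snps)`` float array with values in {0, 1, 2}
        or ``nan`` for a missing call.
    snps
        One row per SNP: ``snp_id``, ``chrom``, ``pos`` (1-based bp),
        ``allele_a`` (major), ``allele_b`` (minor).
    subjects
        One row per subject; see module docstring for required columns.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x snps)")
        if self.dosages.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} snps"
            )
        called = self.dosages[np.isfinite(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or nan")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency among called genotypes.

        The B allele is coded as minor at generation time but may drift
        above 0.5 in a finite sample; the folded frequency is returned.
        """
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return np.isfinite(self.dosages).mean(axis=0)

    def subject_missing_rate(self) -> np.ndarray:
        return 1.0 - np.isfinite(self.dosages).mean(axis=1)

    def take_subjects(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.dosages[mask],
            self.snps.reset_index(drop=True),
            self.subjects.loc[mask].reset_index(drop=True),
        )

    def take_snps(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.dosages[:, mask],
            self.snps.loc[mask].reset_index(drop=True),
            self.subjects.reset_index(drop=True),
        )


@dataclass
class SpectralFeatureMatrix:
    """Subjects × (channels · frequency components) spatio-spectral weights."""

    weights: np.ndarray
    channel_names: list[str]
    n_freq_components: int
    component_spectra: np.ndarray | None = None  # (k, bins), unit-normalized
    spectra_freqs: np.ndarray | None = None
    provenance: str = "supplied"  # "computed" when produced by group ICA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        expected = len(self.channel_names) * self.n_freq_components
        if self.weights.shape[1] != expected:
            raise ValueError(
                f"{self.weights.shape[1]} feature columns, expected "
                f"{len(self.channel_names)} channels x {self.n_freq_components} components"
            )
        if not np.isfinite(self.weights).all():
            raise ValueError("spectral weights must be finite")

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def feature_labels(self) -> list[str]:
        """Channel-major labels, e.g. ``Cz:f3`` for channel Cz, component 3."""
        return [
            f"{ch}:f{j}"
            for ch in self.channel_names
            for j in range(self.n_freq_components)
        ]


@dataclass
class EpochSpectra:
    """Per-subject epoch amplitude spectra (epochs × channels × bins)."""

    amplitudes: list[np.ndarray] = field(default_factory=list)
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.size > 1 and not (np.diff(self.freqs) > 0).all():
            raise ValueError("bin frequencies must be strictly increasing")
        for a in self.amplitudes:
            if a.ndim != 3 or a.shape[1] != len(self.channel_names):
                raise ValueError("each subject array must be epochs x channels x bins")
            if a.shape[2] != self.freqs.size:
                raise ValueError("bin count mismatch")
            if not (np.asarray(a) >= 0).all():
                raise ValueError("amplitudes must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(self.amplitudes)
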