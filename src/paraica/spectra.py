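"""EEG epoch spectra and group-level spectral compression.

``spectral_transform`` converts time-domain epochs to amplitude spectra
(square root of the Hamming-windowed periodogram power) and drops bins
below a low-frequency cutoff (default 1.5 Hz, guarding against slow eye
movements).  ``group_spectral_ica`` stacks every subject's epoch
spectra, reduces them to a small number of data-driven frequency
components with PCA + Infomax, and back-reconstructs one spatio-spectral
weight per subject, channel and component — flattened channel-major so
a 64-channel montage with 8 components yields 512 feature columns.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datasets import EpochSpectra, SpectralFeatureMatrix
from .infomax import infomax_ica

__all__ = ["spectral_transform", "group_spectral_ica"]


def spectral_transform(
    epochs: np.ndarray,
    fs: float,
    low_cut: float = 1.5,
    channel_names: list[str] | None = None,
) -> EpochSpectra:
    """Amplitude spectra of time-domain epochs.

    Parameters
    ----------
    epochs
        ``(n_epochs, n_channels, n_samples)`` time-domain array for one
        subject.
    fs
        Sampling rate in Hz.
    low_cut
        Bins strictly below this frequency are discarded.

    The periodogram is one-sided and window-power normalized, so for a
    white-noise epoch the sum of squared amplitudes over all bins equals
    the windowed signal power (a Parseval identity the tests exercise).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if epochs.shape[-1] < 2:
        raise ValueError("epochs need at least 2 samples")
    if not np.isfinite(epochs).all():
        raise ValueError("epoch samples must be finite")
    if low_cut >= fs / 2:
        raise ValueError(f"low_cut {low_cut} Hz is not below Nyquist {fs / 2} Hz")

    freqs, power = signal.periodogram(
        epochs, fs=fs, window="hamming", axis=-1, scaling="spectrum"
    )
    amplitude = np.sqrt(power)
    keep = freqs >= low_cut
    names = channel_names or [f"ch{c:02d}" for c in range(epochs.shape[1])]
    return EpochSpectra(
        amplitudes=[amplitude[:, :, keep]],
        freqs=freqs[keep],
        channel_names=names,
    )


def group_spectral_ica(
    collection: list[EpochSpectra],
    n_components: int = 8,
    seed: int = 0,
    max_iter: int = 512,
) -> SpectralFeatureMatrix:
    """Compress a cohort's epoch spectra into data-driven frequency components.

    All (subject, epoch, channel) spectra are stacked into one matrix of
    shape (rows × bins) and decomposed with PCA + Infomax into
    ``n_components`` component spectra.  Per-row weights are averaged
    over epochs within each subject, giving one weight per subject,
    channel and component, flattened channel-major.  Component spectra
    are unit-normalized with their peak forced positive; the subject
    weights carry the magnitude.
    """
    # flatten one EpochSpectra per subject; multi-subject EpochSpectra are
    # also accepted (amplitudes list with several subjects)
    subjects: list[np.ndarray] = []
    first = collection[0]
    for spectra in collection:
        if list(spectra.channel_names) != list(first.channel_names):
            raise ValueError("all subjects must share the channel montage")
        if not np.array_equal(spectra.freqs, first.freqs):
            raise ValueError("all subjects must share the frequency grid")
        subjects.extend(spectra.amplitudes)
    if len(subjects) < 2:
        raise ValueError("group ICA needs at least 2 subjects")

    n_ch = len(first.channel_names)
    stacked = np.vstack([a.reshape(a.shape[0] * n_ch, -1) for a in subjects])

    dec = infomax_ica(stacked, n_components, seed=seed, max_iter=max_iter)
    spectra_maps = dec.sources  # (k, bins)
    weights_rows = dec.loadings  # (rows, k)

    # normalize: unit-norm spectra, peak positive; weights absorb scale
    norms = np.linalg.norm(spectra_maps, axis=1)
    norms[norms == 0] = 1.0
    peak_sign = np.sign(spectra_maps[np.arange(n_components),
                                     np.abs(spectra_maps).argmax(axis=1)])
    peak_sign[peak_sign == 0] = 1.0
    spectra_maps = spectra_maps / norms[:, None] * peak_sign[:, None]
    weights_rows = weights_rows * norms[None, :] * peak_sign[None, :]

    # back-reconstruct: average epoch weights within subject per channel
    out = np.empty((len(subjects), n_ch * n_components))
    row = 0
    for s_idx, arr in enumerate(subjects):
        n_ep = arr.shape[0]
        block = weights_rows[row : row + n_ep * n_ch].reshape(n_ep, n_ch, n_components)
        out[s_idx] = block.mean(axis=0).reshape(-1)  # channel-major
        row += n_ep * n_ch

    return SpectralFeatureMatrix(
        weights=out,
        channel_names=list(first.channel_names),
        n_freq_components=n_components,
        component_spectra=spectra_maps,
        spectra_freqs=first.freqs,
        provenance="computed",
    )
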