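"""HDF5 serialization for decompositions, spectral features and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .datasets import SpectralFeatureMatrix
from .infomax import IcaDecomposition
from .parallel import ParaIcaResult
from .synth import CohortConfig, TruthBundle

__all__ = [
    "save_features",
    "load_features",
    "save_truth",
    "load_truth",
    "save_paraica",
    "load_paraica",
]


def save_features(features: SpectralFeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("spectral_features")
        g.create_dataset("weights", data=features.weights)
        g.create_dataset(
            "channel_names", data=np.array(features.channel_names, dtype="S")
        )
        g.attrs["n_freq_components"] = features.n_freq_components
        g.attrs["provenance"] = features.provenance
        if features.component_spectra is not None:
            g.create_dataset("component_spectra", data=features.component_spectra)
        if features.spectra_freqs is not None:
            g.create_dataset("spectra_freqs", data=features.spectra_freqs)


def load_features(path: str | Path) -> SpectralFeatureMatrix:
    with h5py.File(path, "r") as fh:
        g = fh["spectral_features"]
        return SpectralFeatureMatrix(
            weights=g["weights"][()],
            channel_names=[c.decode() for c in g["channel_names"][()]],
            n_freq_components=int(g.attrs["n_freq_components"]),
            component_spectra=g["component_spectra"][()]
            if "component_spectra" in g
            else None,
            spectra_freqs=g["spectra_freqs"][()] if "spectra_freqs" in g else None,
            provenance=str(g.attrs["provenance"]),
        )


def save_truth(truth: TruthBundle, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("truth")
        for name in ("geno_loadings", "eeg_loadings", "geno_maps", "eeg_maps"):
            g.create_dataset(name, data=getattr(truth, name))
        g.create_dataset("group_labels", data=np.array(truth.group_labels, dtype="S"))
        g.create_dataset("subpop_labels", data=np.asarray(truth.subpop_labels))
        g.attrs["designed_r"] = json.dumps([list(p) for p in truth.designed_r])
        if truth.config is not None:
            g.attrs["config"] = truth.config.to_json()


def load_truth(path: str | Path) -> TruthBundle:
    with h5py.File(path, "r") as fh:
        g = fh["truth"]
        cfg = (
            CohortConfig.from_json(g.attrs["config"]) if "config" in g.attrs else None
        )
        return TruthBundle(
            geno_loadings=g["geno_loadings"][()],
            eeg_loadings=g["eeg_loadings"][()],
            geno_maps=g["geno_maps"][()],
            eeg_maps=g["eeg_maps"][()],
            designed_r=tuple(tuple(p) for p in json.loads(g.attrs["designed_r"])),
            group_labels=np.array([b.decode() for b in g["group_labels"][()]]),
            subpop_labels=g["subpop_labels"][()],
            config=cfg,
        )


def _save_decomposition(g: h5py.Group, dec: IcaDecomposition) -> None:
    for name in ("loadings", "sources", "z_maps", "unmixing", "whitening",
                 "dewhitening", "row_means"):
        g.create_dataset(name, data=getattr(dec, name))
    g.attrs["k"] = dec.k
    g.attrs["converged"] = dec.converged
    g.attrs["n_iter"] = dec.n_iter


def _load_decomposition(g: h5py.Group) -> IcaDecomposition:
    return IcaDecomposition(
        loadings=g["loadings"][()],
        sources=g["sources"][()],
        z_maps=g["z_maps"][()],
        unmixing=g["unmixing"][()],
        whitening=g["whitening"][()],
        dewhitening=g["dewhitening"][()],
        k=int(g.attrs["k"]),
        converged=bool(g.attrs["converged"]),
        n_iter=int(g.attrs["n_iter"]),
        row_means=g["row_means"][()],
    )


def save_paraica(result: ParaIcaResult, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        _save_decomposition(fh.create_group("snp"), result.snp)
        _save_decomposition(fh.create_group("eeg"), result.eeg)
        fh.create_dataset("cross_corr", data=result.cross_corr)
        fh.attrs["converged"] = result.converged
        fh.attrs["n_iter"] = result.n_iter
        fh.attrs["trace"] = json.dumps(result.trace)


def load_paraica(path: str | Path) -> ParaIcaResult:
    with h5py.File(path, "r") as fh:
        return ParaIcaResult(
            snp=_load_decomposition(fh["snp"]),
            eeg=_load_decomposition(fh["eeg"]),
            cross_corr=fh["cross_corr"][()],
            trace=json.loads(fh.attrs["trace"]),
            converged=bool(fh.attrs["converged"]),
            n_iter=int(fh.attrs["n_iter"]),
        )
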