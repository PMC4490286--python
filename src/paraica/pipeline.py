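"""End-to-end orchestration: data → QC → prefilter → decomposition →
association → reliability, with per-stage artifacts on disk.

Every stage writes its outputs under the run directory so stages can be
rerun or inspected independently; a manifest records the configuration,
derived seeds, stage ordering and failure point (if any).  Identical
configuration and master seed reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import h5io, plinkio
from .assoc import (
    build_covariate_design,
    group_and_clinical_tests,
    partial_association_matrix,
)
from .datasets import GenotypeTable, SpectralFeatureMatrix
from .order import estimate_order_mdl, estimate_order_stability
from .parallel import CouplingConfig, para_ica, zscore_select
from .qc import (
    ld_prune,
    sample_qc,
    snp_filters,
    stratification_adjust,
    univariate_prefilter,
)
from .synth import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and modes of a pipeline run.

    Exactly one input mode: a synthetic ``cohort`` design, or paths to
    existing genotype (PLINK prefix or dosage-text prefix) and spectral
    feature (HDF5) files.
    """

    cohort: CohortConfig | None = None
    genotype_path: str | None = None
    features_path: str | None = None

    # sample QC
    sample_missing_max: float = 0.03
    het_sd: float = 3.0
    ibd_max: float = 0.1875
    # SNP filters
    maf_min: float = 0.05
    call_min: float = 0.98
    hwe_alpha: float = 1e-5
    diffmiss_alpha: float = 1e-5
    # LD pruning
    ld_r2_max: float = 0.8
    ld_window_bp: int = 10_000
    # stratification / prefilter
    strat_components: int = 10
    strat_alpha: float = 0.05
    prefilter_alpha: float = 0.025
    # decomposition
    order_mode_snp: str = "stability"  # mdl | stability | fixed
    order_mode_eeg: str = "mdl"
    k_snp: int | None = None  # used when mode == "fixed"
    k_eeg: int | None = None
    stability_candidates: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 12)
    stability_runs: int = 10
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    max_iter: int = 512
    # association / selection
    assoc_alpha: float = 0.05
    z_threshold: float = 2.0
    # reliability
    run_reliability: bool = True
    reliability_jobs: int = 1

    # stop early: "prefilter" halts after QC+prefilter artifacts are written
    stop_after: str | None = None

    seed: int = 0

    def validate(self) -> None:
        modes = int(self.cohort is not None) + int(self.genotype_path is not None)
        if modes != 1:
            raise ValueError("exactly one input mode: cohort config OR input paths")
        if self.genotype_path is not None and self.features_path is None:
            raise ValueError("features_path required with genotype_path")
        for name, lo, hi in [
            ("sample_missing_max", 0, 1),
            ("maf_min", 0, 0.5),
            ("call_min", 0, 1),
            ("hwe_alpha", 0, 1),
            ("diffmiss_alpha", 0, 1),
            ("ld_r2_max", 0, 1),
            ("prefilter_alpha", 0, 1),
            ("assoc_alpha", 0, 1),
            ("strat_alpha", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        for mode in (self.order_mode_snp, self.order_mode_eeg):
            if mode not in ("mdl", "stability", "fixed"):
                raise ValueError(f"unknown order mode {mode!r}")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)


def _child_seeds(master: int, n: int = 8) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def _select_order(mode, data, k_fixed, candidates, n_runs, seed, max_iter):
    if mode == "fixed":
        if not k_fixed:
            raise ValueError("fixed order mode requires k")
        return int(k_fixed), {"mode": "fixed"}
    if mode == "mdl":
        k = estimate_order_mdl(data)
        return max(k, 1), {"mode": "mdl"}
    k, detail = estimate_order_stability(
        data, list(candidates), n_runs=n_runs, seed=seed, max_iter=max_iter
    )
    return k, {"mode": "stability", **{k2: v for k2, v in detail.items() if k2 == "scores"}}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages, writing artifacts and a manifest to ``out_dir``.

    Returns the run directory.  On a stage failure the manifest records
    the failure point and earlier artifacts are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    manifest: dict = {
        "config_sha1": hashlib.sha1(config.to_json().encode()).hexdigest(),
        "master_seed": config.seed,
        "child_seeds": seeds,
        "stages": [],
        "status": "running",
    }
    (out / "pipeline_config.json").write_text(config.to_json())

    def _stage(name: str):
        t0 = time.time()
        manifest["stages"].append({"name": name, "t0": t0})

        def _done(**extra):
            manifest["stages"][-1]["seconds"] = round(time.time() - t0, 3)
            manifest["stages"][-1].update(extra)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

        return _done

    try:
        # ---- input ---------------------------------------------------
        done = _stage("input")
        if config.cohort is not None:
            table, features, truth = generate_cohort(config.cohort)
            plinkio.write_plink(table, out / "cohort")
            h5io.save_features(features, out / "features.h5")
            h5io.save_truth(truth, out / "truth.h5")
        else:
            prefix = Path(config.genotype_path)
            if prefix.with_suffix(".bed").exists():
                table = plinkio.read_plink(prefix)
            else:
                table = plinkio.read_dosage_text(prefix)
            features = h5io.load_features(config.features_path)
        if features.n_subjects != table.n_subjects:
            raise ValueError("subject count differs between genotypes and features")
        done(n_subjects=table.n_subjects, n_snps=table.n_snps,
             n_features=features.n_features)

        # ---- QC ------------------------------------------------------
        done = _stage("sample_qc")
        ids_before = table.subjects["subject_id"].to_numpy()
        table, rep_sample = sample_qc(
            table, config.sample_missing_max, config.het_sd, config.ibd_max,
            seed=seeds[0],
        )
        # features rows follow the pre-QC subject order; keep survivors only
        surviving = set(table.subjects["subject_id"])
        row_mask = np.array([sid in surviving for sid in ids_before])
        features = SpectralFeatureMatrix(
            weights=features.weights[row_mask],
            channel_names=features.channel_names,
            n_freq_components=features.n_freq_components,
            component_spectra=features.component_spectra,
            spectra_freqs=features.spectra_freqs,
            provenance=features.provenance,
        )
        done(removed=int((~row_mask).sum()))

        done2 = _stage("snp_qc")
        table, rep_snp = snp_filters(
            table, config.maf_min, config.call_min, config.hwe_alpha,
            config.diffmiss_alpha,
        )
        table, rep_ld = ld_prune(table, config.ld_r2_max, config.ld_window_bp)
        qc_steps = rep_sample.steps + rep_snp.steps + rep_ld.steps
        pd.DataFrame(qc_steps).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        done2(n_snps=table.n_snps)

        done = _stage("stratification")
        adjusted, rep_strat = stratification_adjust(
            table, config.strat_components, config.strat_alpha
        )
        qc_json = {
            "steps": qc_steps,
            "stratification": rep_strat.stratification,
            "notes": rep_sample.notes + rep_strat.notes,
        }
        (out / "qc_report.json").write_text(json.dumps(qc_json, indent=2, default=str))
        done(adjusted_components=rep_strat.stratification["adjusted_components"])

        done = _stage("prefilter")
        selected, prefilter_stats, diag = univariate_prefilter(
            table, adjusted, config.prefilter_alpha
        )
        prefilter_stats.to_csv(out / "prefilter_stats.tsv", sep="\t", index=False)
        lambda_gc = {c: d["lambda_gc"] for c, d in diag["contrasts"].items()}
        for c, d in diag["contrasts"].items():
            d["qq"].to_csv(out / f"qq_{c}.tsv", sep="\t", index=False)
        sel_mask = table.snps["snp_id"].isin(selected).to_numpy()
        snp_data = adjusted[:, sel_mask]
        snp_ids = table.snps["snp_id"].to_numpy()[sel_mask]
        done(n_selected=len(selected), lambda_gc=lambda_gc)

        if config.stop_after == "prefilter":
            manifest["status"] = "success"
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=str)
            )
            return out

        # ---- order selection & decomposition ------------------------
        done = _stage("order_selection")
        k_eeg, info_eeg = _select_order(
            config.order_mode_eeg, features.weights, config.k_eeg,
            config.stability_candidates, config.stability_runs, seeds[1],
            config.max_iter,
        )
        k_snp, info_snp = _select_order(
            config.order_mode_snp, snp_data, config.k_snp,
            config.stability_candidates, config.stability_runs, seeds[2],
            config.max_iter,
        )
        k_eeg = min(k_eeg, features.n_features, table.n_subjects - 1)
        k_snp = min(k_snp, snp_data.shape[1], table.n_subjects - 1)
        done(k_eeg=k_eeg, k_snp=k_snp, eeg=info_eeg, snp=info_snp)

        done = _stage("para_ica")
        result = para_ica(
            snp_data, features.weights, k_snp, k_eeg,
            coupling=config.coupling, seed=seeds[3], max_iter=config.max_iter,
        )
        h5io.save_paraica(result, out / "decomposition.h5")
        done(converged=result.converged, n_iter=result.n_iter,
             max_abs_cross_corr=float(np.abs(result.cross_corr).max()))

        # ---- association ---------------------------------------------
        done = _stage("association")
        covariates = build_covariate_design(table.subjects)
        assoc = partial_association_matrix(
            result.eeg.loadings, result.snp.loadings, covariates,
            alpha=config.assoc_alpha,
        )
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        (out / "association.json").write_text(
            json.dumps(
                {
                    "alpha": assoc.attrs["alpha"],
                    "threshold": assoc.attrs["threshold"],
                    "n_pairs": assoc.attrs["n_pairs"],
                    "rows": assoc.to_dict(orient="records"),
                },
                indent=2,
                default=lambda o: o.item() if hasattr(o, "item") else str(o),
            )
        )
        sig_pairs = [
            (int(r.eeg_component), int(r.snp_component))
            for r in assoc.itertuples()
            if r.significant
        ]

        # component feature tables at |Z| >= threshold
        snp_tables = zscore_select(result.snp, config.z_threshold, list(snp_ids))
        eeg_tables = zscore_select(
            result.eeg, config.z_threshold, features.feature_labels()
        )
        for name, tables in (("snp", snp_tables), ("eeg", eeg_tables)):
            rows = []
            for ci, t in enumerate(tables):
                t = t.copy()
                t.insert(0, "component", ci)
                rows.append(t)
            pd.concat(rows, ignore_index=True).to_csv(
                out / f"components_{name}.tsv", sep="\t", index=False
            )

        # group and clinical comparisons on components of significant pairs
        clin_cols = [
            c for c in table.subjects.columns
            if c.startswith("panss_") or c in ("schizo_bipolar_scale", "cpz_equivalent")
        ]
        clinical = table.subjects[clin_cols] if clin_cols else None
        groups = table.subjects["group"].to_numpy()
        comp_ids = sorted({e for e, _ in sig_pairs}) or list(range(k_eeg))
        group_report = group_and_clinical_tests(
            result.eeg.loadings[:, comp_ids], groups, clinical, comp_ids
        )
        group_report["group_tests"].to_csv(out / "group_tests.tsv", sep="\t", index=False)
        group_report["clinical_correlations"].to_csv(
            out / "clinical_correlations.tsv", sep="\t", index=False
        )
        done(significant_pairs=sig_pairs)

        # ---- reliability ---------------------------------------------
        if config.run_reliability:
            from .reliability import loo_reliability

            done = _stage("reliability")
            pairs = sig_pairs or [
                tuple(
                    int(v)
                    for v in np.unravel_index(
                        np.abs(result.cross_corr).argmax(), result.cross_corr.shape
                    )
                )
            ]
            report = loo_reliability(
                snp_data, features.weights, result, pairs,
                coupling=config.coupling, seed=seeds[3], max_iter=config.max_iter,
                n_jobs=config.reliability_jobs,
            )
            (out / "reliability.json").write_text(
                json.dumps(
                    {
                        "n_runs": report.n_runs,
                        "matched_on": report.matched_on,
                        "n_nonconverged": report.n_nonconverged,
                        "pair_reliability": {
                            f"eeg{e}_snp{s}": v
                            for (e, s), v in report.pair_reliability.items()
                        },
                    },
                    indent=2,
                )
            )
            rows = [
                {"pair": f"eeg{e}_snp{s}", **v}
                for (e, s), v in report.pair_reliability.items()
            ]
            pd.DataFrame(rows).to_csv(out / "reliability.tsv", sep="\t", index=False)
            done(n_nonconverged=report.n_nonconverged)

        manifest["status"] = "success"
    except Exception as exc:  # pragma: no cover - failure bookkeeping
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
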